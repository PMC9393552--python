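"""Phenotype record assembly, plot aggregation, and season combination.

One record holds the five digital phenotypes (LV, LV_Den, LV_PH, Sonar_PH,
NDVI) plus harvested fresh mass (FM, g) for a row or a plot in one season.
Plot records aggregate their three rows: FM and LV are summed, heights are
averaged, NDVI is an area-weighted mean, and LV_Den is the pooled point
ratio (total above-cutoff returns over total returns) when point counts are
available.

Season combination applies the trial's filters: winter FM exists only at
plot level, so winter drops out of the row-level combined set; late spring
loses the plots whose harvest was spoiled by a faulty mower cutting plate.
"""

from __future__ import annotations

import logging

import pandas as pd

from .fieldsim import FAULTY_MOWER_PLOTS

__all__ = ["assemble_dataset", "aggregate_to_plot", "combine_seasons",
           "PHENOTYPES", "IntegrityError", "AggregationError"]

log = logging.getLogger(__name__)

PHENOTYPES = ("LV", "LV_Den", "LV_PH", "Sonar_PH", "NDVI")
SEASON_LABELS = ("winter", "late_spring", "summer")


class IntegrityError(ValueError):
    """Duplicate keys or inconsistent identifiers."""


class AggregationError(ValueError):
    """A plot does not have exactly its expected row records."""


def _check_unique(df: pd.DataFrame, key: str, name: str) -> None:
    dups = df[key][df[key].duplicated()].unique()
    if len(dups):
        raise IntegrityError(f"duplicate {key} in {name}: {list(dups)[:5]}")


def assemble_dataset(
    metric_tables: dict[str, pd.DataFrame],
    fm_table: pd.DataFrame,
    season: str,
    row_areas: dict[int, float] | None = None,
) -> pd.DataFrame:
    """Inner-join per-row metric tables and the FM table on ``row_id``.

    ``metric_tables`` maps a label to a DataFrame with ``row_id`` plus one or
    more phenotype columns (a lidar table may also carry ``n_points`` /
    ``n_above`` counts, kept for pooled plot aggregation). Rows missing any
    required phenotype are dropped and the drop count logged. ``row_areas``
    optionally attaches polygon areas for area-weighted NDVI aggregation.
    """
    if season not in SEASON_LABELS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASON_LABELS}")
    _check_unique(fm_table, "row_id", "FM table")
    merged = fm_table.copy()
    for name, table in metric_tables.items():
        _check_unique(table, "row_id", f"{name} table")
        overlap = [c for c in table.columns if c != "row_id" and c in merged.columns]
        merged = merged.merge(table.drop(columns=overlap), on="row_id", how="inner")
    required = [c for c in PHENOTYPES + ("FM",) if c in merged.columns]
    before = len(merged)
    merged = merged.dropna(subset=required)
    dropped = before - len(merged)
    if dropped:
        log.info("assemble_dataset(%s): dropped %d rows with missing phenotypes", season, dropped)
    merged = merged.copy()
    merged["season"] = season
    merged["level"] = "row"
    if row_areas is not None:
        merged["area"] = merged["row_id"].map(row_areas)
    out_of_range = merged["FM"] < 0
    if out_of_range.any():
        raise IntegrityError("negative FM values present")
    return merged.reset_index(drop=True)


def aggregate_to_plot(records: pd.DataFrame, rows_per_plot: int = 3) -> pd.DataFrame:
    """Aggregate row records to plot level.

    FM and LV are sums; LV_PH and Sonar_PH are means; NDVI is the
    area-weighted mean of row values (plain mean when no ``area`` column);
    LV_Den is the pooled ratio total-above/total points when ``n_points`` /
    ``n_above`` columns exist, else the mean of row ratios.
    """
    if "plot_id" not in records.columns:
        raise AggregationError("records lack a plot_id column")
    bad = records.groupby("plot_id").size()
    bad = bad[bad != rows_per_plot]
    if len(bad):
        raise AggregationError(
            f"plots without exactly {rows_per_plot} row records: {list(bad.index)[:10]}"
        )
    have_counts = {"n_points", "n_above"}.issubset(records.columns)
    have_area = "area" in records.columns

    def agg(group: pd.DataFrame) -> pd.Series:
        out = {"FM": group["FM"].sum()}
        if "LV" in group:
            out["LV"] = group["LV"].sum()
        for col in ("LV_PH", "Sonar_PH"):
            if col in group:
                out[col] = group[col].mean()
        if "NDVI" in group:
            if have_area:
                w = group["area"]
                out["NDVI"] = (group["NDVI"] * w).sum() / w.sum()
            else:
                out["NDVI"] = group["NDVI"].mean()
        if "LV_Den" in group:
            if have_counts and group["n_points"].sum() > 0:
                out["LV_Den"] = group["n_above"].sum() / group["n_points"].sum()
            else:
                out["LV_Den"] = group["LV_Den"].mean()
        return pd.Series(out)

    plot_df = records.groupby("plot_id", sort=True).apply(agg, include_groups=False).reset_index()
    if "season" in records.columns:
        seasons = records.groupby("plot_id")["season"].first()
        plot_df["season"] = plot_df["plot_id"].map(seasons)
    plot_df["level"] = "plot"
    return plot_df


def combine_seasons(
    seasonal: dict[str, dict[str, pd.DataFrame]],
    faulty_plots: tuple[int, ...] = FAULTY_MOWER_PLOTS,
) -> dict[str, pd.DataFrame]:
    """Stack seasonal datasets into combined row- and plot-level tables.

    ``seasonal`` maps season label to ``{"row": df, "plot": df}``; either
    level may be absent (winter has no row-level FM). Filters applied:

    * row level: winter excluded entirely; late-spring rows belonging to
      ``faulty_plots`` removed; summer kept whole,
    * plot level: all seasons stacked after removing ``faulty_plots`` from
      late spring.

    Returns ``{"row": ..., "plot": ...}`` with a ``season`` column retained,
    and logs the record count after each filter.
    """
    for season in seasonal:
        if season not in SEASON_LABELS:
            raise ValueError(f"unknown season label {season!r}")
    row_parts, plot_parts = [], []
    for season, levels in seasonal.items():
        row_df = levels.get("row")
        plot_df = levels.get("plot")
        if season == "winter":
            if row_df is not None and len(row_df):
                log.warning("winter FM is plot-level only; ignoring %d row records", len(row_df))
        elif row_df is not None:
            if season == "late_spring":
                row_df = row_df[~row_df["plot_id"].isin(faulty_plots)]
                log.info("late_spring row level: %d records after faulty-mower filter", len(row_df))
            row_parts.append(row_df)
        if plot_df is not None:
            if season == "late_spring":
                plot_df = plot_df[~plot_df["plot_id"].isin(faulty_plots)]
                log.info("late_spring plot level: %d records after faulty-mower filter", len(plot_df))
            plot_parts.append(plot_df)
    combined = {}
    combined["row"] = (
        pd.concat(row_parts, ignore_index=True) if row_parts else pd.DataFrame()
    )
    combined["plot"] = (
        pd.concat(plot_parts, ignore_index=True) if plot_parts else pd.DataFrame()
    )
    if len(combined["row"]) == 0:
        log.warning("combined row-level dataset is empty (winter FM is plot-level only)")
    log.info("combined datasets: %d row records, %d plot records",
             len(combined["row"]), len(combined["plot"]))
    return combined
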