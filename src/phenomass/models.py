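"""Multiple linear regression model family and best-subset selection.

The biomass prediction models compared here are all MLR fits of harvested
fresh mass, y = b0 + b1*x1 + ... + bn*xn + e. The named family (R-formula
crossing semantics, A x B = A + B + A:B):

====  ==============================  =====================================
name  formula                         expanded terms
====  ==============================  =====================================
M1    FM ~ NDVI x Sonar_PH            NDVI, Sonar_PH, NDVI:Sonar_PH
M2    FM ~ NDVI x LV_PH               NDVI, LV_PH, NDVI:LV_PH
M3    FM ~ LV x NDVI                  LV, NDVI, LV:NDVI
M4    FM ~ LV x LV_Den                LV, LV_Den, LV:LV_Den
M5    FM ~ LV x (LV_Den + NDVI)       LV, LV_Den, NDVI, LV:LV_Den, LV:NDVI
M6    FM ~ LV x (LV_Den x NDVI)       all mains, 2-way and 3-way terms
====  ==============================  =====================================

M3-M6 embody the mass premise FM ~ volume * density: LV proxies volume and
LV_Den / NDVI proxy the unknown plant density, so their interaction term is
the physically motivated predictor.

Best-subset selection enumerates all 31 non-empty main-effects subsets of
the five phenotypes and ranks them by Adjusted R^2 (higher better), Mallows
Cp and BIC (lower better), ties broken toward smaller subsets.

Metric conventions: RSE = sqrt(SSE/(n-p)); RMSE = sqrt(SSE/n); AIC/BIC use
the full Gaussian log-likelihood (including the 2*pi constant) and count the
error variance as a parameter; Cp = SSE/s2_full - n + 2p with s2_full from
the all-predictors main-effects model, so the full model's Cp equals its own
p exactly. PER = RSE / mean(response), a unitless relative prediction error
(this package's definition).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec", "FitResult", "ModelMetrics", "SubsetResult",
    "MODEL_FORMULAS", "expand_model", "fit_ols", "model_metrics",
    "best_subset_search", "pearson", "subset_table",
]

PREDICTORS = ("LV", "LV_Den", "LV_PH", "Sonar_PH", "NDVI")

#: Named model family as (factors crossed fully) | explicit term lists.
MODEL_FORMULAS: dict[str, tuple[tuple[str, ...], ...]] = {
    # each inner tuple is one term: a single name = main effect, several = interaction
    "M1": (("NDVI",), ("Sonar_PH",), ("NDVI", "Sonar_PH")),
    "M2": (("NDVI",), ("LV_PH",), ("NDVI", "LV_PH")),
    "M3": (("LV",), ("NDVI",), ("LV", "NDVI")),
    "M4": (("LV",), ("LV_Den",), ("LV", "LV_Den")),
    "M5": (("LV",), ("LV_Den",), ("NDVI",), ("LV", "LV_Den"), ("LV", "NDVI")),
    "M6": (
        ("LV",), ("LV_Den",), ("NDVI",),
        ("LV", "LV_Den"), ("LV", "NDVI"), ("LV_Den", "NDVI"),
        ("LV", "LV_Den", "NDVI"),
    ),
}


class SpecificationError(ValueError):
    """Unknown model name or a required predictor column is absent."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient; names the collinear terms."""


@dataclass(frozen=True)
class ModelSpec:
    """A model as a list of terms; each term is a tuple of predictor names
    whose columns are multiplied (length 1 = main effect). Intercept always
    included."""

    name: str
    terms: tuple[tuple[str, ...], ...]
    response: str = "FM"

    @property
    def p(self) -> int:
        """Parameter count including the intercept."""
        return len(self.terms) + 1

    def term_labels(self) -> list[str]:
        return [":".join(t) for t in self.terms]

    def design_matrix(self, data: pd.DataFrame) -> np.ndarray:
        missing = {v for t in self.terms for v in t} - set(data.columns)
        if missing:
            raise SpecificationError(f"predictors absent from data: {sorted(missing)}")
        n = len(data)
        cols = [np.ones(n)]
        for term in self.terms:
            col = np.ones(n)
            for v in term:
                col = col * data[v].to_numpy(dtype=float)
            cols.append(col)
        return np.column_stack(cols)


def expand_model(name, available: tuple[str, ...] = PREDICTORS, response: str = "FM") -> ModelSpec:
    """Build a ModelSpec from a family name (M1-M6) or an explicit subset.

    A sequence of predictor names yields a main-effects-only model (the form
    used by best-subset search). Terms are unique; duplicates collapse.
    """
    if isinstance(name, str):
        if name not in MODEL_FORMULAS:
            raise SpecificationError(f"unknown model {name!r}; expected M1-M6 or a subset")
        terms = MODEL_FORMULAS[name]
    else:
        subset = tuple(name)
        if not subset:
            raise SpecificationError("subset must be non-empty")
        unknown = set(subset) - set(available)
        if unknown:
            raise SpecificationError(f"unknown predictors: {sorted(unknown)}")
        terms = tuple((v,) for v in subset)
        name = "+".join(subset)
    needed = {v for t in terms for v in t}
    unknown = needed - set(available)
    if unknown:
        raise SpecificationError(f"required predictors absent: {sorted(unknown)}")
    # de-duplicate preserving order
    seen: list[tuple[str, ...]] = []
    for t in terms:
        if t not in seen:
            seen.append(t)
    return ModelSpec(name=name, terms=tuple(seen), response=response)


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: np.ndarray  # intercept first, g per unit of each term
    n: int
    p: int  # parameters incl. intercept
    sse: float
    sst: float
    fitted: np.ndarray
    residuals: np.ndarray
    y_mean: float

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return self.spec.design_matrix(data) @ self.coefficients


def fit_ols(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Ordinary least squares fit of the model spec on a phenotype table."""
    X = spec.design_matrix(data)
    y = data[spec.response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} <= p={p}: not enough observations")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        labels = ["(intercept)"] + spec.term_labels()
        # identify terms whose removal restores full rank
        collinear = []
        for j in range(1, p):
            Xj = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xj) == rank:
                collinear.append(labels[j])
        raise RankDeficiencyError(f"design matrix rank deficient; collinear terms: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    return FitResult(spec=spec, coefficients=beta, n=n, p=p, sse=sse, sst=sst,
                     fitted=fitted, residuals=resid, y_mean=float(y.mean()))


@dataclass(frozen=True)
class ModelMetrics:
    r_squared: float
    adj_r_squared: float
    rse: float  # g
    rmse: float  # g
    mae: float  # g
    aic: float
    bic: float
    cp: float | None  # Mallows Cp; None when no reference full model given
    per: float  # RSE / mean(response)
    f_statistic: float
    pearson_r: float  # predicted vs measured


def model_metrics(fit: FitResult, full_fit: FitResult | None = None) -> ModelMetrics:
    """All reported fit statistics for one OLS fit.

    ``full_fit`` supplies the error-variance reference for Mallows Cp
    (conventionally the all-predictors main-effects model on the same data).
    """
    n, p = fit.n, fit.p
    if n == p:
        raise ValueError("RSE undefined at n = p")
    sse, sst = fit.sse, fit.sst
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    rse = math.sqrt(sse / (n - p))
    rmse = math.sqrt(sse / n)
    mae = float(np.mean(np.abs(fit.residuals)))
    # Gaussian log-likelihood based criteria, counting the error variance
    aic = n * math.log(2 * math.pi) + n * math.log(sse / n) + n + 2 * (p + 1)
    bic = n * math.log(2 * math.pi) + n * math.log(sse / n) + n + math.log(n) * (p + 1)
    cp = None
    if full_fit is not None:
        s2_full = full_fit.sse / (full_fit.n - full_fit.p)
        cp = sse / s2_full - n + 2 * p
    per = rse / fit.y_mean if fit.y_mean != 0 else float("inf")
    if p > 1 and sse > 0:
        f_stat = ((sst - sse) / (p - 1)) / (sse / (n - p))
    else:
        f_stat = float("inf") if sse == 0 else float("nan")
    if np.std(fit.fitted) > 0 and sst > 0:
        y = fit.fitted + fit.residuals
        r_pred = float(np.corrcoef(fit.fitted, y)[0, 1])
    else:
        r_pred = float("nan")
    return ModelMetrics(r_squared=r2, adj_r_squared=adj_r2, rse=rse, rmse=rmse, mae=mae,
                        aic=aic, bic=bic, cp=cp, per=per, f_statistic=f_stat,
                        pearson_r=r_pred)


@dataclass(frozen=True)
class SubsetResult:
    subset: tuple[str, ...]
    size: int
    sse: float
    adj_r_squared: float
    cp: float
    bic: float
    best_of_size: bool
    rank_adj_r2: int
    rank_cp: int
    rank_bic: int


def best_subset_search(
    data: pd.DataFrame,
    predictors: tuple[str, ...] = PREDICTORS,
    response: str = "FM",
) -> list[SubsetResult]:
    """Exhaustive main-effects best-subset search.

    Fits all 2^k - 1 non-empty subsets (intercept always included), flags
    the minimum-SSE subset of each size, and ranks all subsets globally by
    Adjusted R^2 (higher better), Mallows Cp and BIC (both lower better).
    Ties break toward the smaller subset, then lexicographic predictor
    order. Cp is referenced to the all-predictors model.
    """
    if not predictors:
        raise SpecificationError("need at least one candidate predictor")
    full_fit = fit_ols(expand_model(tuple(predictors), predictors, response), data)
    entries = []
    for size in range(1, len(predictors) + 1):
        for subset in itertools.combinations(predictors, size):
            fit = fit_ols(expand_model(subset, predictors, response), data)
            m = model_metrics(fit, full_fit)
            entries.append({"subset": subset, "size": size, "sse": fit.sse,
                            "adj_r2": m.adj_r_squared, "cp": m.cp, "bic": m.bic})
    # best of each size by SSE
    best_sse: dict[int, float] = {}
    for e in entries:
        if e["sse"] < best_sse.get(e["size"], math.inf):
            best_sse[e["size"]] = e["sse"]

    def ranks(key, reverse):
        order = sorted(
            range(len(entries)),
            key=lambda i: (
                -entries[i][key] if reverse else entries[i][key],
                entries[i]["size"],
                entries[i]["subset"],
            ),
        )
        r = [0] * len(entries)
        for rank, i in enumerate(order, start=1):
            r[i] = rank
        return r

    r_adj = ranks("adj_r2", reverse=True)
    r_cp = ranks("cp", reverse=False)
    r_bic = ranks("bic", reverse=False)
    results = []
    for i, e in enumerate(entries):
        results.append(SubsetResult(
            subset=e["subset"], size=e["size"], sse=e["sse"],
            adj_r_squared=e["adj_r2"], cp=e["cp"], bic=e["bic"],
            best_of_size=math.isclose(e["sse"], best_sse[e["size"]], rel_tol=0, abs_tol=0.0)
            or e["sse"] == best_sse[e["size"]],
            rank_adj_r2=r_adj[i], rank_cp=r_cp[i], rank_bic=r_bic[i],
        ))
    return results


def subset_table(results: list[SubsetResult]) -> pd.DataFrame:
    """Subset-search results as a DataFrame, one indicator column per
    predictor (the colour-map layout: subsets x criteria)."""
    preds = sorted({v for r in results for v in r.subset})
    rows = []
    for r in results:
        row = {p: int(p in r.subset) for p in preds}
        row.update(size=r.size, adj_r_squared=r.adj_r_squared, cp=r.cp, bic=r.bic,
                   best_of_size=r.best_of_size, rank_adj_r2=r.rank_adj_r2,
                   rank_cp=r.rank_cp, rank_bic=r.rank_bic)
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["size", "rank_adj_r2"]).reset_index(drop=True)


def pearson(x, y) -> tuple[float, float, str]:
    """Pearson r, two-sided p-value, and a significance star label.

    Stars: ``***`` for p <= 0.001, ``**`` for p <= 0.01, ``*`` for p <= 0.05,
    empty otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance input")
    r, p = stats.pearsonr(x, y)
    if p <= 0.001:
        stars = "***"
    elif p <= 0.01:
        stars = "**"
    elif p <= 0.05:
        stars = "*"
    else:
        stars = ""
    return float(r), float(p), stars


def correlation_matrix(data: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise Pearson r with star labels, long format (var1, var2, r, p, stars)."""
    cols = list(columns) if columns is not None else [c for c in data.columns
                                                      if data[c].dtype.kind in "fi"]
    rows = []
    for a, b in itertools.combinations(cols, 2):
        r, p, stars = pearson(data[a], data[b])
        rows.append({"var1": a, "var2": b, "r": r, "p": p, "stars": stars})
    return pd.DataFrame(rows)
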