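"""Empirical-line radiometric calibration, NDVI and zonal statistics.

Band rasters arrive as raw digital numbers (DN). Each band is calibrated to
reflectance independently with the empirical-line method: ordinary least
squares of the panels' nominal reflectance on their mean DN, applied
pixel-wise and clipped to [0, 1]. NDVI = (NIR - RED) / (NIR + RED) is
computed on the calibrated rasters and averaged per polygon (mean of
per-pixel NDVI, not NDVI of band means — the two differ and the former is
used throughout). Zonal means use pixel-centre containment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .fieldsim import BandRaster, TarpPanel

__all__ = ["CalibrationFit", "calibrate_band", "ndvi", "zonal_mean", "ndvi_table"]


class CalibrationError(ValueError):
    """Too few usable panels or a singular panel response."""


class RegistrationError(ValueError):
    """Rasters are not on the same grid."""


class EmptyZoneError(ValueError):
    """No raster pixel centre falls inside the polygon."""


@dataclass(frozen=True)
class CalibrationFit:
    slope: float  # reflectance per DN
    intercept: float  # reflectance
    r_squared: float
    panel_mean_dn: tuple[float, ...]
    panel_reflectance: tuple[float, ...]


def _panel_mean_dn(raster: BandRaster, panel: TarpPanel) -> float | None:
    xs, ys = raster.pixel_centers()
    inside = shapely.contains_xy(panel.polygon, xs.ravel(), ys.ravel())
    if not inside.any():
        return None
    return float(raster.data.ravel()[inside].mean())


def calibrate_band(
    dn_raster: BandRaster, panels: Sequence[TarpPanel]
) -> tuple[BandRaster, CalibrationFit]:
    """Fit reflectance = slope * DN + intercept on the tarp panels and apply it.

    Requires at least two panels with distinct nominal reflectances whose
    footprints intersect the raster. The calibrated raster is clipped to
    [0, 1]. Returns the raster and the fit (slope, intercept, R^2).
    """
    dns, refls = [], []
    for panel in panels:
        mean_dn = _panel_mean_dn(dn_raster, panel)
        if mean_dn is not None:
            dns.append(mean_dn)
            refls.append(panel.reflectance)
    if len(set(refls)) < 2:
        raise CalibrationError(
            f"need >= 2 usable panels with distinct reflectances, got {len(set(refls))}"
        )
    dns_a = np.array(dns)
    refl_a = np.array(refls)
    if np.ptp(dns_a) == 0:
        raise CalibrationError("zero DN variance across panels: singular fit")
    slope, intercept = np.polyfit(dns_a, refl_a, 1)
    pred = slope * dns_a + intercept
    sst = float(np.sum((refl_a - refl_a.mean()) ** 2))
    sse = float(np.sum((refl_a - pred) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    calibrated = np.clip(slope * dn_raster.data + intercept, 0.0, 1.0)
    out = replace(dn_raster, data=calibrated)
    fit = CalibrationFit(
        slope=float(slope), intercept=float(intercept), r_squared=r2,
        panel_mean_dn=tuple(dns), panel_reflectance=tuple(refls),
    )
    return out, fit


def ndvi(nir, red):
    """(NIR - RED) / (NIR + RED) on reflectance scalars, arrays or rasters.

    Pixels where NIR + RED = 0 are masked as NaN. Raster inputs must share
    the grid; the result is a raster labelled ``ndvi``.
    """
    if isinstance(nir, BandRaster) or isinstance(red, BandRaster):
        if not (isinstance(nir, BandRaster) and isinstance(red, BandRaster)):
            raise RegistrationError("mixing raster and non-raster NDVI inputs")
        if not nir.same_grid(red):
            raise RegistrationError("NIR and RED rasters are not co-registered")
        values = _ndvi_values(nir.data, red.data)
        return replace(nir, data=values, band="ndvi", wavelength_nm=None)
    return _ndvi_values(np.asarray(nir, dtype=float), np.asarray(red, dtype=float))


def _ndvi_values(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    total = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(total != 0, (nir - red) / np.where(total == 0, 1.0, total), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def zonal_mean(raster: BandRaster, polygon: Polygon) -> float:
    """Mean over non-missing pixels whose centres fall inside the polygon."""
    xs, ys = raster.pixel_centers()
    inside = shapely.contains_xy(polygon, xs.ravel(), ys.ravel())
    vals = raster.data.ravel()[inside]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise EmptyZoneError("no raster pixel centre falls inside the polygon")
    return float(vals.mean())


def ndvi_table(nir: BandRaster, red: BandRaster, polygons) -> "pd.DataFrame":
    """Per-polygon NDVI means; ``polygons`` maps id -> Polygon."""
    import pandas as pd

    ndvi_raster = ndvi(nir, red)
    rows = [{"row_id": key, "NDVI": zonal_mean(ndvi_raster, poly)} for key, poly in polygons.items()]
    return pd.DataFrame(rows)
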