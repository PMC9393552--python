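"""Synthetic row-plot field trial generator.

Emulates a perennial-ryegrass breeding trial: 160 plots laid out in four
primary columns of 40, each plot 1.8 x 4 m with three rows of 16 plants
(0.25 m plant spacing, 0.6 m row spacing), together with the raw sensor
streams a ground/air phenotyping campaign would record over it:

* a 2D line-scanning LiDAR (55-123 deg at 1 deg, 500 Hz, 1.127 m above
  ground) on a vehicle tracked by RTK GPS at 5 Hz,
* a five-band multispectral camera (~2 cm ground sample distance) with a
  five-panel calibration tarp (3/6/11/22/33 % reflectance),
* ultrasonic sonar height sensors sampling at 10 Hz, two per row,
* destructive fresh-mass (FM) harvest per row, generated from the mass
  premise FM = rho * volume * density + noise.

Canopies are sums of per-plant parabolic bumps, which makes the true canopy
volume (total and above any cutting datum) available in closed form, so the
extraction pipeline can be validated against analytic ground truth.

All randomness flows from ``SimulationConfig.seed``; every stream is
bit-reproducible for a fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon, box

__all__ = [
    "SimulationConfig",
    "ScannerConfig",
    "SonarConfig",
    "MultispectralConfig",
    "TarpPanel",
    "TrialLayout",
    "CanopyTruth",
    "LidarFrame",
    "GpsFix",
    "SonarSample",
    "BandRaster",
    "SEASONS",
    "generate_layout",
    "simulate_canopies",
    "simulate_lidar_survey",
    "simulate_multispectral",
    "simulate_sonar",
    "simulate_phenotype_table",
    "default_tarp",
    "noise_sd_for_r2",
]


# Season multipliers on (canopy height, canopy density). The trial spans the
# vegetative stages (winter, late spring) and the reproductive stage (summer),
# where part of each plant bolts into tall sparse seed heads.
SEASONS = {
    "winter": (0.6, 0.85),
    "late_spring": (1.0, 1.0),
    "summer": (1.25, 0.9),
}

#: Plots removed from the late-spring dataset: a faulty mower cutting plate
#: made the fresh-mass cuts of the first 80 plots unusable.
FAULTY_MOWER_PLOTS = tuple(range(1, 81))


@dataclass(frozen=True)
class SimulationConfig:
    """Trial-level configuration; defaults reproduce the reference layout."""

    seed: int = 0
    n_plots: int = 160
    rows_per_plot: int = 3
    plants_per_row: int = 16
    plot_dims: tuple[float, float] = (1.8, 4.0)  # (width across rows, length) m
    row_spacing: float = 0.6  # m between row centrelines
    plant_spacing: float = 0.25  # m between plants along the row
    plots_per_column: int = 40
    column_gap: float = 1.0  # m between primary columns of plots
    plot_gap: float = 0.5  # m between consecutive plots in a column
    season: str = "summer"
    canopy_height_range: tuple[float, float] = (0.15, 0.45)
    canopy_density_range: tuple[float, float] = (0.3, 0.9)
    plant_radius: float = 0.12  # m, radial extent of one plant's bump
    biomass_coefficient: float = 3000.0  # rho, g per m^3 per density unit
    noise_sd: float = 10.0  # g, additive FM measurement noise
    reproductive_fraction: float = 0.3  # summer only: fraction of plants bolting

    def __post_init__(self) -> None:
        for name in ("n_plots", "rows_per_plot", "plants_per_row"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("row_spacing", "plant_spacing", "plant_radius",
                     "column_gap", "plot_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.plot_dims) <= 0:
            raise ValueError(f"plot_dims must be positive, got {self.plot_dims}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.reproductive_fraction <= 1.0:
            raise ValueError("reproductive_fraction must lie in [0, 1]")
        if self.season not in SEASONS:
            raise ValueError(f"unknown season {self.season!r}; expected one of {sorted(SEASONS)}")


@dataclass(frozen=True)
class ScannerConfig:
    """2D LiDAR + RTK GPS survey geometry."""

    angle_min: float = 55.0  # deg, beam elevation from horizontal
    angle_max: float = 123.0
    angle_step: float = 1.0
    scan_rate: float = 500.0  # Hz
    sensor_height: float = 1.127  # m above ground
    gps_rate: float = 5.0  # Hz
    drive_speed: float = 1.2  # m/s
    range_noise_sd: float = 0.003  # m

    @property
    def beam_angles(self) -> np.ndarray:
        n = int(round((self.angle_max - self.angle_min) / self.angle_step)) + 1
        return self.angle_min + self.angle_step * np.arange(n)


@dataclass(frozen=True)
class SonarConfig:
    mount_height: float = 0.60  # m
    sample_rate: float = 10.0  # Hz per sensor
    drive_speed: float = 1.4  # m/s
    noise_sd: float = 0.005  # m
    sensor_offset: float = 0.10  # m, lateral offset of the two per-row sensors


@dataclass(frozen=True)
class MultispectralConfig:
    gsd: float = 0.0208  # m/pixel ground sample distance
    gain: float = 1000.0  # DN per reflectance unit
    offset: float = 50.0  # DN
    dn_noise_sd: float = 0.0  # DN
    soil_reflectance: dict | None = None  # per-band; defaults below

    def soil(self) -> dict[str, float]:
        if self.soil_reflectance is not None:
            return dict(self.soil_reflectance)
        # flat dry-soil spectrum: NDVI of bare soil ~ 0
        return {"blue": 0.10, "green": 0.14, "red": 0.18, "red_edge": 0.19, "nir": 0.20}


# Canonical band set of the five-band camera, with wavelength ranges in nm.
BANDS: dict[str, tuple[float, float]] = {
    "blue": (465.0, 485.0),
    "green": (550.0, 570.0),
    "red": (663.0, 673.0),
    "red_edge": (712.0, 722.0),
    "nir": (820.0, 860.0),
}

# Dense green-leaf reflectance per band; vegetated pixels interpolate between
# soil and this endmember with canopy density as the mixing weight.
_VEG_REFLECTANCE = {"blue": 0.04, "green": 0.10, "red": 0.05, "red_edge": 0.35, "nir": 0.55}


@dataclass(frozen=True)
class TarpPanel:
    """One panel of the radiometric calibration tarp."""

    reflectance: float  # nominal fraction, identical in every band
    polygon: Polygon


@dataclass
class TrialLayout:
    """Georeferenced plot and row polygons in a local planar metre frame."""

    plots: list[tuple[int, Polygon]]
    rows: list[tuple[int, int, Polygon]]  # (row_id, plot_id, polygon)
    crs_note: str = "local planar metric frame, origin at trial south-west corner"

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def bounds(self) -> tuple[float, float, float, float]:
        xs0, ys0, xs1, ys1 = zip(*(p.bounds for _, p in self.plots))
        return min(xs0), min(ys0), max(xs1), max(ys1)

    def row_polygon(self, row_id: int) -> Polygon:
        for rid, _, poly in self.rows:
            if rid == row_id:
                return poly
        raise KeyError(f"unknown row_id {row_id}")


@dataclass
class RowCanopy:
    """Analytic canopy of one row: a sum of parabolic plant bumps.

    Each plant contributes h_i * max(0, 1 - (d/r)^2) where d is the planar
    distance from its centre. Total volume and volume above a cutting datum
    are closed-form, so truth never depends on any discretisation.
    """

    row_id: int
    plot_id: int
    centers: np.ndarray  # (k, 2) plant centres
    heights: np.ndarray  # (k,) bump apex heights, m
    radii: np.ndarray  # (k,) bump radii, m
    density: float  # 0-1 volumetric density of this row's canopy

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Canopy height at planar points; zero outside every bump."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for (cx, cy), h, r in zip(self.centers, self.heights, self.radii):
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            out += h * np.clip(1.0 - d2 / (r * r), 0.0, None)
        return out

    def volume(self) -> float:
        """Exact integral of the surface: sum of pi*r^2*h/2 per bump."""
        return float(np.sum(math.pi * self.radii**2 * self.heights / 2.0))

    def volume_above(self, datum: float) -> float:
        """Exact canopy volume above a horizontal datum (m)."""
        h = self.heights
        r = self.radii
        mask = h > datum
        if not mask.any():
            return 0.0
        return float(np.sum(math.pi * r[mask] ** 2 * (h[mask] - datum) ** 2 / (2.0 * h[mask])))


@dataclass
class CanopyTruth:
    """Ground truth for one simulated season."""

    config: SimulationConfig
    layout: TrialLayout
    rows: list[RowCanopy]
    true_FM: dict[int, float]  # row_id -> g

    def row(self, row_id: int) -> RowCanopy:
        for rc in self.rows:
            if rc.row_id == row_id:
                return rc
        raise KeyError(f"unknown row_id {row_id}")

    def surface(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Whole-trial canopy height field (bumps of all rows summed)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        for rc in self.rows:
            out += rc.surface(x, y)
        return out

    def _plant_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        centers = np.concatenate([rc.centers for rc in self.rows])
        heights = np.concatenate([rc.heights for rc in self.rows])
        radii = np.concatenate([rc.radii for rc in self.rows])
        order = np.argsort(centers[:, 1], kind="stable")
        return centers[order], heights[order], radii[order]

    def truth_table(self):
        """Per-row DataFrame of true volume, density and FM."""
        import pandas as pd

        rows = []
        for rc in self.rows:
            rows.append(
                {
                    "row_id": rc.row_id,
                    "plot_id": rc.plot_id,
                    "true_volume": rc.volume(),
                    "true_density": rc.density,
                    "true_FM": self.true_FM[rc.row_id],
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class LidarFrame:
    timestamp: float
    ranges: np.ndarray  # one distance (m) per beam angle; NaN = no return


@dataclass(frozen=True)
class GpsFix:
    timestamp: float
    easting: float
    northing: float
    heading: float | None = None  # deg, optional


@dataclass(frozen=True)
class SonarSample:
    timestamp: float
    distance: float  # m from sensor to target
    sensor: int  # 1-6
    x: float
    y: float


@dataclass
class BandRaster:
    """Single-band raster on a north-up local metric grid.

    ``data[i, j]`` covers the square whose centre is
    ``(x_origin + (j + 0.5) * pixel_size, y_origin + (i + 0.5) * pixel_size)``,
    i.e. row index increases with northing.
    """

    data: np.ndarray
    x_origin: float
    y_origin: float
    pixel_size: float
    band: str = ""
    wavelength_nm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.data.shape
        xs = self.x_origin + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.y_origin + (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def same_grid(self, other: "BandRaster") -> bool:
        return (
            self.data.shape == other.data.shape
            and math.isclose(self.x_origin, other.x_origin, abs_tol=1e-9)
            and math.isclose(self.y_origin, other.y_origin, abs_tol=1e-9)
            and math.isclose(self.pixel_size, other.pixel_size, rel_tol=1e-12)
        )


# ---------------------------------------------------------------------------
# layout


def generate_layout(config: SimulationConfig) -> TrialLayout:
    """Lay out the trial grid deterministically in local planar metres.

    Plots fill columns of ``plots_per_column`` bottom-to-top, columns left to
    right. Row polygons are the three 0.6 m strips of a plot, inset 1 cm per
    side so neighbouring rows are strictly disjoint. Identifiers are 1-based:
    plot p has rows 3p-2, 3p-1, 3p.
    """
    width, length = config.plot_dims
    n_cols = math.ceil(config.n_plots / config.plots_per_column)
    plots: list[tuple[int, Polygon]] = []
    rows: list[tuple[int, int, Polygon]] = []
    row_inset = 0.01
    row_id = 1
    for plot_id in range(1, config.n_plots + 1):
        col = (plot_id - 1) // config.plots_per_column
        idx = (plot_id - 1) % config.plots_per_column
        x0 = col * (width + config.column_gap)
        y0 = idx * (length + config.plot_gap)
        plots.append((plot_id, box(x0, y0, x0 + width, y0 + length)))
        for k in range(config.rows_per_plot):
            cx = x0 + (k + 0.5) * config.row_spacing
            half = config.row_spacing / 2.0 - row_inset
            rows.append((row_id, plot_id, box(cx - half, y0, cx + half, y0 + length)))
            row_id += 1
    note = (
        f"local planar metric frame, origin at trial south-west corner; "
        f"{n_cols} columns x {config.plots_per_column} plots"
    )
    return TrialLayout(plots=plots, rows=rows, crs_note=note)


# ---------------------------------------------------------------------------
# canopy truth


def simulate_canopies(layout: TrialLayout, config: SimulationConfig) -> CanopyTruth:
    """Draw per-plant canopies and per-row fresh mass for one season.

    Plant apex heights are uniform in the season-scaled height range; each
    row has one density drawn from the season-scaled density range. In
    summer a ``reproductive_fraction`` of plants carries an extra tall,
    narrow seed-head spike. FM = rho * volume * density + N(0, noise_sd),
    truncated at zero.
    """
    rng = np.random.default_rng(config.seed)
    h_mult, d_mult = SEASONS[config.season]
    h_lo, h_hi = (h_mult * v for v in config.canopy_height_range)
    d_lo, d_hi = (min(1.0, d_mult * v) for v in config.canopy_density_range)

    row_canopies: list[RowCanopy] = []
    for row_id, plot_id, poly in layout.rows:
        x0, y0, x1, y1 = poly.bounds
        cx = (x0 + x1) / 2.0
        k = config.plants_per_row
        # plants centred along the row, one per plant_spacing slot
        offset = (y1 - y0 - (k - 1) * config.plant_spacing) / 2.0
        ys = y0 + offset + config.plant_spacing * np.arange(k)
        centers = np.column_stack([np.full(k, cx), ys])
        heights = rng.uniform(h_lo, h_hi, size=k)
        radii = np.full(k, config.plant_radius)
        density = float(rng.uniform(d_lo, d_hi))
        if config.season == "summer" and config.reproductive_fraction > 0:
            bolting = rng.random(k) < config.reproductive_fraction
            if bolting.any():
                spikes = centers[bolting] + rng.normal(0.0, 0.01, size=(bolting.sum(), 2))
                centers = np.vstack([centers, spikes])
                heights = np.concatenate([heights, heights[bolting] * 1.8])
                radii = np.concatenate([radii, np.full(bolting.sum(), 0.03)])
        row_canopies.append(
            RowCanopy(row_id=row_id, plot_id=plot_id, centers=centers,
                      heights=heights, radii=radii, density=density)
        )

    true_fm: dict[int, float] = {}
    for rc in row_canopies:
        fm = config.biomass_coefficient * rc.volume() * rc.density
        if config.noise_sd > 0:
            fm += rng.normal(0.0, config.noise_sd)
        true_fm[rc.row_id] = max(0.0, fm)
    return CanopyTruth(config=config, layout=layout, rows=row_canopies, true_FM=true_fm)


# ---------------------------------------------------------------------------
# LiDAR survey


def _first_return(
    profile_x: np.ndarray,
    profile_h: np.ndarray,
    angles_rad: np.ndarray,
    sensor_x: float,
    sensor_height: float,
    step: float = 0.002,
) -> np.ndarray:
    """Range to the first surface hit per beam within one scan plane.

    The canopy along the scan line is a 1-D height profile sampled on a
    uniform x grid; each beam marches from the sensor until the ray drops
    below the profile (canopy hit) or reaches z = 0 (ground hit).
    """
    sin_t = np.sin(angles_rad)
    cos_t = np.cos(angles_rad)
    s_ground = sensor_height / sin_t  # all beams point downward (55-123 deg)
    n_steps = int(np.ceil(s_ground.max() / step)) + 1
    s = step * np.arange(1, n_steps + 1)  # (n_steps,)
    # ray positions: lateral offset +x for theta < 90 deg, -x beyond nadir
    xs = sensor_x + np.outer(cos_t, s)  # (beams, n_steps)
    zs = sensor_height - np.outer(sin_t, s)
    dx = profile_x[1] - profile_x[0]
    idx = np.clip(np.round((xs - profile_x[0]) / dx).astype(int), 0, len(profile_x) - 1)
    canopy = profile_h[idx]
    hit = zs <= canopy
    first = np.argmax(hit, axis=1)
    any_hit = hit.any(axis=1)
    ranges = np.where(any_hit, s[first], s_ground)
    return np.minimum(ranges, s_ground)


def simulate_lidar_survey(
    truth: CanopyTruth,
    scanner: ScannerConfig = ScannerConfig(),
    seed: int = 0,
    row_ids: Sequence[int] | None = None,
) -> tuple[list[LidarFrame], list[GpsFix]]:
    """Drive the scanner along each row and record frames plus a GPS track.

    One straight pass per row, along +y over the row centreline at
    ``drive_speed``; the wide angular fan means each pass also sees the
    neighbouring row, mimicking the two-rows-per-pass field procedure.
    Passes are concatenated on a common clock (one track, monotone
    timestamps). Ranges get additive Gaussian noise.

    Returns ``ceil(duration * scan_rate)`` frames and
    ``ceil(duration * gps_rate)`` fixes per pass.
    """
    rng = np.random.default_rng(seed)
    angles = np.deg2rad(scanner.beam_angles)
    centers, heights, radii = truth._plant_arrays()
    plant_y = centers[:, 1]
    r_max = float(radii.max()) if len(radii) else 0.1

    frames: list[LidarFrame] = []
    fixes: list[GpsFix] = []
    t0 = 0.0
    wanted = set(row_ids) if row_ids is not None else None
    reach = scanner.sensor_height / math.tan(math.radians(scanner.angle_min)) + 0.1
    for row_id, _plot_id, poly in truth.layout.rows:
        if wanted is not None and row_id not in wanted:
            continue
        x0, y0, x1, y1 = poly.bounds
        cx = (x0 + x1) / 2.0
        duration = (y1 - y0) / scanner.drive_speed
        n_frames = math.ceil(duration * scanner.scan_rate)
        n_fixes = math.ceil(duration * scanner.gps_rate)
        profile_x = np.arange(cx - reach, cx + reach, 0.002)
        for i in range(n_frames):
            t = i / scanner.scan_rate
            y = y0 + scanner.drive_speed * t
            near = np.abs(plant_y - y) <= r_max
            profile_h = np.zeros_like(profile_x)
            if near.any():
                c = centers[near]
                h = heights[near]
                r = radii[near]
                d2 = (profile_x[:, None] - c[:, 0]) ** 2 + (y - c[:, 1]) ** 2
                profile_h = np.sum(h * np.clip(1.0 - d2 / r**2, 0.0, None), axis=1)
            ranges = _first_return(profile_x, profile_h, angles, cx, scanner.sensor_height)
            if scanner.range_noise_sd > 0:
                ranges = ranges + rng.normal(0.0, scanner.range_noise_sd, size=ranges.shape)
            frames.append(LidarFrame(timestamp=t0 + t, ranges=ranges))
        for i in range(n_fixes):
            t = i / scanner.gps_rate
            fixes.append(GpsFix(timestamp=t0 + t, easting=cx,
                                northing=y0 + scanner.drive_speed * t, heading=90.0))
        t0 += duration + 1.0  # idle gap between passes
    return frames, fixes


# ---------------------------------------------------------------------------
# multispectral survey


def default_tarp(layout: TrialLayout, panel_size: float = 0.5) -> list[TarpPanel]:
    """Five-panel calibration tarp placed just south of the trial."""
    x0, y0, _, _ = layout.bounds()
    panels = []
    for i, refl in enumerate((0.03, 0.06, 0.11, 0.22, 0.33)):
        px = x0 + i * (panel_size + 0.1)
        py = y0 - panel_size - 0.3
        panels.append(TarpPanel(reflectance=refl, polygon=box(px, py, px + panel_size, py + panel_size)))
    return panels


def simulate_multispectral(
    truth: CanopyTruth,
    layout: TrialLayout,
    tarp: Sequence[TarpPanel] | None = None,
    seed: int = 0,
    camera: MultispectralConfig = MultispectralConfig(),
) -> dict[str, BandRaster]:
    """Render the five digital-number band rasters over the trial and tarp.

    Scene reflectance per pixel is a soil/vegetation linear mixture: where
    the canopy surface is above zero, the vegetation endmember is weighted
    by the row's density (sparse canopies keep a soil signal); tarp panels
    are painted flat at their nominal reflectance in every band.
    DN = gain * reflectance + offset + N(0, dn_noise_sd).
    """
    if tarp is None:
        tarp = default_tarp(layout)
    rng = np.random.default_rng(seed)
    soil = camera.soil()
    x0, y0, x1, y1 = layout.bounds()
    for panel in tarp:
        px0, py0, px1, py1 = panel.polygon.bounds
        x0, y0 = min(x0, px0), min(y0, py0)
        x1, y1 = max(x1, px1), max(y1, py1)
    pad = camera.gsd
    x0 -= pad
    y0 -= pad
    nx = int(math.ceil((x1 - x0) / camera.gsd)) + 1
    ny = int(math.ceil((y1 - y0) / camera.gsd)) + 1

    # vegetation weight map: canopy presence scaled by row density
    veg = np.zeros((ny, nx))
    xs = x0 + (np.arange(nx) + 0.5) * camera.gsd
    ys = y0 + (np.arange(ny) + 0.5) * camera.gsd
    for rc in truth.rows:
        rx0 = rc.centers[:, 0].min() - rc.radii.max()
        rx1 = rc.centers[:, 0].max() + rc.radii.max()
        ry0 = rc.centers[:, 1].min() - rc.radii.max()
        ry1 = rc.centers[:, 1].max() + rc.radii.max()
        j0, j1 = np.searchsorted(xs, [rx0, rx1])
        i0, i1 = np.searchsorted(ys, [ry0, ry1])
        if j0 >= j1 or i0 >= i1:
            continue
        gx, gy = np.meshgrid(xs[j0:j1], ys[i0:i1])
        h = rc.surface(gx, gy)
        veg[i0:i1, j0:j1] = np.maximum(veg[i0:i1, j0:j1], rc.density * (h > 0.0))

    rasters: dict[str, BandRaster] = {}
    for band, wl in BANDS.items():
        refl = soil[band] * (1.0 - veg) + _VEG_REFLECTANCE[band] * veg
        for panel in tarp:
            px0, py0, px1, py1 = panel.polygon.bounds
            j0, j1 = np.searchsorted(xs, [px0, px1])
            i0, i1 = np.searchsorted(ys, [py0, py1])
            refl[i0:i1, j0:j1] = panel.reflectance
        dn = camera.gain * refl + camera.offset
        if camera.dn_noise_sd > 0:
            dn = dn + rng.normal(0.0, camera.dn_noise_sd, size=dn.shape)
        rasters[band] = BandRaster(
            data=dn, x_origin=x0, y_origin=y0, pixel_size=camera.gsd,
            band=band, wavelength_nm=wl,
        )
    return rasters


# ---------------------------------------------------------------------------
# sonar survey


def simulate_sonar(
    truth: CanopyTruth,
    layout: TrialLayout,
    seed: int = 0,
    sonar: SonarConfig = SonarConfig(),
    row_ids: Sequence[int] | None = None,
) -> list[SonarSample]:
    """Ultrasonic distance traces: two sensors per row, 10 Hz, ~1.4 m/s.

    Each sensor points straight down from ``mount_height`` and reads the
    distance to the canopy surface (or to the ground on bare soil), with
    additive Gaussian noise. With two sensors the pooled along-track sample
    spacing is half of drive_speed / sample_rate.
    """
    rng = np.random.default_rng(seed)
    samples: list[SonarSample] = []
    t0 = 0.0
    wanted = set(row_ids) if row_ids is not None else None
    for k, (row_id, _plot_id, poly) in enumerate(layout.rows):
        if wanted is not None and row_id not in wanted:
            continue
        x0, y0, x1, y1 = poly.bounds
        cx = (x0 + x1) / 2.0
        duration = (y1 - y0) / sonar.drive_speed
        n = math.ceil(duration * sonar.sample_rate)
        sensor_pair = (2 * (k % 3) + 1, 2 * (k % 3) + 2)
        for s_idx, x_off in zip(sensor_pair, (-sonar.sensor_offset, sonar.sensor_offset)):
            for i in range(n):
                t = i / sonar.sample_rate
                y = y0 + sonar.drive_speed * t
                h = float(truth.surface(np.array(cx + x_off), np.array(y)))
                dist = sonar.mount_height - min(h, sonar.mount_height)
                if sonar.noise_sd > 0:
                    dist += float(rng.normal(0.0, sonar.noise_sd))
                samples.append(SonarSample(timestamp=t0 + t, distance=max(dist, 1e-6),
                                           sensor=s_idx, x=cx + x_off, y=y))
        t0 += duration + 1.0
    return samples


def truth_metric_tables(
    truth: CanopyTruth,
    cutoff: float = 0.05,
    camera: MultispectralConfig = MultispectralConfig(),
    sonar: SonarConfig = SonarConfig(),
):
    """Per-row metric tables computed analytically from the canopy truth.

    The sensor-free fast path: LV is the exact bump volume above the
    cutting datum, LV_Den the canopy cover fraction above the datum,
    LV_PH the mean surface height over the above-datum footprint, Sonar_PH
    the mean clipped surface height along the two sonar lines, and NDVI the
    cover-weighted mixture NDVI the multispectral renderer would produce.
    Useful for dataset-scale studies where rendering raw streams adds only
    runtime; agreement with the rendered path is bounded by sampling
    resolution, not by model differences.
    """
    import pandas as pd

    soil = camera.soil()
    ndvi_soil = (soil["nir"] - soil["red"]) / (soil["nir"] + soil["red"])
    lidar_rows, ndvi_rows, sonar_rows = [], [], []
    for rc in truth.rows:
        poly = truth.layout.row_polygon(rc.row_id)
        area = poly.area
        h, r = rc.heights, rc.radii
        above = h > cutoff
        area_above = float(np.sum(math.pi * r[above] ** 2 * (1.0 - cutoff / h[above])))
        lv = rc.volume_above(cutoff)
        lv_ph = cutoff + lv / area_above if area_above > 0 else float("nan")
        lv_den = min(1.0, area_above / area)
        lidar_rows.append({"row_id": rc.row_id, "LV": lv, "LV_Den": lv_den, "LV_PH": lv_ph})

        cover = min(1.0, float(np.sum(math.pi * r**2)) / area)
        d = rc.density
        nir_v = soil["nir"] * (1 - d) + _VEG_REFLECTANCE["nir"] * d
        red_v = soil["red"] * (1 - d) + _VEG_REFLECTANCE["red"] * d
        ndvi_veg = (nir_v - red_v) / (nir_v + red_v)
        ndvi_rows.append({"row_id": rc.row_id,
                          "NDVI": cover * ndvi_veg + (1 - cover) * ndvi_soil})

        x0, y0, x1, y1 = poly.bounds
        cx = (x0 + x1) / 2.0
        ys = np.arange(y0, y1, 0.01)
        heights = []
        for x_off in (-sonar.sensor_offset, sonar.sensor_offset):
            surf = rc.surface(np.full_like(ys, cx + x_off), ys)
            heights.append(np.clip(surf, 0.0, sonar.mount_height))
        sonar_rows.append({"row_id": rc.row_id, "Sonar_PH": float(np.mean(heights))})
    return {
        "lidar": pd.DataFrame(lidar_rows),
        "ndvi": pd.DataFrame(ndvi_rows),
        "sonar": pd.DataFrame(sonar_rows),
    }


def fm_tables(truth: CanopyTruth):
    """Row- and plot-level FM tables from the truth.

    Winter harvests weigh whole plots only, so the row table is withheld for
    a winter truth (plot FM is still the sum of the per-row cuts).
    """
    import pandas as pd

    tt = truth.truth_table()
    row_fm = tt[["row_id", "plot_id"]].copy()
    row_fm["FM"] = tt["true_FM"]
    plot_fm = row_fm.groupby("plot_id", as_index=False)["FM"].sum()
    if truth.config.season == "winter":
        return None, plot_fm
    return row_fm[["row_id", "plot_id", "FM"]], plot_fm


# ---------------------------------------------------------------------------
# direct phenotype-table simulation (no sensor rendering)


def noise_sd_for_r2(signal: np.ndarray, r2: float) -> float:
    """Noise SD that makes a linear fit of signal+noise attain R^2 ~ r2."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must lie in (0, 1)")
    return float(np.std(signal) * math.sqrt((1.0 - r2) / r2))


def simulate_phenotype_table(
    n_rows: int = 480,
    seed: int = 0,
    season: str = "summer",
    rho: float = 3000.0,
    target_r2: float | None = None,
    noise_sd: float | None = None,
    volume_range: tuple[float, float] = (0.02, 0.30),
    density_range: tuple[float, float] = (0.3, 0.9),
):
    """Draw a per-row phenotype table straight from the generative model.

    FM = rho * volume * density + noise; the five digital phenotypes are
    deterministic transforms of (volume, density) plus small sensor noise.
    This is the fast path for model-selection and cross-validation studies
    where rendering sensor streams adds nothing. If ``target_r2`` is given,
    the FM noise SD is set so that the volume-density product explains that
    fraction of FM variance in-sample.
    """
    import pandas as pd

    if n_rows % 3 != 0:
        raise ValueError("n_rows must be a multiple of 3 (three rows per plot)")
    rng = np.random.default_rng(seed)
    h_mult, d_mult = SEASONS[season]
    vol = rng.uniform(*volume_range, size=n_rows) * h_mult
    den = np.clip(rng.uniform(*density_range, size=n_rows) * d_mult, 0.0, 1.0)
    signal = rho * vol * den
    if noise_sd is None:
        noise_sd = noise_sd_for_r2(signal, target_r2) if target_r2 is not None else 0.0
    fm = np.clip(signal + rng.normal(0.0, noise_sd, size=n_rows), 0.0, None)

    footprint = 0.6 * 4.0  # row polygon area, m^2
    lv_ph = vol / footprint / 0.4 + rng.normal(0.0, 0.005, size=n_rows)
    sonar_ph = lv_ph * rng.normal(1.0, 0.08, size=n_rows)
    # NDVI saturates with green density; reproductive material dilutes it
    ndvi = 0.15 + 0.75 * (1.0 - np.exp(-3.0 * den * (0.5 + vol / vol.max())))
    ndvi = np.clip(ndvi + rng.normal(0.0, 0.02, size=n_rows), -1.0, 1.0)
    row_id = np.arange(1, n_rows + 1)
    return pd.DataFrame(
        {
            "row_id": row_id,
            "plot_id": (row_id - 1) // 3 + 1,
            "LV": vol,
            "LV_Den": den,
            "LV_PH": np.clip(lv_ph, 0.0, None),
            "Sonar_PH": np.clip(sonar_ph, 0.0, None),
            "NDVI": ndvi,
            "FM": fm,
        }
    )
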