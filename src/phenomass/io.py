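"""File formats: GeoJSON polygons, CSV sensor traces, TIFF rasters.

Layouts are exchanged as GeoJSON FeatureCollections of Polygons carrying
``plot_id`` (and ``row_id`` for rows) properties in a shared planar metric
frame. Sensor streams are plain CSV: LiDAR frames as timestamp plus one
range column per beam angle, GPS fixes as timestamp/easting/northing
(/heading), sonar as timestamp/distance/sensor/x/y. Rasters are single-band
TIFFs with the geotransform (x_origin, y_origin, pixel_size) and band label
stored as JSON in the ImageDescription tag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .fieldsim import BandRaster, GpsFix, LidarFrame, SonarSample, TarpPanel, TrialLayout

__all__ = [
    "write_layout_geojson", "read_layout_geojson",
    "write_tarp_geojson", "read_tarp_geojson",
    "write_frames_csv", "read_frames_csv",
    "write_track_csv", "read_track_csv",
    "write_sonar_csv", "read_sonar_csv",
    "write_raster_tiff", "read_raster_tiff",
    "read_xyz_pointcloud",
]


def write_layout_geojson(layout: TrialLayout, plots_path, rows_path) -> None:
    plot_features = [
        {"type": "Feature", "geometry": mapping(poly), "properties": {"plot_id": pid}}
        for pid, poly in layout.plots
    ]
    row_features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"row_id": rid, "plot_id": pid},
        }
        for rid, pid, poly in layout.rows
    ]
    for path, features in ((plots_path, plot_features), (rows_path, row_features)):
        doc = {"type": "FeatureCollection", "crs_note": layout.crs_note, "features": features}
        Path(path).write_text(json.dumps(doc))


def read_layout_geojson(plots_path, rows_path) -> TrialLayout:
    plots_doc = json.loads(Path(plots_path).read_text())
    rows_doc = json.loads(Path(rows_path).read_text())
    plots = [
        (f["properties"]["plot_id"], shape(f["geometry"])) for f in plots_doc["features"]
    ]
    rows = [
        (f["properties"]["row_id"], f["properties"]["plot_id"], shape(f["geometry"]))
        for f in rows_doc["features"]
    ]
    return TrialLayout(plots=plots, rows=rows,
                       crs_note=plots_doc.get("crs_note", "unknown planar frame"))


def read_polygons_geojson(path) -> dict:
    """Generic polygon reader: id property (row_id or plot_id) -> Polygon."""
    doc = json.loads(Path(path).read_text())
    out = {}
    for f in doc["features"]:
        props = f.get("properties", {})
        key = props.get("row_id", props.get("plot_id"))
        out[key] = shape(f["geometry"])
    return out


def write_tarp_geojson(panels, path) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(p.polygon),
         "properties": {"reflectance": p.reflectance}}
        for p in panels
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_tarp_geojson(path) -> list[TarpPanel]:
    doc = json.loads(Path(path).read_text())
    return [
        TarpPanel(reflectance=f["properties"]["reflectance"], polygon=shape(f["geometry"]))
        for f in doc["features"]
    ]


def write_frames_csv(frames: list[LidarFrame], angles: np.ndarray, path) -> None:
    cols = {"timestamp": [f.timestamp for f in frames]}
    ranges = np.array([f.ranges for f in frames]) if frames else np.empty((0, len(angles)))
    for j, a in enumerate(angles):
        cols[f"range_{a:g}"] = ranges[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_frames_csv(path) -> tuple[list[LidarFrame], np.ndarray]:
    df = pd.read_csv(path)
    range_cols = [c for c in df.columns if c.startswith("range_")]
    angles = np.array([float(c.split("_", 1)[1]) for c in range_cols])
    frames = [
        LidarFrame(timestamp=row.timestamp, ranges=np.array([getattr(row, c) for c in range_cols]))
        for row in df.itertuples()
    ]
    return frames, angles


def write_track_csv(track: list[GpsFix], path) -> None:
    pd.DataFrame(
        {
            "timestamp": [f.timestamp for f in track],
            "easting": [f.easting for f in track],
            "northing": [f.northing for f in track],
            "heading": [f.heading for f in track],
        }
    ).to_csv(path, index=False)


def read_track_csv(path) -> list[GpsFix]:
    df = pd.read_csv(path)
    has_heading = "heading" in df.columns and df["heading"].notna().any()
    return [
        GpsFix(
            timestamp=r.timestamp, easting=r.easting, northing=r.northing,
            heading=(r.heading if has_heading and np.isfinite(r.heading) else None),
        )
        for r in df.itertuples()
    ]


def write_sonar_csv(samples: list[SonarSample], path) -> None:
    pd.DataFrame(
        {
            "timestamp": [s.timestamp for s in samples],
            "distance": [s.distance for s in samples],
            "sensor": [s.sensor for s in samples],
            "x": [s.x for s in samples],
            "y": [s.y for s in samples],
        }
    ).to_csv(path, index=False)


def read_sonar_csv(path) -> list[SonarSample]:
    df = pd.read_csv(path)
    return [
        SonarSample(timestamp=r.timestamp, distance=r.distance, sensor=int(r.sensor),
                    x=r.x, y=r.y)
        for r in df.itertuples()
    ]


def write_raster_tiff(raster: BandRaster, path) -> None:
    import tifffile

    meta = {
        "x_origin": raster.x_origin,
        "y_origin": raster.y_origin,
        "pixel_size": raster.pixel_size,
        "band": raster.band,
        "wavelength_nm": raster.wavelength_nm,
    }
    tifffile.imwrite(path, raster.data.astype(np.float32), description=json.dumps(meta))


def read_raster_tiff(path) -> BandRaster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        meta = json.loads(page.tags["ImageDescription"].value)
    wl = meta.get("wavelength_nm")
    return BandRaster(
        data=data, x_origin=meta["x_origin"], y_origin=meta["y_origin"],
        pixel_size=meta["pixel_size"], band=meta.get("band", ""),
        wavelength_nm=tuple(wl) if wl else None,
    )


def read_xyz_pointcloud(path):
    """Whitespace- or comma-separated x y z text file -> PointCloud."""
    from .lidar_metrics import PointCloud

    try:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] < 3:
        raise ValueError("XYZ file needs at least three columns")
    pts = arr[:, :3]
    finite = np.isfinite(pts).all(axis=1)
    return PointCloud(points=pts[finite], frame_index=np.zeros(finite.sum(), dtype=int))
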