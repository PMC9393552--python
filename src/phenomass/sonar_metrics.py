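"""Ultrasonic sonar plant height (Sonar_PH) per polygon.

Each downward-looking sonar reports the distance from its mount to the first
target below (canopy, or ground on bare soil). Height = mount_height -
distance, clipped at zero; Sonar_PH for a polygon is the mean (optionally
median) height over all in-polygon samples, pooling the two sensors that
cover a row.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .fieldsim import SonarSample

__all__ = ["extract_sonar_height", "sonar_table"]

log = logging.getLogger(__name__)


class EmptyTraceError(ValueError):
    """No sonar sample is positioned inside the polygon."""


def extract_sonar_height(
    samples: Sequence[SonarSample],
    polygon: Polygon,
    mount_height: float,
    stat: str = "mean",
    noise_tolerance: float = 0.05,
) -> float:
    """Sonar plant height (m) for one polygon.

    Distances exceeding ``mount_height`` by more than ``noise_tolerance``
    (spurious long echoes) are logged and clipped to the mount height, i.e.
    contribute zero height.
    """
    if mount_height <= 0:
        raise ValueError("mount_height must be positive")
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    if len(samples) == 0:
        raise EmptyTraceError("no sonar samples supplied")
    xs = np.array([s.x for s in samples])
    ys = np.array([s.y for s in samples])
    dist = np.array([s.distance for s in samples])
    inside = shapely.contains_xy(polygon, xs, ys)
    if not inside.any():
        raise EmptyTraceError("no sonar sample inside the polygon")
    d = dist[inside]
    n_long = int((d > mount_height + noise_tolerance).sum())
    if n_long:
        log.warning("%d sonar distances exceed mount height by > %.3f m; clipped",
                    n_long, noise_tolerance)
    heights = np.clip(mount_height - d, 0.0, None)
    return float(np.mean(heights) if stat == "mean" else np.median(heights))


def sonar_table(samples, polygons, mount_height: float, stat: str = "mean"):
    """Per-polygon Sonar_PH DataFrame; ``polygons`` maps id -> Polygon."""
    import pandas as pd

    rows = []
    for key, poly in polygons.items():
        rows.append({"row_id": key,
                     "Sonar_PH": extract_sonar_height(samples, poly, mount_height, stat=stat)})
    return pd.DataFrame(rows)
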