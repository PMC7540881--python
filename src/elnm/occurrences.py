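"""Occurrence handling: village-to-polygon assignment, per-group subsampling,
and extraction of environmental vectors at point localities.

Occurrence points are village localities; each language group contributes at
most ``cap`` (default 50) randomly chosen villages from inside its territory
polygon.  Groups with fewer than ``minimum`` (default 10) candidates are still
modelled but flagged low-confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from .raster import EnvStack

DEFAULT_CAP = 50
DEFAULT_MINIMUM = 10


@dataclass
class LanguageGroup:
    """A modelled language group: territory polygon plus metadata."""

    group_id: str               # zero-padded index text, e.g. "00", "31"
    family: str                 # "TNG" or "Austronesian"
    polygon: BaseGeometry
    n_languages: int | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError(f"group {self.group_id}: empty or invalid polygon")


@dataclass
class OccurrenceSet:
    """Sampled occurrence points for one group, with environmental vectors."""

    group_id: str
    points: np.ndarray                       # (n, 2) lon/lat
    seed: int | None = None
    low_confidence: bool = False
    env_vectors: pd.DataFrame | None = None  # rows = points, cols = variables

    def __len__(self) -> int:
        return len(self.points)


def groups_from_geojson(geojson: dict, metadata: pd.DataFrame | None = None) -> list[LanguageGroup]:
    """Build LanguageGroups from a GeoJSON FeatureCollection.

    Each feature needs ``group_id`` and ``family`` properties; ``n_languages``
    is taken from the feature or joined from ``metadata`` (indexed by group_id).
    """
    groups = []
    for feat in geojson["features"]:
        props = feat.get("properties", {})
        gid = str(props["group_id"])
        n_lang = props.get("n_languages")
        if n_lang is None and metadata is not None and gid in metadata.index:
            val = metadata.loc[gid].get("n_languages")
            n_lang = int(val) if pd.notna(val) else None
        groups.append(LanguageGroup(gid, props["family"], shape(feat["geometry"]),
                                    n_languages=n_lang, name=props.get("name", "")))
    return groups


def assign_points_to_polygons(points: np.ndarray,
                              groups: list[LanguageGroup]) -> list[str | None]:
    """Map each (lon, lat) point to the group_id of its containing polygon.

    Points outside every polygon map to None.  Points claimed by several
    polygons (overlap, or exactly on a shared boundary) go to the
    smallest-area polygon; boundary points count as inside (``covers``).
    """
    points = np.asarray(points, float)
    order = sorted(groups, key=lambda g: (g.polygon.area, g.group_id))
    assigned: list[str | None] = [None] * len(points)
    claimed = np.zeros(len(points), bool)
    n_contested = 0
    for g in order:
        within = _covers_xy(g.polygon, points[:, 0], points[:, 1])
        newly = within & ~claimed
        n_contested += int((within & claimed).sum())
        for i in np.where(newly)[0]:
            assigned[i] = g.group_id
        claimed |= within
    if n_contested:
        warnings.warn(f"{n_contested} point(s) inside multiple polygons; "
                      "assigned to the smallest-area polygon")
    return assigned


def _covers_xy(poly: BaseGeometry, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized boundary-inclusive point-in-polygon."""
    inside = contains_xy(poly, x, y)
    # contains_xy excludes the boundary; patch the (rare) boundary points
    border = ~inside
    if border.any():
        from shapely.geometry import Point
        for i in np.where(border)[0]:
            if poly.covers(Point(x[i], y[i])):
                inside[i] = True
    return inside


def sample_occurrences(group: LanguageGroup, candidates: np.ndarray,
                       cap: int = DEFAULT_CAP, minimum: int = DEFAULT_MINIMUM,
                       seed: int | None = None) -> OccurrenceSet:
    """Subsample up to ``cap`` candidate points for one group (seeded).

    All candidates when at or below the cap; a uniform sample without
    replacement otherwise.  Fewer than ``minimum`` candidates flags the set
    low-confidence (the group is still modelled).
    """
    candidates = np.asarray(candidates, float)
    if len(candidates) == 0:
        raise ValueError(f"group {group.group_id}: no candidate occurrences")
    if len(candidates) > cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(candidates), size=cap, replace=False)
        pts = candidates[np.sort(idx)]
    else:
        pts = candidates.copy()
    low = len(candidates) < minimum
    if low:
        warnings.warn(f"group {group.group_id}: only {len(candidates)} occurrences "
                      f"(< {minimum}); flagged low confidence")
    return OccurrenceSet(group.group_id, pts, seed=seed, low_confidence=low)


def extract_env(points: np.ndarray, stack: EnvStack,
                names: list[str] | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Environmental vectors at point localities (nearest-cell rule).

    Returns (frame of values for kept points, boolean keep-mask over the input
    points).  Points on nodata cells are dropped with a warning; all points on
    nodata is an error.
    """
    points = np.asarray(points, float)
    names = list(names) if names is not None else stack.names
    stack.require(names)
    shared = stack.shared_mask
    rows, cols, keep = [], [], np.zeros(len(points), bool)
    for i, (lon, lat) in enumerate(points):
        try:
            r, c = stack.grid.index_of(lon, lat)
        except ValueError:
            continue
        if shared[r, c]:
            continue
        rows.append(r)
        cols.append(c)
        keep[i] = True
    if not keep.any():
        raise ValueError("all points fall on nodata cells or outside the grid")
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} point(s) on nodata/outside cells dropped")
    r = np.array(rows)
    c = np.array(cols)
    data = {n: stack[n].values[r, c] for n in names}
    return pd.DataFrame(data), keep


def attach_env(occ: OccurrenceSet, stack: EnvStack,
               names: list[str] | None = None) -> OccurrenceSet:
    """Extract env vectors for an occurrence set, dropping nodata points."""
    frame, keep = extract_env(occ.points, stack, names)
    occ.points = occ.points[keep]
    occ.env_vectors = frame.reset_index(drop=True)
    return occ
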