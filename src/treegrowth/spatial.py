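"""Urban-form covariates from planar street and zone geometry.

Trees arrive as planar (x, y) points in a projected CRS whose length unit is
metres; the module never reprojects. Three geometric primitives feed the
covariate table:

* the *linear directional mean* of a street centerline — the length-weighted
  axial mean orientation of its edges, computed by angle doubling so that 10°
  and 170° average to 0° (a north–south axis) rather than 90°. Orientation is
  a compass axis in [0°, 180°): 0° = north–south, 90° = east–west;
* the *nearest segment* to each tree (with a maximum search radius), giving
  street width and the offset vector used for the roadside quadrant;
* *point-in-polygon joins* against zone layers (tax lots, tracts, ZIP zones)
  carrying land use, built floor-area ratio, population density and the
  social vulnerability index.

The roadside quadrant is axis-relative: a tree on an east–west street is
North or South of it, on a north–south street East or West. Streets within
45° of the east–west axis count as east–west; the 45° boundary itself and
zero offset components resolve by fixed, documented tie rules (east–west;
North/East) so the assignment is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, mapping, shape
from shapely.strtree import STRtree

__all__ = [
    "linear_directional_mean",
    "nearest_segment",
    "roadside_quadrant",
    "polygon_join",
    "aggregate_by_zone",
    "attach_covariates",
    "read_geojson_layer",
    "write_geojson_layer",
]


def read_geojson_layer(path: str | Path) -> tuple[list, list[dict]]:
    """Read a GeoJSON FeatureCollection into (geometries, property dicts)."""
    with open(path) as fh:
        collection = json.load(fh)
    geoms, props = [], []
    for feat in collection["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties", {}))
    return geoms, props


def write_geojson_layer(path: str | Path, geoms: list, props: list[dict]) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geoms, props)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def linear_directional_mean(line: LineString) -> float | None:
    """Length-weighted axial mean orientation of a polyline, degrees in [0, 180).

    Compass convention: 0° is a north–south axis, 90° east–west. Each edge's
    doubled orientation angle is summed with its length as weight; a vanishing
    resultant (e.g. equal-length edges at 0° and 90°) has no defined axis and
    returns ``None``.
    """
    coords = np.asarray(line.coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("segment needs at least two vertices")
    d = np.diff(coords, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    if lengths.sum() == 0:
        raise ValueError("segment has zero length")
    # compass angle of each edge: atan2(dx, dy), doubled for axial averaging
    theta = np.arctan2(d[:, 0], d[:, 1])
    s = float(np.sum(lengths * np.sin(2 * theta)))
    c = float(np.sum(lengths * np.cos(2 * theta)))
    if np.hypot(s, c) < 1e-9 * lengths.sum():
        return None
    mean = 0.5 * np.degrees(np.arctan2(s, c))
    return float(mean % 180.0)


def nearest_segment(
    points: list[Point] | np.ndarray,
    segments: list[LineString],
    segment_ids: list,
    max_radius: float = 100.0,
) -> pd.DataFrame:
    """Nearest street segment per tree, with the perpendicular offset vector.

    Returns a frame with ``segment_id`` (None beyond ``max_radius``),
    ``distance`` and the offset components ``offset_x``/``offset_y`` from the
    closest point on the segment to the tree. Exact distance ties resolve to
    the lowest segment id.
    """
    if len(segments) == 0:
        raise ValueError("no segments supplied")
    pts = [p if isinstance(p, Point) else Point(p) for p in points]
    order = np.argsort(np.asarray(segment_ids, dtype=object), kind="stable")
    segs = [segments[i] for i in order]
    ids = [segment_ids[i] for i in order]
    tree = STRtree(segs)
    pt_idx, seg_idx = tree.query_nearest(
        pts, max_distance=max_radius, all_matches=True
    )
    rows: dict[int, tuple] = {}
    for pi, si in zip(pt_idx, seg_idx):
        cand = (float(pts[pi].distance(segs[si])), ids[si], si)
        if pi not in rows or cand < rows[pi]:
            rows[pi] = cand
    out = []
    for i, p in enumerate(pts):
        if i not in rows:
            out.append((None, np.nan, np.nan, np.nan))
            continue
        dist, sid, si = rows[i]
        nearest = segs[si].interpolate(segs[si].project(p))
        out.append((sid, dist, p.x - nearest.x, p.y - nearest.y))
    return pd.DataFrame(
        out, columns=["segment_id", "distance", "offset_x", "offset_y"]
    )


def roadside_quadrant(orientation_deg: float, offset_x: float, offset_y: float) -> str | None:
    """Side of the street a tree stands on: North, South, East or West.

    ``orientation_deg`` is the street's axial orientation (0° = N–S,
    90° = E–W); the offset vector points from the street to the tree. Streets
    within 45° of the east–west axis (boundary inclusive) assign North/South
    by the northing; otherwise East/West by the easting. A zero component on
    the deciding axis resolves to North (resp. East); a zero offset vector has
    no side and returns ``None``.
    """
    if offset_x == 0 and offset_y == 0:
        return None
    if orientation_deg is None or not np.isfinite(orientation_deg):
        return None
    a = orientation_deg % 180.0
    east_west = 45.0 <= a <= 135.0
    if east_west:
        return "North" if offset_y >= 0 else "South"
    return "East" if offset_x >= 0 else "West"


def polygon_join(
    points: list[Point] | np.ndarray,
    polygons: list,
    zone_ids: list,
) -> list:
    """Assign each point the id of the polygon covering it.

    Boundary points count as inside; a point covered by several polygons gets
    the lowest zone id; a point outside all polygons gets ``None``.
    """
    for zid, poly in zip(zone_ids, polygons):
        if not poly.is_valid:
            raise ValueError(f"invalid polygon for zone {zid!r}")
    pts = [p if isinstance(p, Point) else Point(p) for p in points]
    tree = STRtree(polygons)
    pt_idx, poly_idx = tree.query(pts, predicate="intersects")
    best: dict[int, object] = {}
    for pi, gi in zip(pt_idx, poly_idx):
        zid = zone_ids[gi]
        if pi not in best or zid < best[pi]:
            best[pi] = zid
    return [best.get(i) for i in range(len(pts))]


@dataclass
class ZoneExclusion:
    zone_id: object
    reason: str
    n_trees: int


def aggregate_by_zone(
    trees: pd.DataFrame,
    zones: pd.DataFrame,
    min_n: int = 100,
    exclude: tuple = (),
    zone_col: str = "zone_id",
    rate_col: str = "rate_in_per_yr",
    dbh_col: str = "dbh_in_05",
) -> tuple[pd.DataFrame, list[ZoneExclusion]]:
    """Per-zone mean rate, mean DBH, tree count and density.

    ``zones`` needs ``zone_id`` and ``area_km2`` columns (plus any zone-level
    attributes such as ``svi``, which are carried through). Zones with fewer
    than ``min_n`` trees, or listed in ``exclude``, are dropped from the
    output and recorded with a reason.
    """
    if zone_col not in trees.columns:
        raise KeyError(f"trees frame lacks {zone_col!r}")
    grouped = (
        trees.dropna(subset=[zone_col])
        .groupby(zone_col)
        .agg(
            n_trees=(rate_col, "size"),
            mean_rate=(rate_col, "mean"),
            mean_dbh=(dbh_col, "mean"),
        )
        .reset_index()
    )
    merged = grouped.merge(zones, left_on=zone_col, right_on="zone_id", how="left")
    if (merged["area_km2"] <= 0).any():
        bad = merged.loc[merged["area_km2"] <= 0, "zone_id"].tolist()
        raise ValueError(f"zones with non-positive area: {bad}")
    merged["trees_per_km2"] = merged["n_trees"] / merged["area_km2"]

    exclusions: list[ZoneExclusion] = []
    listed = merged["zone_id"].isin(exclude)
    small = merged["n_trees"] < min_n
    for _, row in merged.loc[listed].iterrows():
        exclusions.append(ZoneExclusion(row["zone_id"], "listed", int(row["n_trees"])))
    for _, row in merged.loc[small & ~listed].iterrows():
        exclusions.append(
            ZoneExclusion(row["zone_id"], f"fewer than {min_n} trees", int(row["n_trees"]))
        )
    kept = merged.loc[~(listed | small)].reset_index(drop=True)
    return kept, exclusions


def attach_covariates(
    trees: pd.DataFrame,
    segments: list[LineString],
    segment_props: list[dict],
    zone_layers: dict[str, tuple[list, list[dict]]],
    max_radius: float = 100.0,
    x_col: str = "x",
    y_col: str = "y",
    id_col: str = "record_id",
) -> pd.DataFrame:
    """Build the covariate table for a frame of tree points.

    ``zone_layers`` maps a layer name to (polygons, property dicts); every
    property of the covering polygon is copied onto the tree, plus a
    ``<layer>_zone_id`` column. Street-derived covariates are the nearest
    segment's width and the roadside quadrant from its directional mean.
    """
    pts = [Point(x, y) for x, y in zip(trees[x_col], trees[y_col])]
    seg_ids = [p.get("segment_id", i) for i, p in enumerate(segment_props)]
    near = nearest_segment(pts, segments, seg_ids, max_radius=max_radius)

    seg_lookup = {sid: (seg, props) for sid, seg, props in zip(seg_ids, segments, segment_props)}
    orientations = {sid: linear_directional_mean(seg) for sid, (seg, _) in seg_lookup.items()}

    out = pd.DataFrame({id_col: trees[id_col].values})
    out["segment_id"] = near["segment_id"].values
    widths, quadrants = [], []
    for sid, ox, oy in zip(near["segment_id"], near["offset_x"], near["offset_y"]):
        if sid is None or (isinstance(sid, float) and np.isnan(sid)):
            widths.append(np.nan)
            quadrants.append(None)
            continue
        widths.append(seg_lookup[sid][1].get("st_width", np.nan))
        quadrants.append(roadside_quadrant(orientations[sid], ox, oy))
    out["st_width"] = widths
    out["roadside_location"] = quadrants

    for layer, (polys, props) in zone_layers.items():
        zids = [p.get("zone_id", i) for i, p in enumerate(props)]
        assigned = polygon_join(pts, polys, zids)
        out[f"{layer}_zone_id"] = assigned
        prop_lookup = {zid: p for zid, p in zip(zids, props)}
        attr_names = set().union(*(p.keys() for p in props)) - {"zone_id"}
        for attr in sorted(attr_names):
            out[attr] = [
                prop_lookup[z].get(attr) if z is not None else np.nan for z in assigned
            ]
    return out
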