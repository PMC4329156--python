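"""Vector-GIS delineation of potential buffer placements and impact areas.

The procedure mirrors the national mapping workflow: watercourse
centerlines are assigned a nominal channel width (15 m by default) and
dilated to their edge lines; an agricultural block is paired with a
watercourse when its boundary runs along the watercourse edge for at
least 30 m; pastures and undefined/minor crops are excluded; and the
impact area — the land whose P export a buffer can intercept — is the
part of the block within a fixed distance (60 m by default) of the
centerline.  The enrollable strip is accounted as a rectangle:
frontage length x buffer width.

All geometry is planar with metric coordinates; no CRS handling beyond
that assumption.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import LineString, MultiLineString, Polygon, mapping, shape
from shapely.ops import snap

from .catchment import (
    BUFFER_WIDTHS_M,
    IMPACT_DEPTH_M,
    MIN_ADJACENCY_M,
    LandUseCategory,
    ValidationError,
)

__all__ = [
    "WatercourseFeature",
    "BlockFeature",
    "DelineationEntry",
    "watercourse_edge",
    "adjacency_length",
    "filter_eligible",
    "delineate_impact",
    "delineate",
    "summarize_subcatchment",
    "read_blocks_geojson",
    "read_watercourses_geojson",
    "write_impact_geojson",
    "entries_to_frame",
]

#: Snapping tolerance (m) when matching a block boundary to a watercourse
#: edge; block layers are digitized against the same hydrography, so a
#: small tolerance absorbs floating-point vertex mismatch.
SNAP_TOLERANCE_M = 1.0

#: Tolerance for exact geometric predicates.
GEOM_EPS = 1e-6

#: Nominal channel width (m) assigned to every watercourse.
DEFAULT_CHANNEL_WIDTH_M = 15.0


@dataclass(frozen=True)
class WatercourseFeature:
    """A watercourse (stream or ditch) centerline with its nominal channel width."""

    id: str
    centerline: LineString
    assigned_width: float = DEFAULT_CHANNEL_WIDTH_M

    def __post_init__(self) -> None:
        if self.assigned_width <= 0:
            raise ValidationError(f"watercourse {self.id!r}: assigned width must be positive")
        if len(self.centerline.coords) < 2 or self.centerline.length <= GEOM_EPS:
            raise ValidationError(f"watercourse {self.id!r}: degenerate centerline")


@dataclass(frozen=True)
class BlockFeature:
    """An agricultural block polygon with its land-use category."""

    id: str
    polygon: Polygon
    land_use: LandUseCategory
    sub_catchment_id: str | None = None

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValidationError(f"block {self.id!r}: invalid polygon")


@dataclass(frozen=True)
class DelineationEntry:
    """Outcome for one (block, watercourse) pair."""

    block_id: str
    watercourse_id: str
    adjacency_length: float  # m of shared frontage along the watercourse edge
    eligible: bool
    impact_polygon: Polygon | None
    impact_area: float  # ha
    potential_strip_area_by_width: dict[int, float] = field(default_factory=dict)
    sub_catchment_id: str | None = None


def watercourse_edge(watercourse: WatercourseFeature) -> tuple[LineString, ...]:
    """Edge lines of the watercourse: the centerline dilated by half the channel width.

    For an open centerline this is the pair of parallel offset curves,
    one per bank; for a closed-loop centerline, the two concentric rings
    bounding the dilated channel polygon.
    """
    line = watercourse.centerline
    half = watercourse.assigned_width / 2.0
    if line.is_closed:
        rings = _as_lines(line.buffer(half).boundary)
        return tuple(rings)
    left = line.offset_curve(half)
    right = line.offset_curve(-half)
    edges: list[LineString] = []
    for side in (left, right):
        edges.extend(_as_lines(side))
    if not edges:
        raise ValidationError(f"watercourse {watercourse.id!r}: could not construct edge lines")
    return tuple(edges)


def _as_lines(geom) -> list[LineString]:
    if geom.is_empty:
        return []
    if isinstance(geom, LineString):
        return [geom]
    if isinstance(geom, MultiLineString):
        return list(geom.geoms)
    if hasattr(geom, "geoms"):
        out: list[LineString] = []
        for g in geom.geoms:
            out.extend(_as_lines(g))
        return out
    return []


def adjacency_length(
    block: BlockFeature,
    watercourse: WatercourseFeature,
    tolerance: float = SNAP_TOLERANCE_M,
) -> float:
    """Length (m) of the watercourse edge running along the block boundary.

    Edge vertices are snapped to the block boundary within ``tolerance``
    and the one-dimensional overlap measured, so geometry digitized flush
    against the hydrography yields the exact shared length.  Disjoint
    features give 0.
    """
    if block.polygon.distance(watercourse.centerline) > watercourse.assigned_width / 2 + tolerance:
        return 0.0
    boundary = block.polygon.boundary
    total = 0.0
    for edge in watercourse_edge(watercourse):
        snapped = snap(edge, boundary, tolerance)
        shared = snapped.intersection(boundary)
        total += sum(line.length for line in _as_lines(shared))
    return total


def filter_eligible(
    blocks: Iterable[BlockFeature],
    watercourses: Iterable[WatercourseFeature],
    min_adjacency: float = MIN_ADJACENCY_M,
    tolerance: float = SNAP_TOLERANCE_M,
) -> list[tuple[BlockFeature, WatercourseFeature, float]]:
    """Pairs eligible for buffer placement: cropped blocks with >= ``min_adjacency`` m frontage.

    Returns ``(block, watercourse, adjacency_length)`` triples.
    """
    out = []
    for b in blocks:
        if not b.land_use.buffer_eligible:
            continue
        for w in watercourses:
            adj = adjacency_length(b, w, tolerance)
            if adj >= min_adjacency:
                out.append((b, w, adj))
    return out


def delineate_impact(
    block: BlockFeature,
    watercourse: WatercourseFeature,
    buffer_distance: float = IMPACT_DEPTH_M,
    adjacency: float | None = None,
    tolerance: float = SNAP_TOLERANCE_M,
    min_adjacency: float = MIN_ADJACENCY_M,
) -> DelineationEntry:
    """Delineate one pair's impact area and enrollable strip areas.

    The impact polygon is the block clipped to the centerline dilated by
    ``buffer_distance``; the enrollable strip at width *w* is accounted
    as a rectangle, frontage x *w*, in hectares.
    """
    if not block.polygon.is_valid:
        raise ValidationError(f"block {block.id!r}: invalid polygon")
    adj = adjacency_length(block, watercourse, tolerance) if adjacency is None else adjacency
    corridor = watercourse.centerline.buffer(buffer_distance)
    impact = block.polygon.intersection(corridor)
    impact_area_ha = impact.area / 10_000.0
    eligible = (
        block.land_use.buffer_eligible and adj >= min_adjacency and impact_area_ha > 0
    )
    strips = {w: adj * w / 10_000.0 for w in BUFFER_WIDTHS_M} if eligible else dict.fromkeys(BUFFER_WIDTHS_M, 0.0)
    return DelineationEntry(
        block_id=block.id,
        watercourse_id=watercourse.id,
        adjacency_length=adj,
        eligible=eligible,
        impact_polygon=impact if not impact.is_empty else None,
        impact_area=impact_area_ha,
        potential_strip_area_by_width=strips,
        sub_catchment_id=block.sub_catchment_id,
    )


def delineate(
    blocks: Sequence[BlockFeature],
    watercourses: Sequence[WatercourseFeature],
    min_adjacency: float = MIN_ADJACENCY_M,
    buffer_distance: float = IMPACT_DEPTH_M,
    tolerance: float = SNAP_TOLERANCE_M,
) -> list[DelineationEntry]:
    """Run the full procedure over all (block, watercourse) pairs that touch."""
    entries = []
    for b in blocks:
        for w in watercourses:
            adj = adjacency_length(b, w, tolerance)
            if adj <= 0:
                continue
            entries.append(
                delineate_impact(
                    b, w, buffer_distance,
                    adjacency=adj, tolerance=tolerance, min_adjacency=min_adjacency,
                )
            )
    return entries


def summarize_subcatchment(
    entries: Sequence[DelineationEntry], sub_catchment_id: str
) -> dict:
    """Aggregate eligible pairs of one sub-catchment.

    Returns eligible frontage (m), potential buffer area per width (ha)
    and total impact area (ha).  Raises for an id no entry references.
    """
    known = {e.sub_catchment_id for e in entries}
    if sub_catchment_id not in known:
        raise ValidationError(f"unknown sub-catchment id {sub_catchment_id!r}")
    mine = [e for e in entries if e.sub_catchment_id == sub_catchment_id and e.eligible]
    return {
        "sub_catchment_id": sub_catchment_id,
        "eligible_length_m": sum(e.adjacency_length for e in mine),
        "potential_buffer_area_by_width": {
            w: sum(e.potential_strip_area_by_width.get(w, 0.0) for e in mine)
            for w in BUFFER_WIDTHS_M
        },
        "impact_area_ha": sum(e.impact_area for e in mine),
    }


# ---------------------------------------------------------------------------
# GeoJSON I/O (planar metric coordinates)


def _load_feature_collection(path: str | Path) -> list[dict]:
    with open(path) as fh:
        fc = json.load(fh)
    if fc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    return fc.get("features", [])


def read_blocks_geojson(path: str | Path) -> list[BlockFeature]:
    """Read agricultural block polygons; ``land_use`` property required."""
    blocks = []
    for i, feat in enumerate(_load_feature_collection(path)):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValidationError(f"{path}: feature {i} is not a Polygon")
        blocks.append(
            BlockFeature(
                id=str(props.get("id", i)),
                polygon=geom,
                land_use=LandUseCategory(str(props.get("land_use", "CROP")).upper()),
                sub_catchment_id=props.get("sub_catchment_id"),
            )
        )
    return blocks


def read_watercourses_geojson(path: str | Path) -> list[WatercourseFeature]:
    """Read watercourse centerlines; optional ``assigned_width_m`` property."""
    out = []
    for i, feat in enumerate(_load_feature_collection(path)):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if not isinstance(geom, LineString):
            raise ValidationError(f"{path}: feature {i} is not a LineString")
        out.append(
            WatercourseFeature(
                id=str(props.get("id", i)),
                centerline=geom,
                assigned_width=float(props.get("assigned_width_m", DEFAULT_CHANNEL_WIDTH_M)),
            )
        )
    return out


def write_impact_geojson(entries: Sequence[DelineationEntry], path: str | Path) -> None:
    """Write the delineated impact polygons as a GeoJSON FeatureCollection."""
    feats = []
    for e in entries:
        if e.impact_polygon is None:
            continue
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(e.impact_polygon),
                "properties": {
                    "block_id": e.block_id,
                    "watercourse_id": e.watercourse_id,
                    "adjacency_length_m": e.adjacency_length,
                    "eligible": e.eligible,
                    "impact_area_ha": e.impact_area,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def entries_to_frame(entries: Sequence[DelineationEntry]) -> pd.DataFrame:
    """Per-pair results as a table (block_id, watercourse_id, adjacency, eligibility, area)."""
    return pd.DataFrame(
        [
            {
                "block_id": e.block_id,
                "watercourse_id": e.watercourse_id,
                "adjacency_length_m": e.adjacency_length,
                "eligible": e.eligible,
                "impact_area_ha": e.impact_area,
            }
            for e in entries
        ]
    )
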