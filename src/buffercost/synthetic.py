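"""Synthetic catchment bundles emulating a mid-Swedish agricultural catchment.

The generator reproduces the structural facts of the Svärta River
catchment — 13 sub-catchments in the "Svealands slättbygder" production
region, about 9000 ha of agricultural land of which 7500 ha is cropped,
11 sub-catchments in the highest soil-P class (1 middle, 1 low), and 11
in the steepest slope class (2 middle) — and then *calibrates* the
per-impact-area baseline P transports by one global scale factor so
that a reference allocation reproduces a reference total reduction.
Calibration is exact because the reduction model is linear in the
baselines; it preserves every ratio between impact areas.

Defaults place the total eligible watercourse frontage at 1 100 000/6 m
(183 333.3 m), so the full 6-m potential area is 110 ha, and spread
162 ha of existing 10-m buffers over sub-catchments pro rata by
frontage — the catchment-level figures reported for the study system.
Per-sub-catchment transports and frontages are random (seeded): the real
ones are unpublished, so only catchment-level totals and the arithmetic
identities that follow from them are meaningful on synthetic bundles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon, mapping

from .catchment import (
    Catchment,
    ImpactArea,
    LandUseCategory,
    SlopeClass,
    SoilPClass,
    SubCatchment,
    ValidationError,
    Allocation,
    IMPACT_DEPTH_M,
    rescale_transports,
)
from .costs import default_cost_schedule
from .delineation import BlockFeature, WatercourseFeature, DEFAULT_CHANNEL_WIDTH_M
from .reduction import ReductionTable, allocation_reduction
from .scenarios import existing_allocation

__all__ = [
    "SynthParams",
    "ReferenceAnchor",
    "generate",
    "calibrate",
    "svarta_like_catchment",
    "generate_geometry",
    "write_blocks_geojson",
    "write_watercourses_geojson",
]

logger = logging.getLogger(__name__)

#: Reference totals for the study system: 162 ha of existing 10-m
#: buffers reducing 97.2 kg P per year.
REFERENCE_EXISTING_AREA_HA = 162.0
REFERENCE_REDUCTION_KG = 97.2

#: Total eligible frontage (m) such that the 6-m potential area is 110 ha.
DEFAULT_TOTAL_ELIGIBLE_LENGTH_M = 110.0 * 10_000.0 / 6.0


@dataclass(frozen=True)
class SynthParams:
    """Study-condition parameters of the synthetic catchment generator."""

    seed: int = 1
    n_sub: int = 13
    region: str = "Svealands slättbygder"
    #: sub-catchment counts per soil-P class, HIGH/MID/LOW
    soil_p_split: tuple[int, int, int] = (11, 1, 1)
    #: sub-catchment counts per slope class, SL3/SL2/SL1
    slope_split: tuple[int, int, int] = (11, 2, 0)
    total_agricultural_area: float = 9_000.0  # ha
    crop_area: float = 7_500.0  # ha
    #: per-sub-catchment frontage draw (m), rescaled to the fixed total
    eligible_length_range: tuple[float, float] = (8_000.0, 22_000.0)
    total_eligible_length_m: float = DEFAULT_TOTAL_ELIGIBLE_LENGTH_M
    #: uncalibrated P export intensity of impact strips (kg P / ha / yr)
    transport_intensity_range: tuple[float, float] = (0.1, 0.3)
    existing_buffer_total_ha: float = REFERENCE_EXISTING_AREA_HA
    existing_buffer_width_m: int = 10

    def __post_init__(self) -> None:
        if sum(self.soil_p_split) != self.n_sub:
            raise ValidationError(
                f"soil-P split {self.soil_p_split} does not sum to n_sub={self.n_sub}"
            )
        if sum(self.slope_split) != self.n_sub:
            raise ValidationError(
                f"slope split {self.slope_split} does not sum to n_sub={self.n_sub}"
            )
        if self.crop_area > self.total_agricultural_area:
            raise ValidationError("crop area exceeds total agricultural area")
        for lo, hi in (self.eligible_length_range, self.transport_intensity_range):
            if not 0 < lo <= hi:
                raise ValidationError("ranges must be positive with lo <= hi")


@dataclass(frozen=True)
class ReferenceAnchor:
    """A reference allocation and the total reduction it must reproduce."""

    allocation: Allocation
    target_total_reduction: float  # kg P / yr


def _spread(counts: tuple[int, int, int], labels, rng) -> list:
    seq = [lab for lab, c in zip(labels, counts) for _ in range(c)]
    return [seq[i] for i in rng.permutation(len(seq))]


def generate(params: SynthParams = SynthParams()) -> Catchment:
    """Generate a reproducible catchment honouring the configured splits.

    Frontages are drawn uniformly per sub-catchment and rescaled to the
    fixed catchment total; baseline transports are export intensity x
    impact-strip area (frontage x 60 m).  Existing buffer area is
    spread pro rata by frontage at the configured width.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_sub
    lengths = rng.uniform(*params.eligible_length_range, size=n)
    lengths *= params.total_eligible_length_m / lengths.sum()
    slope = _spread(params.slope_split, (SlopeClass.SL3, SlopeClass.SL2, SlopeClass.SL1), rng)
    soil = _spread(params.soil_p_split, (SoilPClass.HIGH, SoilPClass.MID, SoilPClass.LOW), rng)
    intensity = rng.uniform(*params.transport_intensity_range, size=n)
    region = default_cost_schedule()[params.region]

    subs = []
    for i in range(n):
        sid = f"sc{i + 1:02d}"
        area_ha = lengths[i] * IMPACT_DEPTH_M / 10_000.0
        ia = ImpactArea(
            id=f"{sid}-ia1",
            sub_catchment_id=sid,
            area=area_ha,
            slope_class=slope[i],
            baseline_p_transport=float(intensity[i] * area_ha),
            eligible_length=float(lengths[i]),
            existing_buffer_width=params.existing_buffer_width_m,
        )
        subs.append(
            SubCatchment(
                id=sid,
                region=region,
                soil_p_class=soil[i],
                impact_areas=(ia,),
                existing_buffer_area=float(
                    params.existing_buffer_total_ha * lengths[i] / lengths.sum()
                ),
            )
        )
    return Catchment(id=f"synthetic-svarta-seed{params.seed}", sub_catchments=tuple(subs))


def calibrate(
    catchment: Catchment, anchor: ReferenceAnchor, table: ReductionTable
) -> Catchment:
    """Scale all baseline transports so the anchor allocation hits its target exactly.

    A single global factor ``k = target / current`` is applied, so every
    ratio between impact areas is preserved and, by linearity of the
    reduction model, the anchor reproduces the target to round-off.
    """
    current = allocation_reduction(catchment, anchor.allocation, table)
    if current <= 0:
        raise ValidationError("cannot calibrate: anchor allocation yields zero reduction")
    k = anchor.target_total_reduction / current
    logger.info("calibration factor k = %.6g (current %.3f kg -> target %.3f kg)",
                k, current, anchor.target_total_reduction)
    return rescale_transports(catchment, k)


def svarta_like_catchment(
    seed: int = 1,
    table: ReductionTable | None = None,
    params: SynthParams | None = None,
) -> Catchment:
    """Generate and calibrate a catchment anchored to the reference program.

    The anchor is the existing-buffer allocation (162 ha at 10 m)
    reproducing a 97.2 kg/yr total reduction.
    """
    from .reduction import default_reduction_table

    table = table or default_reduction_table()
    params = params or SynthParams(seed=seed)
    catchment = generate(params)
    anchor = ReferenceAnchor(
        allocation=existing_allocation(catchment, params.existing_buffer_width_m),
        target_total_reduction=REFERENCE_REDUCTION_KG,
    )
    return calibrate(catchment, anchor, table)


# ---------------------------------------------------------------------------
# toy geometry fixtures for the delineation stage


@dataclass(frozen=True)
class GeometryTruth:
    """Construction-time ground truth recorded alongside generated features."""

    adjacency_by_block: dict[str, float] = field(default_factory=dict)


def generate_geometry(
    seed: int = 1,
    n_blocks: int = 8,
    landscape_size: float = 5_000.0,
    channel_width: float = DEFAULT_CHANNEL_WIDTH_M,
) -> tuple[list[BlockFeature], list[WatercourseFeature], GeometryTruth]:
    """Random riverside landscape with analytically known adjacency lengths.

    One straight watercourse runs along y = 0; blocks are rectangles
    either flush against the upper channel edge (adjacency = frontage)
    or set back beyond the impact corridor (adjacency = 0, empty impact
    area).  Block corners sit on whole metres, emulating cadastral
    digitization precision.  Land use is mostly cropped with occasional
    pasture/minor-crop blocks, so eligibility filtering is exercised
    too.
    """
    rng = np.random.default_rng(seed)
    wc = WatercourseFeature(
        id="wc1",
        centerline=LineString([(0.0, 0.0), (landscape_size, 0.0)]),
        assigned_width=channel_width,
    )
    edge_y = channel_width / 2.0
    uses = [
        LandUseCategory.CROP,
        LandUseCategory.MANAGED_PASTURE,
        LandUseCategory.EXTENSIVE_PASTURE,
        LandUseCategory.MINOR_CROP,
    ]
    blocks: list[BlockFeature] = []
    truth: dict[str, float] = {}
    x = float(rng.integers(50, 150))
    for i in range(n_blocks):
        frontage = float(rng.integers(20, 301))
        depth = float(rng.integers(60, 201))
        if x + frontage > landscape_size - 50.0:
            break
        flush = bool(rng.random() < 0.75)
        y0 = edge_y if flush else edge_y + float(rng.integers(60, 151))
        bid = f"b{i + 1:02d}"
        poly = Polygon(
            [(x, y0), (x + frontage, y0), (x + frontage, y0 + depth), (x, y0 + depth)]
        )
        use = uses[int(rng.choice(len(uses), p=[0.7, 0.1, 0.1, 0.1]))]
        blocks.append(BlockFeature(id=bid, polygon=poly, land_use=use, sub_catchment_id="sc01"))
        truth[bid] = frontage if flush else 0.0
        x += frontage + float(rng.integers(10, 121))
    return blocks, [wc], GeometryTruth(adjacency_by_block=truth)


def write_blocks_geojson(blocks, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(b.polygon),
            "properties": {
                "id": b.id,
                "land_use": b.land_use.value,
                "sub_catchment_id": b.sub_catchment_id,
            },
        }
        for b in blocks
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def write_watercourses_geojson(watercourses, path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(w.centerline),
            "properties": {"id": w.id, "assigned_width_m": w.assigned_width},
        }
        for w in watercourses
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
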