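"""Domain types and bundle I/O for catchment-scale buffer-zone accounting.

A *catchment* is a set of sub-catchments, each carrying the attributes
needed to evaluate riparian buffer zones: the production region (which
fixes the annual cost of enrolled land), a three-tier soil-phosphorus
class, one or more *impact areas* — the strips of cropped land along
watercourses whose phosphorus export a buffer can intercept — and the
eligible watercourse frontage from which the enrollable (potential)
buffer area at each width follows.

Units are fixed package-wide: areas in hectares, lengths in metres,
costs in EUR per year, phosphorus transports in kg P per year.  All unit
conversions happen at the reader boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SlopeClass",
    "SoilPClass",
    "LandUseCategory",
    "BUFFER_WIDTHS_M",
    "IMPACT_DEPTH_M",
    "MIN_ADJACENCY_M",
    "ProductionRegion",
    "ImpactArea",
    "SubCatchment",
    "Catchment",
    "Allocation",
    "ValidationError",
    "classify_slope",
    "percentile_90",
    "load_catchment",
    "save_catchment",
]

#: The five buffer widths (m) supported by the subsidy scheme.
BUFFER_WIDTHS_M: tuple[int, ...] = (2, 6, 10, 15, 20)

#: Depth (m) of the impact strip along a watercourse used to delineate
#: the land whose P export a buffer can intercept.
IMPACT_DEPTH_M: float = 60.0

#: Minimum watercourse frontage (m) along a block for buffer eligibility.
MIN_ADJACENCY_M: float = 30.0


class ValidationError(ValueError):
    """Raised when an input bundle or allocation violates a model invariant."""


class SlopeClass(enum.Enum):
    """Slope-percentage class of erosion-sensitive land near watercourses.

    SL1 covers [0, 1.99) %, SL2 covers [1.99, 3.26] %, SL3 is > 3.26 %.
    The three intervals partition the non-negative slopes; boundary
    values belong to the middle class (3.26 % is SL2, consistent with
    SL3 being strictly above 3.26 %).
    """

    SL1 = "SL1"
    SL2 = "SL2"
    SL3 = "SL3"

    @property
    def bounds(self) -> tuple[float, float]:
        return _SLOPE_BOUNDS[self]


_SLOPE_BOUNDS = {
    SlopeClass.SL1: (0.0, 1.99),
    SlopeClass.SL2: (1.99, 3.26),
    SlopeClass.SL3: (3.26, math.inf),
}


class SoilPClass(enum.Enum):
    """Three-tier soil phosphorus concentration class (metadata only)."""

    LOW = "LOW"
    MID = "MID"
    HIGH = "HIGH"


class LandUseCategory(enum.Enum):
    """Land use of an agricultural block.

    Only ``CROP`` is buffer-eligible: pastures have very limited impact
    on P losses, and undefined/minor crops lack reliable P-loss
    coefficients.
    """

    CROP = "CROP"
    MANAGED_PASTURE = "MANAGED_PASTURE"
    EXTENSIVE_PASTURE = "EXTENSIVE_PASTURE"
    UNDEFINED = "UNDEFINED"
    MINOR_CROP = "MINOR_CROP"

    @property
    def buffer_eligible(self) -> bool:
        return self is LandUseCategory.CROP


def classify_slope(slope_percent: float) -> SlopeClass:
    """Map a slope (in percent) to its slope class.

    Raises ``ValidationError`` for negative slopes.
    """
    if not math.isfinite(slope_percent) or slope_percent < 0:
        raise ValidationError(f"slope must be a finite non-negative percent, got {slope_percent!r}")
    if slope_percent < 1.99:
        return SlopeClass.SL1
    if slope_percent <= 3.26:
        return SlopeClass.SL2
    return SlopeClass.SL3


def percentile_90(prices: Iterable[float]) -> float:
    """90th percentile of reported leasing prices.

    Linear interpolation between closest order statistics (the common
    statistical-package default).  The high percentile — rather than the
    mean — is used so the payment is high enough to compensate most
    landowners for forgone production.
    """
    arr = np.asarray(list(prices), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot take the 90th percentile of an empty price list")
    return float(np.percentile(arr, 90))


def validate_width(width: float) -> int:
    """Check that ``width`` is one of the supported buffer widths (m)."""
    w = int(width)
    if w != width or w not in BUFFER_WIDTHS_M:
        raise ValidationError(f"unsupported buffer width {width!r}; legal widths are {BUFFER_WIDTHS_M}")
    return w


@dataclass(frozen=True)
class ProductionRegion:
    """One of the eight Swedish production regions (PO8).

    ``leasing_price`` is the 90th percentile of reported agricultural
    leasing prices (EUR/ha/yr); ``establishment_cost`` is the annualized
    sowing/seed/labour cost (EUR/ha/yr, a national constant of 17 by
    default).
    """

    name: str
    leasing_price: float
    establishment_cost: float = 17.0

    def __post_init__(self) -> None:
        if self.leasing_price <= 0:
            raise ValidationError(f"region {self.name!r}: leasing price must be positive")
        if self.establishment_cost < 0:
            raise ValidationError(f"region {self.name!r}: establishment cost must be non-negative")

    @property
    def total_annual_cost(self) -> float:
        """Annual cost of one hectare of buffer zone (EUR/ha/yr)."""
        return self.leasing_price + self.establishment_cost


@dataclass(frozen=True)
class ImpactArea:
    """A strip of cropped land whose P export a buffer zone intercepts.

    ``baseline_p_transport`` is the *no-buffer* baseline (kg P/yr): the
    transport the strip would export with no buffer present.  Observed
    transports measured behind an existing buffer must first be
    back-corrected (see ``reduction.strip_existing_buffers``).
    """

    id: str
    sub_catchment_id: str
    area: float  # ha
    slope_class: SlopeClass
    baseline_p_transport: float  # kg P / yr, no-buffer baseline
    eligible_length: float  # m of watercourse frontage
    existing_buffer_width: int | None = None  # m

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValidationError(f"impact area {self.id!r}: negative area {self.area}")
        if self.baseline_p_transport < 0:
            raise ValidationError(
                f"impact area {self.id!r}: negative baseline transport {self.baseline_p_transport}"
            )
        if self.eligible_length < 0:
            raise ValidationError(f"impact area {self.id!r}: negative eligible length")
        if self.existing_buffer_width is not None:
            validate_width(self.existing_buffer_width)

    @property
    def eligible(self) -> bool:
        """Frontages shorter than 30 m are excluded from the potential area."""
        return self.eligible_length >= MIN_ADJACENCY_M


@dataclass(frozen=True)
class SubCatchment:
    """Smallest drainage accounting unit; one buffer allocation applies per unit."""

    id: str
    region: ProductionRegion
    soil_p_class: SoilPClass
    impact_areas: tuple[ImpactArea, ...]
    existing_buffer_area: float = 0.0  # ha already enrolled (e.g. under the RDP)

    def __post_init__(self) -> None:
        if self.existing_buffer_area < 0:
            raise ValidationError(f"sub-catchment {self.id!r}: negative existing buffer area")
        for ia in self.impact_areas:
            if ia.sub_catchment_id != self.id:
                raise ValidationError(
                    f"impact area {ia.id!r} belongs to {ia.sub_catchment_id!r}, not {self.id!r}"
                )

    @property
    def eligible_length(self) -> float:
        """Total eligible watercourse frontage (m)."""
        return sum(ia.eligible_length for ia in self.impact_areas if ia.eligible)

    def potential_area(self, width: float) -> float:
        """Enrollable strip area (ha) at ``width``: frontage x width / 10 000."""
        w = validate_width(width)
        return self.eligible_length * w / 10_000.0

    @property
    def potential_buffer_area_by_width(self) -> dict[int, float]:
        return {w: self.potential_area(w) for w in BUFFER_WIDTHS_M}

    @property
    def baseline_p_transport(self) -> float:
        """Summed no-buffer baseline over eligible impact areas (kg P/yr)."""
        return sum(ia.baseline_p_transport for ia in self.impact_areas if ia.eligible)


@dataclass(frozen=True)
class Catchment:
    id: str
    sub_catchments: tuple[SubCatchment, ...]

    def __post_init__(self) -> None:
        ids = [sc.id for sc in self.sub_catchments]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate sub-catchment ids: {dupes}")

    def __iter__(self):
        return iter(self.sub_catchments)

    def __len__(self) -> int:
        return len(self.sub_catchments)

    def __getitem__(self, sub_id: str) -> SubCatchment:
        for sc in self.sub_catchments:
            if sc.id == sub_id:
                return sc
        raise KeyError(sub_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sc.id for sc in self.sub_catchments)


@dataclass(frozen=True)
class Allocation:
    """Per-sub-catchment assignment of one buffer width and an enrolled area.

    ``entries`` maps sub-catchment id to ``(width_m, enrolled_area_ha)``.
    """

    entries: Mapping[str, tuple[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for sid, (w, area) in self.entries.items():
            validate_width(w)
            if area < 0:
                raise ValidationError(f"allocation for {sid!r}: negative enrolled area {area}")

    def validate(self, catchment: Catchment) -> None:
        """Check every entry against the catchment's potential areas."""
        for sid, (w, area) in self.entries.items():
            try:
                sc = catchment[sid]
            except KeyError:
                raise ValidationError(f"allocation references unknown sub-catchment {sid!r}") from None
            pot = sc.potential_area(w)
            # small relative slack for float round-trips through CSV
            if area > pot * (1 + 1e-9) + 1e-9:
                raise ValidationError(
                    f"allocation for {sid!r}: enrolled {area:.6f} ha exceeds "
                    f"potential {pot:.6f} ha at width {w} m"
                )

    @property
    def total_area(self) -> float:
        return sum(area for _, area in self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# bundle I/O

SUBCATCHMENT_COLUMNS = [
    "id",
    "region",
    "soil_p_class",
    "slope_class",
    "eligible_length_m",
    "baseline_p_transport_kg",
    "existing_buffer_area_ha",
    "existing_buffer_width_m",
]


def _resolve_bundle_csv(bundle_path: str | Path) -> Path:
    p = Path(bundle_path)
    if p.is_dir():
        p = p / "subcatchments.csv"
    if not p.exists():
        raise ValidationError(f"no sub-catchment table found at {p}")
    return p


def load_catchment(
    bundle_path: str | Path,
    regions: Mapping[str, ProductionRegion] | None = None,
    catchment_id: str | None = None,
) -> Catchment:
    """Read a catchment bundle (directory with ``subcatchments.csv``, or the CSV itself).

    ``regions`` maps region name to :class:`ProductionRegion`; when omitted the
    packaged default cost schedule (the eight PO8 regions) is used.  Every row's
    region must resolve against it.
    """
    from .costs import default_cost_schedule  # deferred: costs imports this module

    csv_path = _resolve_bundle_csv(bundle_path)
    if regions is None:
        regions = default_cost_schedule().regions
    df = pd.read_csv(csv_path, dtype={"id": str})
    missing = [c for c in SUBCATCHMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{csv_path}: missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{csv_path}: no sub-catchments")

    subs = []
    for i, row in df.iterrows():
        where = f"{csv_path} row {i} (id={row['id']!r})"
        region_name = str(row["region"])
        if region_name not in regions:
            raise ValidationError(f"{where}: unknown region {region_name!r}")
        try:
            soil = SoilPClass(str(row["soil_p_class"]).upper())
            slope = SlopeClass(str(row["slope_class"]).upper())
        except ValueError as exc:
            raise ValidationError(f"{where}: {exc}") from None
        length = float(row["eligible_length_m"])
        baseline = float(row["baseline_p_transport_kg"])
        existing_area = float(row["existing_buffer_area_ha"])
        raw_w = row["existing_buffer_width_m"]
        existing_width = None if pd.isna(raw_w) or float(raw_w) == 0 else int(raw_w)
        if length < 0 or baseline < 0 or existing_area < 0:
            raise ValidationError(f"{where}: negative length, transport or area")
        ia = ImpactArea(
            id=f"{row['id']}-ia1",
            sub_catchment_id=str(row["id"]),
            area=length * IMPACT_DEPTH_M / 10_000.0,
            slope_class=slope,
            baseline_p_transport=baseline,
            eligible_length=length,
            existing_buffer_width=existing_width,
        )
        subs.append(
            SubCatchment(
                id=str(row["id"]),
                region=regions[region_name],
                soil_p_class=soil,
                impact_areas=(ia,),
                existing_buffer_area=existing_area,
            )
        )
    cid = catchment_id or Path(bundle_path).stem or "catchment"
    return Catchment(id=cid, sub_catchments=tuple(subs))


def save_catchment(catchment: Catchment, bundle_path: str | Path) -> Path:
    """Write a catchment bundle; inverse of :func:`load_catchment`.

    Each sub-catchment is flattened to one row; multi-impact-area
    sub-catchments are aggregated (summed lengths/transports, slope class
    of the dominant impact area by transport).
    """
    p = Path(bundle_path)
    if p.suffix != ".csv":
        p.mkdir(parents=True, exist_ok=True)
        p = p / "subcatchments.csv"
    rows = []
    for sc in catchment.sub_catchments:
        ias = sc.impact_areas
        dominant = max(ias, key=lambda ia: ia.baseline_p_transport) if ias else None
        rows.append(
            {
                "id": sc.id,
                "region": sc.region.name,
                "soil_p_class": sc.soil_p_class.value,
                "slope_class": dominant.slope_class.value if dominant else SlopeClass.SL1.value,
                "eligible_length_m": repr(sum(ia.eligible_length for ia in ias)),
                "baseline_p_transport_kg": repr(sum(ia.baseline_p_transport for ia in ias)),
                "existing_buffer_area_ha": repr(sc.existing_buffer_area),
                "existing_buffer_width_m": dominant.existing_buffer_width if dominant else None,
            }
        )
    pd.DataFrame(rows, columns=SUBCATCHMENT_COLUMNS).to_csv(p, index=False)
    return p


def rescale_transports(catchment: Catchment, factor: float) -> Catchment:
    """Return a copy with every impact area's baseline transport scaled by ``factor``."""
    if factor < 0:
        raise ValidationError("scale factor must be non-negative")
    subs = tuple(
        replace(
            sc,
            impact_areas=tuple(
                replace(ia, baseline_p_transport=ia.baseline_p_transport * factor)
                for ia in sc.impact_areas
            ),
        )
        for sc in catchment.sub_catchments
    )
    return Catchment(id=catchment.id, sub_catchments=subs)
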