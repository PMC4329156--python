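"""Phosphorus-reduction model for riparian buffer zones.

A buffer of width *w* on land of slope class *s* intercepts a fixed
fraction ``f(s, w)`` of the no-buffer baseline P transport of its impact
area.  The fractions come from leaching-model estimates of the
percentage reduction of P transport per width and slope class,
parameterized for one crop type and one climate region; they are a
configurable input so other coefficient sets can be swapped in.

The model is linear in the baseline transport, which also makes the
removal of existing-buffer effects an exact algebraic inverse:
``baseline = observed / (1 - f)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .catchment import (
    BUFFER_WIDTHS_M,
    Allocation,
    Catchment,
    SlopeClass,
    ValidationError,
    validate_width,
)

__all__ = [
    "ReductionTable",
    "load_reduction_table",
    "default_reduction_table",
    "reduction_fraction",
    "impact_reduction",
    "strip_existing_buffers",
    "allocation_reduction",
]

_SLOPE_ORDER = [SlopeClass.SL1, SlopeClass.SL2, SlopeClass.SL3]


@dataclass(frozen=True)
class ReductionTable:
    """Reduction fraction per (slope class, buffer width); all 15 cells required.

    Fractions are stored as positive decimals in (0, 1) — a cell of 0.46
    means the buffer removes 46 % of the impact area's baseline P
    transport.  Fractions must increase strictly with width within each
    slope class, and with slope class at each width (steeper land loses
    more particulate P, so a buffer there intercepts more).
    """

    fraction: Mapping[tuple[SlopeClass, int], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "fraction", dict(self.fraction))
        for s in _SLOPE_ORDER:
            for w in BUFFER_WIDTHS_M:
                if (s, w) not in self.fraction:
                    raise ValidationError(f"reduction table missing cell ({s.value}, {w} m)")
                f = self.fraction[(s, w)]
                if not 0.0 < f < 1.0:
                    raise ValidationError(
                        f"reduction fraction for ({s.value}, {w} m) must be in (0, 1), got {f}"
                    )
        for s in _SLOPE_ORDER:
            fs = [self.fraction[(s, w)] for w in BUFFER_WIDTHS_M]
            if any(b <= a for a, b in zip(fs, fs[1:])):
                raise ValidationError(f"fractions not strictly increasing in width for {s.value}")
        for w in BUFFER_WIDTHS_M:
            fs = [self.fraction[(s, w)] for s in _SLOPE_ORDER]
            if any(b <= a for a, b in zip(fs, fs[1:])):
                raise ValidationError(f"fractions not strictly increasing in slope class at {w} m")

    def __call__(self, width: float, slope: SlopeClass) -> float:
        return reduction_fraction(self, width, slope)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"slope_class": s.value, "width_m": w, "reduction_fraction": self.fraction[(s, w)]}
            for s in _SLOPE_ORDER
            for w in BUFFER_WIDTHS_M
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_reduction_table(path: str | Path) -> ReductionTable:
    """Read a reduction-fraction CSV: ``slope_class,width_m,reduction_fraction``."""
    df = pd.read_csv(path)
    needed = {"slope_class", "width_m", "reduction_fraction"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: reduction table needs columns {sorted(needed)}")
    frac: dict[tuple[SlopeClass, int], float] = {}
    for _, row in df.iterrows():
        key = (SlopeClass(str(row["slope_class"]).upper()), validate_width(row["width_m"]))
        if key in frac:
            raise ValidationError(f"{path}: duplicate cell {key}")
        frac[key] = float(row["reduction_fraction"])
    return ReductionTable(frac)


def default_reduction_table() -> ReductionTable:
    """The packaged default reduction fractions."""
    with resources.as_file(resources.files("buffercost.data") / "reduction_table.csv") as p:
        return load_reduction_table(p)


def reduction_fraction(table: ReductionTable, width: float, slope: SlopeClass) -> float:
    """Tabulated fraction of baseline P transport removed by a buffer."""
    w = validate_width(width)
    try:
        return table.fraction[(slope, w)]
    except KeyError:
        raise ValidationError(f"reduction table has no cell ({slope.value}, {w} m)") from None


def impact_reduction(
    baseline_kg: float, width: float, slope: SlopeClass, table: ReductionTable
) -> float:
    """P reduction (kg/yr) of a buffer on an impact area with the given baseline."""
    if baseline_kg < 0:
        raise ValidationError(f"baseline transport must be non-negative, got {baseline_kg}")
    return baseline_kg * reduction_fraction(table, width, slope)


def strip_existing_buffers(
    observed_kg: float,
    existing_width: float | None,
    slope: SlopeClass,
    table: ReductionTable,
) -> float:
    """Back out the no-buffer baseline from a transport observed behind an existing buffer.

    Identity when there is no existing buffer; otherwise the exact
    inverse of :func:`impact_reduction`, ``observed / (1 - f)``.
    """
    if observed_kg < 0:
        raise ValidationError(f"observed transport must be non-negative, got {observed_kg}")
    if existing_width is None:
        return observed_kg
    f = reduction_fraction(table, existing_width, slope)
    return observed_kg / (1.0 - f)


def allocation_reduction(
    catchment: Catchment, allocation: Allocation, table: ReductionTable
) -> float:
    """Total P reduction (kg/yr) of a buffer allocation over a catchment.

    Each allocated sub-catchment contributes the tabulated fraction of
    its eligible impact areas' baseline transports, scaled by the
    enrolled share of the potential area at the chosen width (partial
    enrolment thins all impact areas pro rata).
    """
    allocation.validate(catchment)
    total = 0.0
    for sid, (width, enrolled) in allocation.entries.items():
        sc = catchment[sid]
        if enrolled == 0:
            continue
        pot = sc.potential_area(width)
        share = min(enrolled / pot, 1.0)
        total += share * sum(
            impact_reduction(ia.baseline_p_transport, width, ia.slope_class, table)
            for ia in sc.impact_areas
            if ia.eligible
        )
    return total
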