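"""Annualized cost accounting for buffer-zone programs.

The annual cost of one hectare of buffer is the opportunity cost of the
land — proxied by the regional 90th-percentile agricultural leasing
price — plus a flat establishment/maintenance cost (sowing, seed,
labour, annualized over the 5-year commitment).  All figures are EUR
per hectare per year; there is no discounting, the accounting is
entirely in annual terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd

from .catchment import Allocation, Catchment, ProductionRegion, ValidationError

__all__ = [
    "CostSchedule",
    "load_cost_schedule",
    "default_cost_schedule",
    "annual_cost_per_ha",
    "allocation_cost",
    "cost_efficiency",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (report convention, e.g. 206.75 -> 207)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CostSchedule:
    """Per-region annual buffer cost: 90th-percentile leasing + establishment."""

    regions: Mapping[str, ProductionRegion]

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", dict(self.regions))
        if not self.regions:
            raise ValidationError("cost schedule has no regions")

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def __getitem__(self, name: str) -> ProductionRegion:
        try:
            return self.regions[name]
        except KeyError:
            raise ValidationError(
                f"unknown production region {name!r}; known: {sorted(self.regions)}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": r.name,
                "leasing_eur_per_ha": r.leasing_price,
                "establishment_eur_per_ha": r.establishment_cost,
            }
            for r in self.regions.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_cost_schedule(path: str | Path) -> CostSchedule:
    """Read a cost-schedule CSV: ``region,leasing_eur_per_ha,establishment_eur_per_ha``."""
    df = pd.read_csv(path)
    needed = {"region", "leasing_eur_per_ha", "establishment_eur_per_ha"}
    if not needed.issubset(df.columns):
        raise ValidationError(f"{path}: cost schedule needs columns {sorted(needed)}")
    regions = {}
    for _, row in df.iterrows():
        name = str(row["region"])
        if name in regions:
            raise ValidationError(f"{path}: duplicate region {name!r}")
        regions[name] = ProductionRegion(
            name=name,
            leasing_price=float(row["leasing_eur_per_ha"]),
            establishment_cost=float(row["establishment_eur_per_ha"]),
        )
    return CostSchedule(regions)


def default_cost_schedule() -> CostSchedule:
    """The packaged default schedule for the eight PO8 production regions."""
    with resources.as_file(resources.files("buffercost.data") / "cost_schedule.csv") as p:
        return load_cost_schedule(p)


def annual_cost_per_ha(schedule: CostSchedule, region: str) -> float:
    """Annual cost (EUR/ha/yr) of buffer land in ``region``: leasing + establishment."""
    return schedule[region].total_annual_cost


def allocation_cost(
    catchment: Catchment, allocation: Allocation, schedule: CostSchedule
) -> tuple[float, float]:
    """Total annual cost (EUR/yr) and total enrolled area (ha) of an allocation."""
    allocation.validate(catchment)
    total_cost = 0.0
    total_area = 0.0
    for sid, (_, enrolled) in allocation.entries.items():
        sc = catchment[sid]
        total_cost += enrolled * annual_cost_per_ha(schedule, sc.region.name)
        total_area += enrolled
    return total_cost, total_area


def cost_efficiency(total_cost: float, total_reduction: float) -> float:
    """Average cost of reduction (EUR per kg P removed per year).

    Raises for non-positive reduction rather than silently returning
    infinity.
    """
    if total_reduction <= 0:
        raise ValidationError(
            f"cost efficiency undefined: total reduction is {total_reduction} kg"
        )
    return total_cost / total_reduction
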