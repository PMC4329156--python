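"""Scenario construction, evaluation and cost-optimal allocation.

Three scenario kinds are supported, mirroring how buffer-zone programs
are compared in practice:

* ``EXISTING`` — the real enrolled areas (e.g. the subsidised 2008
  distribution), all accounted at one nominal width (10 m by national
  load-compilation convention, since subsidy records hold areas but not
  widths);
* ``UNIFORM_WIDTH`` — one width (typically 6 m) on the full potential
  area of every sub-catchment;
* ``COST_OPTIMAL`` — a targeted program: whole (sub-catchment, width)
  options are enrolled in order of increasing average cost of reduction
  (EUR per kg P) until a reduction target is met.

The allocator is a greedy heuristic for the underlying knapsack-like
problem; an exhaustive whole-option solver is provided for verification
at small instance sizes.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .catchment import (
    BUFFER_WIDTHS_M,
    Allocation,
    Catchment,
    ValidationError,
    validate_width,
)
from .costs import CostSchedule, allocation_cost, cost_efficiency, round_half_up
from .reduction import ReductionTable, allocation_reduction, impact_reduction

__all__ = [
    "ScenarioKind",
    "ScenarioSpec",
    "ScenarioResult",
    "ScenarioComparison",
    "evaluate",
    "existing_allocation",
    "uniform_allocation",
    "cost_optimal_allocation",
    "exhaustive_allocation",
    "build_allocation",
    "run_scenarios",
    "pct_delta",
]

#: Nominal width (m) at which existing subsidised areas are accounted.
EXISTING_NOMINAL_WIDTH_M = 10


class ScenarioKind(enum.Enum):
    EXISTING = "EXISTING"
    UNIFORM_WIDTH = "UNIFORM_WIDTH"
    COST_OPTIMAL = "COST_OPTIMAL"


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one scenario."""

    kind: ScenarioKind
    name: str = ""
    width: int | None = None  # UNIFORM_WIDTH; nominal width for EXISTING
    target_reduction_kg: float | None = None  # COST_OPTIMAL
    candidate_widths: tuple[int, ...] = BUFFER_WIDTHS_M  # COST_OPTIMAL
    allocation: Allocation | None = None  # EXISTING override

    def __post_init__(self) -> None:
        if self.kind is ScenarioKind.UNIFORM_WIDTH and self.width is None:
            raise ValidationError("UNIFORM_WIDTH scenario needs a width")
        if self.kind is ScenarioKind.COST_OPTIMAL and self.target_reduction_kg is None:
            raise ValidationError("COST_OPTIMAL scenario needs a target reduction")
        if not self.name:
            object.__setattr__(self, "name", self.kind.value.lower())


@dataclass(frozen=True)
class ScenarioResult:
    """The six summary quantities of a scenario evaluation (unrounded).

    ``cost_per_ha`` is area-weighted over regions; the three averages
    are exact ratio identities of the totals and are NaN (flagged by
    ``averages_defined``) when a denominator is zero.
    """

    buffer_area: float  # ha
    cost_per_ha: float  # EUR / ha / yr
    total_cost: float  # EUR / yr
    total_p_reduction: float  # kg P / yr
    avg_reduction_per_ha: float  # kg P / ha
    avg_cost_per_kg: float  # EUR / kg P

    @property
    def averages_defined(self) -> bool:
        return not (math.isnan(self.avg_reduction_per_ha) or math.isnan(self.avg_cost_per_kg))

    def rounded(self) -> dict[str, float]:
        """Report rounding: costs to whole EUR, average reduction to 2 decimals."""
        return {
            "buffer_area_ha": round_half_up(self.buffer_area, 1),
            "cost_per_ha_eur": round_half_up(self.cost_per_ha),
            "total_cost_eur": round_half_up(self.total_cost),
            "total_p_reduction_kg": round_half_up(self.total_p_reduction, 1),
            "avg_reduction_kg_per_ha": round_half_up(self.avg_reduction_per_ha, 2),
            "avg_cost_eur_per_kg": round_half_up(self.avg_cost_per_kg),
        }


def evaluate(
    catchment: Catchment,
    allocation: Allocation,
    schedule: CostSchedule,
    table: ReductionTable,
) -> ScenarioResult:
    """Evaluate an allocation: areas, costs, reduction and the ratio identities."""
    total_cost, total_area = allocation_cost(catchment, allocation, schedule)
    total_red = allocation_reduction(catchment, allocation, table)
    if total_area > 0:
        cost_per_ha = total_cost / total_area
        avg_red = total_red / total_area
    else:
        cost_per_ha = math.nan
        avg_red = math.nan
    avg_cost = cost_efficiency(total_cost, total_red) if total_red > 0 else math.nan
    return ScenarioResult(
        buffer_area=total_area,
        cost_per_ha=cost_per_ha,
        total_cost=total_cost,
        total_p_reduction=total_red,
        avg_reduction_per_ha=avg_red,
        avg_cost_per_kg=avg_cost,
    )


def existing_allocation(
    catchment: Catchment, width: int = EXISTING_NOMINAL_WIDTH_M
) -> Allocation:
    """Enrol each sub-catchment's existing buffer area at one nominal width."""
    w = validate_width(width)
    return Allocation(
        {
            sc.id: (w, sc.existing_buffer_area)
            for sc in catchment
            if sc.existing_buffer_area > 0
        }
    )


def uniform_allocation(catchment: Catchment, width: int) -> Allocation:
    """Enrol every sub-catchment at its full potential area for ``width``."""
    w = validate_width(width)
    return Allocation({sc.id: (w, sc.potential_area(w)) for sc in catchment})


@dataclass(frozen=True)
class _Option:
    """One whole enrolment option: a sub-catchment at full potential for a width."""

    sub_id: str
    width: int
    area: float  # ha
    reduction: float  # kg P / yr
    cost: float  # EUR / yr

    @property
    def avg_cost(self) -> float:
        return self.cost / self.reduction


def _options(
    catchment: Catchment,
    candidate_widths: Sequence[int],
    schedule: CostSchedule,
    table: ReductionTable,
) -> list[_Option]:
    opts = []
    for sc in catchment:
        for w in sorted({validate_width(w) for w in candidate_widths}):
            area = sc.potential_area(w)
            red = sum(
                impact_reduction(ia.baseline_p_transport, w, ia.slope_class, table)
                for ia in sc.impact_areas
                if ia.eligible
            )
            if area <= 0 or red <= 0:
                continue
            opts.append(
                _Option(sc.id, w, area, red, area * schedule[sc.region.name].total_annual_cost)
            )
    return opts


def _sort_key(o: _Option):
    # ascending avg cost, then descending reduction, then id, then width
    return (o.avg_cost, -o.reduction, o.sub_id, o.width)


def cost_optimal_allocation(
    catchment: Catchment,
    target_reduction_kg: float,
    candidate_widths: Sequence[int] = BUFFER_WIDTHS_M,
    schedule: CostSchedule | None = None,
    table: ReductionTable | None = None,
    nearest: bool = False,
) -> Allocation:
    """Greedy cost-effectiveness allocation meeting a P-reduction target.

    All (sub-catchment, width) options at full potential area are ranked
    by average cost of reduction and admitted in order — at most one
    width per sub-catchment — until the cumulative reduction reaches the
    target; the crossing option is taken whole.  With ``nearest=True``
    the chain stops at whichever of the last two cumulative reductions
    is closer to the target.

    Raises if the target exceeds what the admissible greedy chain can
    reach, reporting the maximum achievable reduction.
    """
    from .costs import default_cost_schedule
    from .reduction import default_reduction_table

    schedule = schedule or default_cost_schedule()
    table = table or default_reduction_table()
    if target_reduction_kg < 0:
        raise ValidationError("target reduction must be non-negative")
    if target_reduction_kg == 0:
        return Allocation({})

    opts = sorted(_options(catchment, candidate_widths, schedule, table), key=_sort_key)
    chosen: dict[str, _Option] = {}
    cum = 0.0
    for o in opts:
        if o.sub_id in chosen:
            continue
        chosen[o.sub_id] = o
        prev = cum
        cum += o.reduction
        if cum >= target_reduction_kg:
            if nearest and (cum - target_reduction_kg) > (target_reduction_kg - prev):
                del chosen[o.sub_id]
            break
    else:
        raise ValidationError(
            f"target {target_reduction_kg} kg unattainable: greedy chain reaches "
            f"only {cum:.3f} kg with candidate widths {tuple(candidate_widths)}"
        )
    return Allocation({sid: (o.width, o.area) for sid, o in chosen.items()})


def narrowest_attainable_width(
    catchment: Catchment,
    target_reduction_kg: float,
    table: ReductionTable,
    widths: Sequence[int] = BUFFER_WIDTHS_M,
) -> int:
    """Narrowest width whose full-coverage reduction meets the target.

    Because the per-kg cost of a buffer grows with width (area grows
    linearly but the reduction fraction is sublinear), the cheapest
    single-width program uses the narrowest width that can still reach
    the target; this picks it.  Raises if even the widest candidate
    cannot.
    """
    best = None
    for w in sorted({validate_width(w) for w in widths}):
        full = allocation_reduction(catchment, uniform_allocation(catchment, w), table)
        if full >= target_reduction_kg:
            return w
        best = full
    raise ValidationError(
        f"target {target_reduction_kg} kg unattainable: full coverage at the widest "
        f"candidate reaches only {best:.3f} kg"
    )


def exhaustive_allocation(
    catchment: Catchment,
    target_reduction_kg: float,
    candidate_widths: Sequence[int] = BUFFER_WIDTHS_M,
    schedule: CostSchedule | None = None,
    table: ReductionTable | None = None,
) -> Allocation:
    """Minimum-cost whole-option allocation by exhaustive enumeration.

    Considers every assignment of (none or one candidate width) per
    sub-catchment; intended as a verification oracle for small
    instances (cost is O((1+|widths|)^n)).
    """
    from .costs import default_cost_schedule
    from .reduction import default_reduction_table

    schedule = schedule or default_cost_schedule()
    table = table or default_reduction_table()
    if target_reduction_kg <= 0:
        return Allocation({})
    opts = _options(catchment, candidate_widths, schedule, table)
    by_sub: dict[str, list[_Option]] = {}
    for o in opts:
        by_sub.setdefault(o.sub_id, []).append(o)
    sub_ids = sorted(by_sub)
    best: tuple[float, float, dict[str, _Option]] | None = None
    choices = [[None, *by_sub[s]] for s in sub_ids]
    for combo in itertools.product(*choices):
        picked = [o for o in combo if o is not None]
        red = sum(o.reduction for o in picked)
        if red < target_reduction_kg:
            continue
        cost = sum(o.cost for o in picked)
        key = (cost, -red)
        if best is None or key < (best[0], -best[1]):
            best = (cost, red, {o.sub_id: o for o in picked})
    if best is None:
        raise ValidationError(
            f"target {target_reduction_kg} kg unattainable by any whole-option assignment"
        )
    return Allocation({sid: (o.width, o.area) for sid, o in best[2].items()})


def build_allocation(catchment: Catchment, spec: ScenarioSpec,
                     schedule: CostSchedule, table: ReductionTable) -> Allocation:
    """Materialize a spec into a concrete allocation for ``catchment``."""
    if spec.kind is ScenarioKind.EXISTING:
        if spec.allocation is not None:
            return spec.allocation
        return existing_allocation(catchment, spec.width or EXISTING_NOMINAL_WIDTH_M)
    if spec.kind is ScenarioKind.UNIFORM_WIDTH:
        assert spec.width is not None
        return uniform_allocation(catchment, spec.width)
    return cost_optimal_allocation(
        catchment, spec.target_reduction_kg, spec.candidate_widths, schedule, table
    )


def pct_delta(reference: float, value: float) -> float:
    """Percentage change of ``value`` vs ``reference``, rounded half-up to whole %."""
    if reference == 0:
        raise ValidationError("percentage delta undefined for zero reference")
    return round_half_up((value - reference) / reference * 100.0)


_DELTA_FIELDS = ["total_cost", "total_p_reduction", "avg_reduction_per_ha", "avg_cost_per_kg"]


@dataclass(frozen=True)
class ScenarioComparison:
    """Evaluated scenarios plus pairwise percentage deltas of the unrounded totals."""

    names: tuple[str, ...]
    results: tuple[ScenarioResult, ...]
    allocations: tuple[Allocation, ...] = field(repr=False, default=())

    def table(self, precision: str = "report") -> pd.DataFrame:
        """Six-column comparison table; ``precision`` is 'report' or 'full'."""
        rows = []
        for name, r in zip(self.names, self.results):
            row = r.rounded() if precision == "report" else {
                "buffer_area_ha": r.buffer_area,
                "cost_per_ha_eur": r.cost_per_ha,
                "total_cost_eur": r.total_cost,
                "total_p_reduction_kg": r.total_p_reduction,
                "avg_reduction_kg_per_ha": r.avg_reduction_per_ha,
                "avg_cost_eur_per_kg": r.avg_cost_per_kg,
            }
            rows.append({"scenario": name, **row})
        return pd.DataFrame(rows).set_index("scenario")

    def deltas(self) -> pd.DataFrame:
        """Pairwise deltas (whole %) computed from the unrounded quantities."""
        rows = []
        for i, j in itertools.combinations(range(len(self.results)), 2):
            a, b = self.results[i], self.results[j]
            row = {"comparison": f"{self.names[j]} vs {self.names[i]}"}
            for f in _DELTA_FIELDS:
                ref, val = getattr(a, f), getattr(b, f)
                row[f + "_pct"] = (
                    pct_delta(ref, val)
                    if ref and not (math.isnan(ref) or math.isnan(val))
                    else math.nan
                )
            rows.append(row)
        return pd.DataFrame(rows).set_index("comparison")


def run_scenarios(
    catchment: Catchment,
    specs: Sequence[ScenarioSpec],
    schedule: CostSchedule,
    table: ReductionTable,
) -> ScenarioComparison:
    """Build, evaluate and compare a list of scenarios on one catchment."""
    names, results, allocations = [], [], []
    for spec in specs:
        alloc = build_allocation(catchment, spec, schedule, table)
        names.append(spec.name)
        results.append(evaluate(catchment, alloc, schedule, table))
        allocations.append(alloc)
    return ScenarioComparison(tuple(names), tuple(results), tuple(allocations))
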