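"""Scenario evaluation, greedy cost-optimal allocation and comparisons."""

import math
from fractions import Fraction

import pytest

import buffercost as bc
from buffercost.catchment import Allocation, ValidationError
from buffercost.scenarios import (
    ScenarioKind,
    ScenarioSpec,
    narrowest_attainable_width,
    pct_delta,
)

from conftest import make_random_catchment


class TestEvaluate:
    def test_ratio_identities_from_scratch(self, demo_catchment, schedule, table):
        """The six quantities re-verified against an independent recomputation."""
        alloc = bc.uniform_allocation(demo_catchment, 6)
        r = bc.evaluate(demo_catchment, alloc, schedule, table)
        area = sum(a for _, a in alloc.entries.values())
        cost = sum(
            a * (demo_catchment[sid].region.leasing_price
                 + demo_catchment[sid].region.establishment_cost)
            for sid, (_, a) in alloc.entries.items()
        )
        red = sum(
            min(a / demo_catchment[sid].potential_area(w), 1.0)
            * sum(ia.baseline_p_transport * table.fraction[(ia.slope_class, w)]
                  for ia in demo_catchment[sid].impact_areas if ia.eligible)
            for sid, (w, a) in alloc.entries.items()
        )
        assert r.buffer_area == pytest.approx(area, rel=1e-12)
        assert r.total_cost == pytest.approx(cost, rel=1e-12)
        assert r.total_p_reduction == pytest.approx(red, rel=1e-12)
        assert r.cost_per_ha == pytest.approx(cost / area, rel=1e-12)
        assert r.avg_reduction_per_ha == pytest.approx(red / area, rel=1e-12)
        assert r.avg_cost_per_kg == pytest.approx(cost / red, rel=1e-12)

    def test_empty_allocation_flags_undefined(self, demo_catchment, schedule, table):
        r = bc.evaluate(demo_catchment, Allocation({}), schedule, table)
        assert r.buffer_area == r.total_cost == r.total_p_reduction == 0.0
        assert math.isnan(r.avg_cost_per_kg) and math.isnan(r.avg_reduction_per_ha)
        assert not r.averages_defined

    def test_single_region_cost_per_ha(self, demo_catchment, schedule, table):
        r = bc.evaluate(demo_catchment, bc.existing_allocation(demo_catchment), schedule, table)
        assert r.cost_per_ha == pytest.approx(234.0, rel=1e-12)


class TestUniformAllocation:
    def test_full_potential_everywhere(self, demo_catchment):
        alloc = bc.uniform_allocation(demo_catchment, 6)
        assert len(alloc) == len(demo_catchment)
        for sc in demo_catchment:
            w, a = alloc.entries[sc.id]
            assert w == 6 and a == pytest.approx(sc.potential_area(6), rel=1e-12)
        assert alloc.total_area == pytest.approx(
            sum(sc.potential_area(6) for sc in demo_catchment), rel=1e-12
        )

    def test_zero_potential_enrolled_at_zero(self, table):
        c = make_random_catchment(seed=1, n_sub=2)
        from dataclasses import replace

        zeroed = bc.Catchment(
            id=c.id,
            sub_catchments=(
                c.sub_catchments[0],
                replace(
                    c.sub_catchments[1],
                    impact_areas=tuple(
                        replace(ia, eligible_length=0.0, area=0.0)
                        for ia in c.sub_catchments[1].impact_areas
                    ),
                ),
            ),
        )
        alloc = bc.uniform_allocation(zeroed, 6)
        assert alloc.entries[zeroed.sub_catchments[1].id] == (6, 0.0)


class TestCostOptimal:
    def test_zero_target_empty(self, demo_catchment, schedule, table):
        alloc = bc.cost_optimal_allocation(demo_catchment, 0.0, (6,), schedule, table)
        assert len(alloc) == 0

    def test_target_met_and_chain_minimal(self, demo_catchment, schedule, table):
        target = 50.0
        alloc = bc.cost_optimal_allocation(demo_catchment, target, (10,), schedule, table)
        red = bc.allocation_reduction(demo_catchment, alloc, table)
        assert red >= target
        # the chain has no slack: dropping the last-admitted (most expensive
        # per kg) option leaves the target unmet
        per_option = {
            sid: (
                bc.allocation_cost(demo_catchment, Allocation({sid: wa}), schedule)[0],
                bc.allocation_reduction(demo_catchment, Allocation({sid: wa}), table),
            )
            for sid, wa in alloc.entries.items()
        }
        last = max(per_option, key=lambda sid: per_option[sid][0] / per_option[sid][1])
        assert red - per_option[last][1] < target

    def test_unattainable_reports_maximum(self, demo_catchment, schedule, table):
        with pytest.raises(ValidationError, match="unattainable"):
            bc.cost_optimal_allocation(demo_catchment, 1e6, (20,), schedule, table)

    def test_tie_break_prefers_lower_id(self, schedule, table):
        c = make_random_catchment(seed=2, n_sub=2, regions=["Nedre Norrland"])
        from dataclasses import replace

        # identical sub-catchments except id: equal average costs
        proto = c.sub_catchments[0]
        twin = replace(
            proto, id="r9",
            impact_areas=tuple(
                replace(ia, id="r9-ia1", sub_catchment_id="r9") for ia in proto.impact_areas
            ),
        )
        cc = bc.Catchment(id="tie", sub_catchments=(proto, twin))
        one_sub_red = bc.allocation_reduction(
            cc, Allocation({proto.id: (6, proto.potential_area(6))}), table
        )
        alloc = bc.cost_optimal_allocation(cc, one_sub_red * 0.5, (6,), schedule, table)
        assert list(alloc.entries) == [proto.id]

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_equals_exhaustive_when_reductions_uniform(self, schedule, table, seed):
        """With equal per-option reductions and distinct costs, greedy is optimal."""
        import numpy as np
        from dataclasses import replace

        rng = np.random.default_rng(seed)
        c = make_random_catchment(seed=seed + 50, n_sub=6)
        # equalize reductions: same baseline and slope everywhere
        subs = tuple(
            replace(
                sc,
                impact_areas=tuple(
                    replace(ia, baseline_p_transport=10.0, slope_class=bc.SlopeClass.SL3)
                    for ia in sc.impact_areas
                ),
            )
            for sc in c.sub_catchments
        )
        cc = bc.Catchment(id="uniform", sub_catchments=subs)
        target = 10.0 * 0.46 * rng.integers(1, 6)  # k whole options at 6 m
        greedy = bc.cost_optimal_allocation(cc, target, (6,), schedule, table)
        exact = bc.exhaustive_allocation(cc, target, (6,), schedule, table)
        g_cost, _ = bc.allocation_cost(cc, greedy, schedule)
        e_cost, _ = bc.allocation_cost(cc, exact, schedule)
        assert g_cost == pytest.approx(e_cost, rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_greedy_never_beats_exhaustive(self, schedule, table, seed):
        c = make_random_catchment(seed=seed + 80, n_sub=5)
        cap = sum(
            bc.allocation_reduction(c, Allocation({sc.id: (10, sc.potential_area(10))}), table)
            for sc in c
        )
        target = 0.4 * cap
        greedy = bc.cost_optimal_allocation(c, target, (6, 10), schedule, table)
        exact = bc.exhaustive_allocation(c, target, (6, 10), schedule, table)
        g_cost, _ = bc.allocation_cost(c, greedy, schedule)
        e_cost, _ = bc.allocation_cost(c, exact, schedule)
        assert bc.allocation_reduction(c, greedy, table) >= target
        assert bc.allocation_reduction(c, exact, table) >= target
        assert e_cost <= g_cost * (1 + 1e-12)


class TestNarrowestWidth:
    def test_picks_first_width_meeting_target(self, demo_catchment, table):
        full6 = bc.allocation_reduction(
            demo_catchment, bc.uniform_allocation(demo_catchment, 6), table
        )
        assert narrowest_attainable_width(demo_catchment, full6 * 0.99, table) == 6
        assert narrowest_attainable_width(demo_catchment, full6 * 1.01, table) == 10

    def test_unattainable_even_at_widest(self, demo_catchment, table):
        with pytest.raises(ValidationError, match="unattainable"):
            narrowest_attainable_width(demo_catchment, 1e6, table)


class TestComparison:
    def test_self_comparison_zero_deltas(self, demo_catchment, schedule, table):
        spec = ScenarioSpec(kind=ScenarioKind.UNIFORM_WIDTH, width=6, name="a")
        spec2 = ScenarioSpec(kind=ScenarioKind.UNIFORM_WIDTH, width=6, name="b")
        comp = bc.run_scenarios(demo_catchment, [spec, spec2], schedule, table)
        row = comp.deltas().iloc[0]
        assert (row == 0).all()

    def test_deltas_match_fraction_oracle(self, demo_catchment, schedule, table):
        specs = [
            ScenarioSpec(kind=ScenarioKind.EXISTING, name="s1", width=10),
            ScenarioSpec(kind=ScenarioKind.UNIFORM_WIDTH, name="s2", width=6),
        ]
        comp = bc.run_scenarios(demo_catchment, specs, schedule, table)
        a, b = comp.results
        # independent recomputation with exact rationals
        expect = round(
            Fraction(b.total_cost).__sub__(Fraction(a.total_cost))
            / Fraction(a.total_cost) * 100
        )
        got = comp.deltas().loc["s2 vs s1", "total_cost_pct"]
        assert got == pytest.approx(float(expect), abs=0.5)
        assert got == -32.0

    def test_pct_delta_half_up(self):
        assert pct_delta(100.0, 67.5) == -33.0  # ties round away from zero
        assert pct_delta(200.0, 200.0) == 0.0
        with pytest.raises(ValidationError):
            pct_delta(0.0, 5.0)

    def test_table_shape(self, demo_catchment, schedule, table):
        specs = [
            ScenarioSpec(kind=ScenarioKind.EXISTING, name="s1", width=10),
            ScenarioSpec(kind=ScenarioKind.UNIFORM_WIDTH, name="s2", width=6),
        ]
        comp = bc.run_scenarios(demo_catchment, specs, schedule, table)
        df = comp.table("report")
        assert list(df.columns) == [
            "buffer_area_ha",
            "cost_per_ha_eur",
            "total_cost_eur",
            "total_p_reduction_kg",
            "avg_reduction_kg_per_ha",
            "avg_cost_eur_per_kg",
        ]
        assert df.loc["s1", "total_cost_eur"] == 37_908.0
        assert df.loc["s1", "avg_cost_eur_per_kg"] == 390.0
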