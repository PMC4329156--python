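import numpy as np
import pytest
from hypothesis import settings

from buffercost import (
    SlopeClass,
    SoilPClass,
    default_cost_schedule,
    default_reduction_table,
    svarta_like_catchment,
)
from buffercost.catchment import Catchment, ImpactArea, SubCatchment

settings.register_profile("ci", derandomize=True, max_examples=100, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    return default_reduction_table()


@pytest.fixture(scope="session")
def schedule():
    return default_cost_schedule()


@pytest.fixture(scope="session")
def demo_catchment(table):
    """Calibrated synthetic catchment (13 sub-catchments, seed 1)."""
    return svarta_like_catchment(seed=1, table=table)


def make_random_catchment(seed: int, n_sub: int = 6, regions=None) -> Catchment:
    """Small random catchment for oracle comparisons (multi-region, mixed slopes)."""
    rng = np.random.default_rng(seed)
    schedule = default_cost_schedule()
    region_names = regions or list(schedule.regions)
    slopes = list(SlopeClass)
    subs = []
    for i in range(n_sub):
        sid = f"r{i}"
        length = float(rng.uniform(500, 20_000))
        ia = ImpactArea(
            id=f"{sid}-ia1",
            sub_catchment_id=sid,
            area=length * 60 / 1e4,
            slope_class=slopes[int(rng.integers(3))],
            baseline_p_transport=float(rng.uniform(0.5, 30.0)),
            eligible_length=length,
        )
        subs.append(
            SubCatchment(
                id=sid,
                region=schedule[region_names[int(rng.integers(len(region_names)))]],
                soil_p_class=SoilPClass.HIGH,
                impact_areas=(ia,),
                existing_buffer_area=float(rng.uniform(0, length / 1000)),
            )
        )
    return Catchment(id=f"random-{seed}", sub_catchments=tuple(subs))
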