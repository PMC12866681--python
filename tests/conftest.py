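import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from cuetrade import (
    CohortSpec,
    ObserverSpec,
    PsychometricParams,
    ResponseTable,
    simulate_cohort,
)
from cuetrade.model import _p_right


def make_binomial_table(
    params: PsychometricParams,
    n_per_cell: int,
    seed: int,
    animal_id: str = "obs",
) -> ResponseTable:
    """Response table with binomial counts drawn directly from the model."""
    rng = np.random.default_rng(seed)
    table = ResponseTable(animal_id=animal_id)
    counts = {}
    for ild in table.ild_grid:
        for itd in table.itd_grid:
            if itd == 0 and ild == 0:
                continue
            p = float(_p_right(params, itd, ild))
            counts[(itd, ild)] = (int(rng.binomial(n_per_cell, p)), n_per_cell)
    return ResponseTable(animal_id=animal_id, counts=counts)


@pytest.fixture
def tiny_cohort_spec() -> CohortSpec:
    """Two strong observers, small session schedule — fast end-to-end runs."""
    return CohortSpec(
        observers=(
            ObserverSpec("a1", PsychometricParams(0.30, 0.015, 0.0, 0.06, 0.0)),
            ObserverSpec("a2", PsychometricParams(0.18, 0.012, 0.05, 0.10, 0.02)),
        ),
        n_sessions=3,
        trials_per_session=120,
        seed=11,
    )


@pytest.fixture
def tiny_sessions(tiny_cohort_spec):
    return simulate_cohort(tiny_cohort_spec)
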