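import numpy as np
import pandas as pd
import pytest

from transmix import (
    GroupStructure,
    ScenarioParams,
    TransmissionTree,
    discretised_gamma_pmf,
)


@pytest.fixture
def toy_tree() -> TransmissionTree:
    """Four-case chain: A imports into g1, infects B (g1) and C (g2);
    B infects D (g1)."""
    return TransmissionTree(pd.DataFrame({
        "case_id": ["A", "B", "C", "D"],
        "group": ["g1", "g1", "g2", "g1"],
        "onset_day": [0, 3, 4, 6],
        "infector_id": [None, "A", "A", "B"],
    }))


@pytest.fixture
def toy_groups() -> GroupStructure:
    return GroupStructure(("g1", "g2"), np.array([50, 50]))


def make_scenario(
    group_sizes=(100, 100),
    deltas=(0.0, 0.0),
    r0s=(2.0, 2.0),
    initial_imports=(2, 2),
    gt_mean=5.0,
    gt_sd=2.0,
    inc_mean=4.0,
    inc_sd=2.0,
    horizon=365,
    **kw,
) -> ScenarioParams:
    return ScenarioParams(
        group_sizes=group_sizes,
        deltas=deltas,
        r0s=r0s,
        initial_imports=initial_imports,
        generation_time_pmf=discretised_gamma_pmf(gt_mean, gt_sd, zero_lag=False),
        incubation_pmf=discretised_gamma_pmf(inc_mean, inc_sd),
        horizon=horizon,
        **kw,
    )


@pytest.fixture
def scenario_factory():
    return make_scenario
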