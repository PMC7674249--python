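import numpy as np
import pandas as pd
import pytest

from jointmarg.fit import FitResult, ParameterTransform
from jointmarg.model_core import (
    BaselineHazardBasis,
    JointModelSpec,
    ParameterSet,
    parse_formula,
    validate_dataset,
)
from jointmarg.simulate import scenario_preset, simulate_dataset


def make_spec(
    fixed="1 + time + trt:time",
    random="1 + time",
    baseline=("trt",),
    association="value",
    degree=3,
    interior=(14.0 / 3.0, 28.0 / 3.0),
    boundary=(0.0, 14.0),
    treatment="trt",
):
    return JointModelSpec(
        fixed_terms=parse_formula(fixed),
        random_terms=parse_formula(random),
        baseline_terms=baseline,
        association=association,
        bh_basis=BaselineHazardBasis(degree, interior, boundary),
        treatment_name=treatment,
    )


def truth_fit(spec, params) -> FitResult:
    """FitResult wrapper around known parameters (no fitting)."""
    tr = ParameterTransform(spec.bh_basis.size, spec.p_beta, spec.q_gamma, spec.dim_b)
    return FitResult(
        params=params, spec=spec, vcov_unconstrained=None, transform=tr,
        loglik=0.0, converged=True, n_quad=9,
    )


@pytest.fixture
def tiny_dataset():
    long = pd.DataFrame(
        {
            "id": [1, 1, 1, 2, 2, 2],
            "time": [0.0, 1.0, 2.0, 0.0, 1.0, 3.0],
            "y": [1.0, 0.9, 1.1, 1.2, 1.0, 0.8],
            "trt": [0.0] * 3 + [1.0] * 3,
        }
    )
    surv = pd.DataFrame(
        {"id": [1, 2], "time": [4.0, 5.0], "event": [1, 0], "trt": [0.0, 1.0]}
    )
    return validate_dataset(long, surv)


@pytest.fixture(scope="session")
def scen2():
    return scenario_preset("II", n_subjects=60, seed=5)


@pytest.fixture(scope="session")
def scen2_data(scen2):
    return simulate_dataset(scen2)
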