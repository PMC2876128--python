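import numpy as np
import pytest

from crpcna import (
    CrpModel,
    EmissionParams,
    ProbeSeries,
    StateSpace,
    TransitionParams,
    default_model,
    enumerate_patterns,
)


@pytest.fixture
def model5() -> CrpModel:
    """Default 5-state SNP-array model (m=4)."""
    return default_model()


@pytest.fixture
def model3() -> CrpModel:
    """Small 3-state model with well-separated means, handy for oracles."""
    return CrpModel(
        states=StateSpace(labels=(1, 2, 3), normal=2),
        emission=EmissionParams(
            mean={1: -0.45, 2: 0.0, 3: 0.38},
            sd={1: 0.15, 2: 0.15, 3: 0.15},
        ),
        transition=TransitionParams(),
        patterns=enumerate_patterns(4),
    )


def make_series(values, spacing_bp=10_000, chromosome="chrT") -> ProbeSeries:
    values = np.asarray(values, dtype=float)
    pos = np.arange(len(values), dtype=np.int64) * spacing_bp + 1_000
    ids = np.array([f"m{i:04d}" for i in range(len(values))], dtype=object)
    return ProbeSeries(chromosome=chromosome, ids=ids, pos_bp=pos, value=values)


@pytest.fixture
def series_factory():
    return make_series
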