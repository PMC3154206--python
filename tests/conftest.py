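import numpy as np
import pytest

from fcrci import ExpressionMatrix, GroupAssignment


def make_dataset(rng, m=50, n1=5, n2=5, effects=None, sigmas=None):
    """Random two-group dataset: gene j ~ N(0, sigma_j^2), group 2 shifted."""
    sigmas = np.ones(m) if sigmas is None else np.asarray(sigmas, float)
    truth = np.zeros(m)
    if effects:
        for j, eff in effects.items():
            truth[j] = eff
    values = rng.normal(0.0, 1.0, size=(m, n1 + n2)) * sigmas[:, None]
    values[:, n1:] += truth[:, None]
    expr = ExpressionMatrix(
        values=values,
        gene_ids=tuple(f"g{j}" for j in range(m)),
        sample_ids=tuple(f"s{i}" for i in range(n1 + n2)),
    )
    groups = GroupAssignment(labels=np.r_[np.ones(n1, int), np.full(n2, 2)])
    return expr, groups, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_dataset(rng):
    return make_dataset(rng, m=50, n1=5, n2=5)
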