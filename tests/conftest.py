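import numpy as np
import pytest

from cpmkit.core import ConnectomeStack, CovariateTable, Outcome
from cpmkit.design import assemble_design


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_symmetric_stack(M, N, rng, scale=0.3):
    """Random symmetric zero-diagonal stack shaped (M, M, N)."""
    values = np.zeros((M, M, N))
    for s in range(N):
        a = rng.normal(0, scale, size=(M, M))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        values[:, :, s] = a
    return ConnectomeStack(values, tuple(f"s{i}" for i in range(N)))


@pytest.fixture
def small_stack(rng):
    return make_symmetric_stack(M=6, N=12, rng=rng)


def centered_unit_design(n, K, J, rng):
    """Design whose edge columns are centered with unit population sd.

    Internal standardization is then the identity, so fits can be compared
    directly against unstandardized closed forms.
    """
    A = rng.normal(size=(n, K))
    A = (A - A.mean(axis=0)) / A.std(axis=0)
    cov = None
    if J:
        C = rng.normal(size=(n, J))
        C -= C.mean(axis=0)
        cov = CovariateTable(C, tuple(f"c{j}" for j in range(J)))
    return assemble_design(A, cov), A, (cov.values if cov else None)


@pytest.fixture
def gaussian_problem(rng):
    design, A, C = centered_unit_design(n=80, K=5, J=2, rng=rng)
    beta_true = np.array([0.5, -0.4, 0.0, 0.3, 0.0])
    y = A @ beta_true + C @ [1.0, -0.5] + rng.normal(0, 0.3, size=80)
    y -= y.mean()
    return design, Outcome.continuous(y)
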