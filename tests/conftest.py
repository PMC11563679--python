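import numpy as np
import pytest

from clonefix import CohortConfig, MoranParameters


@pytest.fixture
def default_cohort() -> CohortConfig:
    return CohortConfig(rng_seed=123)


@pytest.fixture
def noiseless_degenerate_cohort() -> CohortConfig:
    """Point-mass healthy rates and a collapsed fitness band: every
    downstream estimate must be recovered exactly."""
    return CohortConfig(
        healthy_sd_no_cxcl8=0.0,
        healthy_sd_cxcl8=0.0,
        cmml_fitness_low=1.5,
        cmml_fitness_high=1.5,
        noise_cv=0.0,
        rng_seed=5,
    )


def dense_fixation_probability(N: int, r: float, k0: int = 1) -> float:
    """Independent oracle: hitting probability of state N from k0 by a dense
    linear solve of the full (N+1)-state absorbing-chain system."""
    P = np.zeros((N + 1, N + 1))
    for k in range(N + 1):
        if k in (0, N):
            P[k, k] = 1.0
            continue
        denom = r * k + (N - k)
        up = (r * k / denom) * ((N - k) / N)
        down = ((N - k) / denom) * (k / N)
        P[k, k + 1] = up
        P[k, k - 1] = down
        P[k, k] = 1.0 - up - down
    # phi = P phi with phi(0)=0, phi(N)=1 -> solve on interior states
    interior = np.arange(1, N)
    A = np.eye(N - 1) - P[np.ix_(interior, interior)]
    b = P[interior, N]
    phi = np.linalg.solve(A, b)
    return float(phi[k0 - 1])


def dense_conditional_time(N: int, r: float, k0: int = 1) -> float:
    """Independent oracle: expected iterations to fixation conditioned on
    fixation, via a dense solve of the h-transformed chain (h from the
    dense hitting-probability solve above, not the closed form)."""
    phi = np.array([0.0] + [dense_fixation_probability(N, r, k) for k in range(1, N)] + [1.0])
    interior = np.arange(1, N)
    A = np.zeros((N - 1, N - 1))
    b = np.ones(N - 1)
    for i, k in enumerate(interior):
        denom = r * k + (N - k)
        up = (r * k / denom) * ((N - k) / N) * phi[k + 1] / phi[k]
        down = ((N - k) / denom) * (k / N) * phi[k - 1] / phi[k]
        A[i, i] = up + down
        if k + 1 < N:
            A[i, i + 1] = -up
        if k - 1 >= 1:
            A[i, i - 1] = -down
    t = np.linalg.solve(A, b)
    return float(t[k0 - 1])
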