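"""Two-type Moran process on a fixed stem-cell compartment.

The compartment holds ``N`` cells. At every iteration one cell divides
(chosen with probability proportional to its fitness) and one cell dies
(chosen uniformly); divider and dier may coincide, so the population size
never changes. With a single mutant type of relative fitness ``r`` against
a wild-type of fitness 1, the process reduces exactly to a birth-death
chain on the mutant count ``k`` with absorbing states 0 and ``N``:

    p_up(k)   = [r k / (r k + N - k)] * [(N - k) / N]
    p_down(k) = [(N - k) / (r k + N - k)] * [k / N]
    p_stay(k) = 1 - p_up(k) - p_down(k)

Self-replacement iterations (``p_stay``) count as iterations; this matters
because calendar time is attached per iteration (one iteration spans
``1 / (division_rate * N)`` years).

Production simulation runs on the reduced ``k``-chain. An agent-wise
implementation that tracks an explicit fitness vector of all ``N`` cells is
provided as a distributional oracle for small ``N`` only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .errors import InvalidParameterError

__all__ = [
    "MoranParameters",
    "FixationEstimate",
    "step_probabilities",
    "simulate_trajectory",
    "simulate_fixation",
    "simulate_agentwise",
    "exact_fixation_probability",
    "exact_conditional_fixation_time",
    "exact_unconditional_absorption_time",
]

#: Baseline human HSC compartment size used throughout the analysis.
DEFAULT_N = 100_000
#: Literature band for the HSC compartment size.
N_BOUNDS = (25_000, 1_300_000)
#: Baseline symmetric self-renewal division rate, divisions/cell/year.
DEFAULT_DIVISION_RATE = 1.0

EXACT_SOLVER_LIMIT = 2_000
AGENTWISE_LIMIT = 64


@dataclass(frozen=True)
class MoranParameters:
    """Parameters of the two-type Moran process.

    Parameters
    ----------
    N
        Compartment size (number of stem cells), >= 2.
    r
        Relative fitness of the mutant lineage (wild-type fitness is 1).
    division_rate
        Divisions per cell per year; sets the calendar-time scale of one
        iteration, ``1 / (division_rate * N)`` years.
    initial_mutants
        Mutant count at time 0. The headline analysis uses a single
        founder cell; 0 and ``N`` are permitted as (absorbing) boundary
        starts for the trajectory contract.
    """

    N: int
    r: float
    division_rate: float = DEFAULT_DIVISION_RATE
    initial_mutants: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 2):
            raise InvalidParameterError(f"N must be an integer >= 2, got {self.N!r}")
        if not (self.r > 0 and math.isfinite(self.r)):
            raise InvalidParameterError(f"r must be a positive finite number, got {self.r!r}")
        if not self.division_rate > 0:
            raise InvalidParameterError(
                f"division_rate must be positive, got {self.division_rate!r}"
            )
        if not (0 <= self.initial_mutants <= self.N):
            raise InvalidParameterError(
                f"initial_mutants must lie in [0, N], got {self.initial_mutants!r}"
            )


@dataclass(frozen=True)
class FixationEstimate:
    """Result of a fixation computation.

    ``standard_error`` fields are populated only by stochastic methods
    (``monte_carlo``, ``agentwise``); exact and analytic methods leave them
    at 0 / None. ``mean_conditional_iterations`` is the expected number of
    Moran iterations to absorption at ``N`` among runs that fix, i.e. the
    conditional fixation time.
    """

    method: str
    fixation_probability: float | None
    mean_conditional_iterations: float | None
    probability_se: float | None = None
    iterations_se: float | None = None
    replicates: int | None = None
    rng_seed: int | None = None
    params: MoranParameters | None = field(default=None, repr=False)


def _transition_arrays(N: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectors p_up[k], p_down[k] for k = 0..N (absorbing boundaries)."""
    k = np.arange(N + 1, dtype=float)
    denom = r * k + (N - k)
    p_up = (r * k / denom) * ((N - k) / N)
    p_down = ((N - k) / denom) * (k / N)
    p_up[0] = p_up[N] = 0.0
    p_down[0] = p_down[N] = 0.0
    return p_up, p_down


def step_probabilities(params: MoranParameters, k: int) -> tuple[float, float, float]:
    """One-step probabilities (p_up, p_down, p_stay) at mutant count ``k``.

    ``k = 0`` and ``k = N`` are absorbing: both move probabilities are 0.
    """
    N, r = params.N, params.r
    if not (0 <= k <= N):
        raise InvalidParameterError(f"mutant count k={k} outside [0, {N}]")
    if k == 0 or k == N:
        return 0.0, 0.0, 1.0
    denom = r * k + (N - k)
    p_up = (r * k / denom) * ((N - k) / N)
    p_down = ((N - k) / denom) * (k / N)
    return p_up, p_down, 1.0 - p_up - p_down


def simulate_trajectory(
    params: MoranParameters, rng_seed: int | np.random.Generator
) -> tuple[int, int]:
    """Run one trajectory of the mutant-count chain to absorption.

    Returns ``(absorbed_at, iterations)`` where ``absorbed_at`` is 0
    (extinction) or ``N`` (fixation) and ``iterations`` counts every Moran
    event including self-replacements. Self-replacement runs are skipped in
    a single geometric draw, which leaves the iteration count distribution
    exact. A boundary start absorbs immediately in 0 iterations.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    N, r = params.N, params.r
    k = params.initial_mutants
    if k == 0 or k == N:
        return k, 0
    p_up, p_down = _transition_arrays(N, r)
    p_move = p_up + p_down
    up_frac = np.divide(p_up, p_move, out=np.zeros_like(p_up), where=p_move > 0)
    iterations = 0
    while 0 < k < N:
        iterations += int(rng.geometric(p_move[k]))
        k += 1 if rng.random() < up_frac[k] else -1
    return k, iterations


def simulate_fixation(
    params: MoranParameters, replicates: int, rng_seed: int
) -> FixationEstimate:
    """Monte-Carlo fixation probability and conditional fixation time.

    Runs ``replicates`` independent trajectories of the mutant-count chain
    (vectorised across replicates, with self-replacement runs collapsed
    into geometric draws). If no replicate fixes, the conditional time is
    reported as None with a warning.
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    rng = np.random.default_rng(rng_seed)
    N, r = params.N, params.r
    p_up, p_down = _transition_arrays(N, r)
    p_move = p_up + p_down
    up_frac = np.divide(p_up, p_move, out=np.zeros_like(p_up), where=p_move > 0)

    state = np.full(replicates, params.initial_mutants, dtype=np.int64)
    iterations = np.zeros(replicates, dtype=np.int64)
    active = (state > 0) & (state < N)
    while active.any():
        idx = np.flatnonzero(active)
        k = state[idx]
        iterations[idx] += rng.geometric(p_move[k])
        move_up = rng.random(idx.size) < up_frac[k]
        k = k + np.where(move_up, 1, -1)
        state[idx] = k
        active[idx] = (k > 0) & (k < N)

    fixed = state == N
    n_fixed = int(fixed.sum())
    p_hat = n_fixed / replicates
    p_se = math.sqrt(p_hat * (1.0 - p_hat) / replicates)
    if n_fixed == 0:
        warnings.warn(
            "no replicate reached fixation; conditional fixation time is undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        t_hat, t_se = None, None
    else:
        t_fix = iterations[fixed].astype(float)
        t_hat = float(t_fix.mean())
        t_se = float(t_fix.std(ddof=1) / math.sqrt(n_fixed)) if n_fixed > 1 else 0.0
    return FixationEstimate(
        method="monte_carlo",
        fixation_probability=p_hat,
        mean_conditional_iterations=t_hat,
        probability_se=p_se,
        iterations_se=t_se,
        replicates=replicates,
        rng_seed=rng_seed if isinstance(rng_seed, int) else None,
        params=params,
    )


def simulate_agentwise(
    params: MoranParameters, rng_seed: int | np.random.Generator
) -> tuple[int, int]:
    """Literal N-cell simulation: explicit fitness vector, divider sampled
    proportionally to fitness, dier sampled uniformly (may coincide).

    Distributionally identical to :func:`simulate_trajectory`; intended
    only as a small-``N`` test oracle for the chain reduction.
    """
    N, r = params.N, params.r
    if N > AGENTWISE_LIMIT:
        raise InvalidParameterError(
            f"agentwise simulation limited to N <= {AGENTWISE_LIMIT}; "
            "use simulate_trajectory for larger compartments"
        )
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    is_mutant = np.zeros(N, dtype=bool)
    is_mutant[: params.initial_mutants] = True
    fitness = np.where(is_mutant, r, 1.0)
    k = params.initial_mutants
    iterations = 0
    while 0 < k < N:
        iterations += 1
        cum = np.cumsum(fitness)
        divider = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        dier = int(rng.integers(N))
        k += int(is_mutant[divider]) - int(is_mutant[dier])
        is_mutant[dier] = is_mutant[divider]
        fitness[dier] = fitness[divider]
    return (N if k == N else 0), iterations


def _log_r_phi(N: int, r: float, k: np.ndarray | int) -> np.ndarray | float:
    """Fixation (hitting-N) probability from mutant count k, evaluated
    stably for r near 1 and large N via expm1 identities."""
    if r == 1.0:
        return np.asarray(k, dtype=float) / N
    log_r = math.log(r)
    return np.expm1(-np.asarray(k, dtype=float) * log_r) / math.expm1(-N * log_r)


def exact_fixation_probability(params: MoranParameters) -> float:
    """Exact probability that the mutant lineage takes over the compartment.

    For a single founder this is ``(1 - 1/r) / (1 - 1/r^N)`` (``1/N`` in the
    neutral case); general starting counts use the standard ratio of partial
    geometric sums, evaluated in a numerically stable form.
    """
    N, r, k = params.N, params.r, params.initial_mutants
    if k == 0:
        return 0.0
    if k == N:
        return 1.0
    if r == 1.0:
        return k / N
    return float(_log_r_phi(N, r, k))


def _conditioned_tridiagonal(N: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Doob h-transform of the chain on interior states 1..N-1, conditioned
    on absorption at N. Returns (p_up_tilde, p_down_tilde) aligned to k=1..N-1."""
    p_up, p_down = _transition_arrays(N, r)
    k = np.arange(N + 1)
    phi = np.asarray(_log_r_phi(N, r, k), dtype=float)
    pu = p_up[1:N] * phi[2 : N + 1] / phi[1:N]
    pd = p_down[1:N] * phi[0 : N - 1] / phi[1:N]  # phi[0]=0 kills the k=1 down-move
    return pu, pd


def exact_conditional_fixation_time(params: MoranParameters) -> float:
    """Exact expected iterations to fixation, conditioned on fixation.

    First-step analysis on the h-transformed mutant-count chain: the
    conditioned transition probabilities are
    ``p~_up(k) = p_up(k) phi(k+1)/phi(k)`` and
    ``p~_down(k) = p_down(k) phi(k-1)/phi(k)`` with ``phi`` the fixation
    probability, and the expected-time system is tridiagonal in k. Stay
    iterations are counted. Dense in memory as O(N); limited to
    ``N <= EXACT_SOLVER_LIMIT``.
    """
    N = params.N
    if N > EXACT_SOLVER_LIMIT:
        raise InvalidParameterError(
            f"exact conditional solver limited to N <= {EXACT_SOLVER_LIMIT}; "
            "use simulate_fixation or the analytic approximation for larger N"
        )
    k0 = params.initial_mutants
    if k0 == N:
        return 0.0
    if k0 == 0:
        raise InvalidParameterError("fixation from 0 mutants is impossible")
    pu, pd = _conditioned_tridiagonal(N, params.r)
    n = N - 1
    ab = np.zeros((3, n))
    ab[0, 1:] = -pu[:-1]
    ab[1, :] = pu + pd
    ab[2, :-1] = -pd[1:]
    t = solve_banded((1, 1), ab, np.ones(n))
    return float(t[k0 - 1])


def exact_unconditional_absorption_time(params: MoranParameters) -> float:
    """Exact expected iterations to absorption at either boundary.

    Companion quantity to :func:`exact_conditional_fixation_time`, used in
    the approximation-quality report to identify which expectation the
    analytic formula approximates.
    """
    N = params.N
    if N > EXACT_SOLVER_LIMIT:
        raise InvalidParameterError(f"exact solver limited to N <= {EXACT_SOLVER_LIMIT}")
    k0 = params.initial_mutants
    if k0 in (0, N):
        return 0.0
    p_up, p_down = _transition_arrays(N, params.r)
    pu, pd = p_up[1:N], p_down[1:N]
    n = N - 1
    ab = np.zeros((3, n))
    ab[0, 1:] = -pu[:-1]
    ab[1, :] = pu + pd
    ab[2, :-1] = -pd[1:]
    t = solve_banded((1, 1), ab, np.ones(n))
    return float(t[k0 - 1])
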