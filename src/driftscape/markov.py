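"""Origin-fixation Markov chains on two-peak fitness landscapes.

In the weak-mutation/strong-selection regime a population is essentially
monomorphic and evolution reduces to a Markov chain over genotypes: a
mutation is proposed at rate ``u_ij`` and fixes with probability
``pi_ij``.  This module builds that chain for a family of landscapes with
one *drift-fragile* peak (fitness ``1 + s``, reached through ``n`` small
beneficial steps of size ``s/n``) and one *drift-robust* peak (fitness
``1 + s - eps``, reached through a single large step), solves for the
stationary distribution, and locates the critical population size at
which the two peaks are equally occupied.

Edge selection coefficients are additive (Malthusian) increments of the
fitness ladder, so the ratio of forward and backward fixation
probabilities obeys ``pi_ij / pi_ji = exp(2 s_ij (N - 1))`` exactly for
both supported fixation kernels; the closed-form critical size

    N_crit = 1 + (n - 1) * log(1/kappa) / (2 * eps),   kappa = u_b / s_bar

is then an identity of the chain, not an approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FixationKind",
    "FixationModel",
    "MarkovLandscapeSpec",
    "TransitionMatrix",
    "StationaryResult",
    "fixation_probability",
    "fixation_ratio",
    "dfe_mutation_rates",
    "build_transition_matrix",
    "stationary_distribution",
    "occupancy_ratio",
    "n_crit_closed",
    "n_crit_numeric",
    "solve_landscape",
]

_NEUTRAL_TOL = 1e-12


class FixationKind(str, Enum):
    """Which fixation-probability kernel to use."""

    kimura = "kimura"
    sella_hirsh = "sella_hirsh"


@dataclass(frozen=True)
class FixationModel:
    """A fixation kernel together with the (real-valued) population size."""

    kind: FixationKind = FixationKind.kimura
    N: float = 100.0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"population size must be >= 1, got {self.N}")
        object.__setattr__(self, "kind", FixationKind(self.kind))


@dataclass(frozen=True)
class MarkovLandscapeSpec:
    """Parameters of the two-peak landscape chain.

    Parameters
    ----------
    s:
        Selection coefficient of the drift-fragile peak (> 0).
    epsilon:
        Fitness deficit of the drift-robust peak, 0 < epsilon < s.
    n:
        Number of beneficial steps to the fragile peak (n >= 2).
    u_b:
        Likelihood that a mutation is beneficial.
    s_bar:
        Mean effect of the exponential beneficial-effect distribution
        ``rho(x) = exp(-x / s_bar) / s_bar``.
    mu:
        Overall (deleterious/back) mutation rate per genotype per
        generation.
    use_epsilon_in_u14:
        If True the robust up-step rate is ``p_b(s - epsilon)`` instead
        of the default small-epsilon approximation ``p_b(s)``.  The
        default keeps ``R(N_crit) = 1`` exact.
    """

    s: float = 0.1
    epsilon: float = 0.05
    n: int = 2
    u_b: float = 1e-3
    s_bar: float = 0.1
    mu: float = 0.01
    use_epsilon_in_u14: bool = False

    def __post_init__(self) -> None:
        if not (self.s > 0 and self.s_bar > 0 and self.u_b > 0 and self.mu > 0):
            raise ValueError("all rates and effects must be strictly positive")
        if not (0 < self.epsilon < self.s):
            raise ValueError(f"need 0 < epsilon < s, got epsilon={self.epsilon}, s={self.s}")
        if self.n < 2:
            raise ValueError(f"need n >= 2 fragile steps, got n={self.n}")
        if self.kappa >= 1:
            raise ValueError(
                f"kappa = u_b/s_bar = {self.kappa:g} >= 1 violates the model "
                "assumption that beneficial mutations are rarer than their mean effect"
            )

    @property
    def kappa(self) -> float:
        return self.u_b / self.s_bar

    def rho(self, x: float) -> float:
        """Exponential density of beneficial effects."""
        return math.exp(-x / self.s_bar) / self.s_bar

    def p_b(self, x: float) -> float:
        """Beneficial mutation rate toward an effect-``x`` genotype."""
        return self.u_b * self.mu * self.rho(x)

    @property
    def state_labels(self) -> list[str]:
        fragile = [f"fragile_{k}" for k in range(1, self.n + 1)]
        return ["wild", *fragile, "robust"]

    @property
    def fitness(self) -> np.ndarray:
        """Fitness vector: 1, 1 + k s/n (k=1..n), 1 + s - epsilon."""
        w = [1.0] + [1.0 + k * self.s / self.n for k in range(1, self.n + 1)] + [
            1.0 + self.s - self.epsilon
        ]
        return np.asarray(w)


def fixation_probability(s_eff: float, model: FixationModel) -> float:
    """Probability that a mutant with selection coefficient ``s_eff`` fixes.

    ``s_eff`` is a Malthusian coefficient: the mutant/resident fitness
    ratio is ``exp(s_eff)`` for the exact Sella–Hirsh kernel, while the
    Kimura diffusion kernel uses ``s_eff`` directly.  The neutral limit
    1/N is taken analytically for |s_eff| below 1e-12.
    """
    if s_eff <= -1:
        raise ValueError(f"selection coefficient must exceed -1, got {s_eff}")
    N = model.N
    if N == 1:
        return 1.0
    if abs(s_eff) < _NEUTRAL_TOL:
        return 1.0 / N
    if model.kind is FixationKind.kimura:
        # pi = (1 - e^{-2s}) / (1 - e^{-2Ns})
        return _expm1_ratio(-2.0 * s_eff, -2.0 * N * s_eff)
    # Sella-Hirsh with fitness ratio r = e^{s}: pi = (1 - r^-2) / (1 - r^-2N)
    r = math.exp(s_eff)
    logr = math.log(r)
    return _expm1_ratio(-2.0 * logr, -2.0 * N * logr)


def _expm1_ratio(num_arg: float, den_arg: float) -> float:
    """``expm1(num_arg) / expm1(den_arg)``, robust to overflow for den_arg >> 0."""
    if den_arg > 700.0:  # deleterious mutant in a large population: pi underflows
        return math.expm1(num_arg) * math.exp(-den_arg)
    return math.expm1(num_arg) / math.expm1(den_arg)


def _log_abs_expm1(x: float) -> float:
    """log |expm1(x)|, robust for any x."""
    if x > 700.0:
        return x
    return math.log(abs(math.expm1(x)))


def log_fixation_probability(s_eff: float, model: FixationModel) -> float:
    """``log`` of :func:`fixation_probability`, overflow-free for any N."""
    if s_eff <= -1:
        raise ValueError(f"selection coefficient must exceed -1, got {s_eff}")
    N = model.N
    if N == 1:
        return 0.0
    if abs(s_eff) < _NEUTRAL_TOL:
        return -math.log(N)
    # both kernels share the log form under the Malthusian parameterisation
    return _log_abs_expm1(-2.0 * s_eff) - _log_abs_expm1(-2.0 * N * s_eff)


def fixation_ratio(s_eff: float, model: FixationModel) -> float:
    """Forward/backward fixation-probability ratio ``pi_ij / pi_ji``.

    Equals ``exp(2 s_eff (N - 1))`` for both kernels; the backward step
    carries coefficient ``-s_eff`` (reciprocal fitness ratio).
    """
    forward = fixation_probability(s_eff, model)
    backward = fixation_probability(-s_eff, model)
    return forward / backward


def dfe_mutation_rates(spec: MarkovLandscapeSpec) -> dict[tuple[int, int], float]:
    """Per-edge mutation rates of the chain.

    Up-steps on the fragile path get ``p_b(s/n)``; the robust up-step
    gets ``p_b(s)`` (or ``p_b(s - epsilon)`` if requested); every
    down/back edge gets the overall rate ``mu``.  Keys are state-index
    pairs with 0 = wild, 1..n = fragile ladder, n+1 = robust.
    """
    n = spec.n
    robust = n + 1
    u_fragile = spec.p_b(spec.s / n)
    u_robust = spec.p_b(spec.s - spec.epsilon) if spec.use_epsilon_in_u14 else spec.p_b(spec.s)
    rates: dict[tuple[int, int], float] = {}
    for k in range(n):
        rates[(k, k + 1)] = u_fragile
        rates[(k + 1, k)] = spec.mu
    rates[(0, robust)] = u_robust
    rates[(robust, 0)] = spec.mu
    return rates


def flux_ratio(spec: MarkovLandscapeSpec, rates: dict[tuple[int, int], float] | None = None) -> float:
    """Mutational flux ratio M between the two peaks.

    ``M = (u_{r1}/u_{1r}) * prod_k (u_{k,k+1}/u_{k+1,k})``; with the
    exponential-DFE rates this telescopes to ``kappa^(n-1)`` and the
    overall rate ``mu`` cancels.
    """
    if rates is None:
        rates = dfe_mutation_rates(spec)
    robust = spec.n + 1
    m = rates[(robust, 0)] / rates[(0, robust)]
    for k in range(spec.n):
        m *= rates[(k, k + 1)] / rates[(k + 1, k)]
    return m


@dataclass
class TransitionMatrix:
    """Row-stochastic per-generation transition matrix of the chain."""

    states: list[str]
    T: np.ndarray
    fitness: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.T, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1] or T.shape[0] != len(self.states):
            raise ValueError("transition matrix must be square and match the state labels")
        if np.any(T < -1e-15) or np.any(T > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rowsums = T.sum(axis=1)
        if np.max(np.abs(rowsums - 1.0)) > 1e-12:
            raise ValueError("rows of a per-generation transition matrix must sum to 1")
        self.T = T

    @classmethod
    def from_edges(
        cls,
        states: Sequence[str],
        edges: dict[tuple[int, int], tuple[float, float]],
        model: FixationModel,
        fitness: Sequence[float] | None = None,
    ) -> "TransitionMatrix":
        """Build ``T`` from directed edges ``(i, j) -> (u_ij, s_ij)``.

        Off-diagonal entries are ``u_ij * pi_ij``; diagonals complement
        the row sum.  Raises if any row's total leave probability
        exceeds 1 (rates too large for a per-generation chain).
        """
        k = len(states)
        T = np.zeros((k, k))
        for (i, j), (u, s_eff) in edges.items():
            if i == j:
                raise ValueError("self-edges are implicit (diagonal complement)")
            T[i, j] = u * fixation_probability(s_eff, model)
        leave = T.sum(axis=1)
        if np.any(leave > 1 + 1e-12):
            raise ValueError("edge rates too large: some row's leave probability exceeds 1")
        np.fill_diagonal(T, 1.0 - leave)
        fit = None if fitness is None else np.asarray(fitness, dtype=float)
        return cls(states=list(states), T=T, fitness=fit)


def build_transition_matrix(
    spec: MarkovLandscapeSpec,
    model: FixationModel,
    rates: dict[tuple[int, int], float] | None = None,
) -> TransitionMatrix:
    """Per-generation transition matrix of the two-peak chain.

    ``rates`` may override the mutational edge rates (same sparsity
    pattern); edge selection coefficients are always the additive
    increments of the fitness ladder.
    """
    if rates is None:
        rates = dfe_mutation_rates(spec)
    n = spec.n
    robust = n + 1
    step = spec.s / n
    s_edge: dict[tuple[int, int], float] = {}
    for k in range(n):
        s_edge[(k, k + 1)] = step
        s_edge[(k + 1, k)] = -step
    s_edge[(0, robust)] = spec.s - spec.epsilon
    s_edge[(robust, 0)] = -(spec.s - spec.epsilon)
    edges = {ij: (rates[ij], s_edge[ij]) for ij in s_edge}
    return TransitionMatrix.from_edges(spec.state_labels, edges, model, fitness=spec.fitness)


@dataclass
class StationaryResult:
    """Stationary distribution and derived occupancy diagnostics."""

    states: list[str]
    x_star: np.ndarray
    R: float | None = None
    M: float | None = None
    N_crit_closed: float | None = None
    N_crit_numeric: float | None = None


def stationary_distribution(T: TransitionMatrix) -> StationaryResult:
    """Left eigenvector of ``T`` with eigenvalue 1, normalised to sum 1.

    Solved by the Grassmann-Taksar-Heyman state-elimination scheme: a
    deterministic direct solve of ``x T = x`` that is subtraction-free
    and therefore gives full relative accuracy even for stationary
    components many orders of magnitude apart (origin-fixation chains
    routinely span such scales).  Raises if the chain has no unique
    stationary distribution.
    """
    k = len(T.states)
    if np.linalg.matrix_rank(T.T - np.eye(k), tol=1e-12) < k - 1:
        raise ValueError("no unique stationary distribution: chain is reducible")
    P = T.T.copy()
    for m in range(k - 1, 0, -1):
        S = P[m, :m].sum()
        if S <= 0.0:
            raise ValueError("no unique stationary distribution: chain is reducible")
        P[:m, m] /= S
        P[:m, :m] += np.outer(P[:m, m], P[m, :m])
    x = np.empty(k)
    x[0] = 1.0
    for m in range(1, k):
        x[m] = x[:m] @ P[:m, m]
    x /= x.sum()
    residual = np.max(np.abs(x @ T.T - x))
    if residual > 1e-10:
        raise ValueError(
            f"stationary solve failed to converge (residual={residual:g})"
        )
    return StationaryResult(states=list(T.states), x_star=x)


def occupancy_ratio(
    result: StationaryResult,
    fragile_state: str | None = None,
    robust_state: str = "robust",
) -> float:
    """Occupancy ratio R = x*(fragile top) / x*(robust peak)."""
    states = result.states
    if fragile_state is None:
        # top of the fragile ladder = last fragile_* label
        fragile_state = [s for s in states if s.startswith("fragile_")][-1]
    x = result.x_star
    x_robust = x[states.index(robust_state)]
    if x_robust <= 0:
        raise ValueError("degenerate landscape: robust peak has zero occupancy")
    return float(x[states.index(fragile_state)] / x_robust)


def n_crit_closed(kappa: float, epsilon: float, n: int = 2) -> float:
    """Closed-form critical population size.

    ``N_crit = 1 + (n - 1) log(1/kappa) / (2 epsilon)``: the size at
    which the drift-fragile and drift-robust peaks are equally occupied.
    """
    if not 0 < kappa < 1:
        raise ValueError(f"need 0 < kappa < 1 for a crossing to exist, got {kappa}")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    return 1.0 + (n - 1) * math.log(1.0 / kappa) / (2.0 * epsilon)


def log_occupancy_ratio(
    spec: MarkovLandscapeSpec, kind: FixationKind | str, N: float
) -> float:
    """``log R(N)`` via the detailed-balance cycle product.

    The two-peak chain is a tree, hence reversible, so the stationary
    occupancy ratio equals the product of forward/backward transition
    probabilities along the wild-to-peak paths; summing logs keeps the
    result representable at population sizes where the eigenvector
    components themselves under- or overflow.  Agrees with the
    eigenvector pipeline wherever both are representable.
    """
    model = FixationModel(kind=FixationKind(kind), N=N)
    rates = dfe_mutation_rates(spec)
    n = spec.n
    robust = n + 1
    step = spec.s / n
    s_rob = spec.s - spec.epsilon
    log_r = math.log(rates[(robust, 0)]) - math.log(rates[(0, robust)])
    log_r += log_fixation_probability(-s_rob, model) - log_fixation_probability(s_rob, model)
    for k in range(n):
        log_r += math.log(rates[(k, k + 1)]) - math.log(rates[(k + 1, k)])
        log_r += log_fixation_probability(step, model) - log_fixation_probability(-step, model)
    return log_r


def n_crit_numeric(
    spec: MarkovLandscapeSpec,
    kind: FixationKind | str = FixationKind.kimura,
    tol: float = 1e-6,
    N_hi: float = 8.0,
) -> float:
    """Critical population size as the root of ``R(N) = 1``.

    Brent bisection on ``log R(N)`` over ``[1, N_hi]``, doubling
    ``N_hi`` (up to 40 times) until the root is bracketed.
    ``R(1) = M < 1`` is guaranteed by the flux-ratio precondition.
    """
    kind = FixationKind(kind)
    if flux_ratio(spec) >= 1:
        raise ValueError("flux ratio M >= 1: both peaks equally fed, no crossing exists")

    def f(N: float) -> float:
        return log_occupancy_ratio(spec, kind, N)

    lo = 1.0
    hi = N_hi
    for _ in range(41):
        if f(hi) > 0:
            break
        hi *= 2
    else:
        raise ValueError("R(N) never crosses 1 within the doubling cap")
    return float(brentq(f, lo, hi, xtol=tol))


def solve_landscape(spec: MarkovLandscapeSpec, model: FixationModel) -> StationaryResult:
    """Full pipeline: transition matrix, x*, R, M and both critical sizes."""
    T = build_transition_matrix(spec, model)
    res = stationary_distribution(T)
    res.R = occupancy_ratio(res)
    res.M = flux_ratio(spec)
    res.N_crit_closed = n_crit_closed(spec.kappa, spec.epsilon, spec.n)
    res.N_crit_numeric = n_crit_numeric(spec, model.kind)
    return res
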