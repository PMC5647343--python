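"""Monte-Carlo simulation of the monomorphic origin-fixation chain.

Serves as an independent stochastic oracle for the stationary
distribution computed by :mod:`driftscape.markov`: the empirical
occupancy of a long trajectory must converge to the analytic left
eigenvector, and the empirical peak-occupancy ratio must cross 1
between the integer population sizes bracketing the critical size.

Occupancy samples from a Markov trajectory are autocorrelated (the
chain holds its state for many generations between fixation events), so
goodness-of-fit uses a regeneration-based effective sample size: the
trajectory is split into excursions between returns to a reference
state, which are independent by the strong Markov property.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .markov import TransitionMatrix

__all__ = ["ChainTrajectory", "simulate_origin_fixation", "occupancy_gof"]


@dataclass
class ChainTrajectory:
    """A simulated origin-fixation trajectory."""

    states: np.ndarray  # visited state index per generation (post burn-in)
    occupancy: np.ndarray  # time-in-state counts over the retained generations
    seed: int
    burn_in: int

    @property
    def occupancy_fractions(self) -> np.ndarray:
        return self.occupancy / self.occupancy.sum()


def simulate_origin_fixation(
    T: TransitionMatrix,
    steps: int,
    burn_in: int = 0,
    seed: int = 0,
    start: int = 0,
) -> ChainTrajectory:
    """Sample ``steps`` generations of the chain by categorical row sampling.

    The first ``burn_in`` generations are discarded from the occupancy
    counts.  One explicit RNG stream per trajectory; identical seeds
    yield identical trajectories.
    """
    if not 0 <= burn_in < steps:
        raise ValueError("need steps > burn_in >= 0")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T.T, axis=1)
    # guard against round-off in the last column
    cum[:, -1] = 1.0
    k = cum.shape[0]
    out = np.empty(steps, dtype=np.int64)
    state = start
    block = 65536
    pos = 0
    while pos < steps:
        m = min(block, steps - pos)
        u = rng.random(m)
        for t in range(m):
            state = int(np.searchsorted(cum[state], u[t], side="right"))
            if state >= k:  # pragma: no cover - u ~ U[0,1) and cum[-1]=1
                state = k - 1
            out[pos + t] = state
        pos += m
    kept = out[burn_in:]
    occupancy = np.bincount(kept, minlength=k)
    return ChainTrajectory(states=kept, occupancy=occupancy, seed=seed, burn_in=burn_in)


def occupancy_gof(trajectory: ChainTrajectory, x_star: np.ndarray) -> tuple[float, float, int]:
    """Chi-squared goodness of fit of empirical occupancy against ``x_star``.

    Returns ``(chi2, p, n_eff)`` where ``n_eff`` is the number of
    regeneration cycles (returns to the analytically most-occupied
    state), used in place of the raw, autocorrelated generation count.
    """
    x_star = np.asarray(x_star, dtype=float)
    f = trajectory.occupancy_fractions
    ref = int(np.argmax(x_star))
    visits = trajectory.states == ref
    # a cycle completes at each entry into the reference state
    entries = int(np.count_nonzero(visits[1:] & ~visits[:-1])) + int(visits[0])
    n_eff = max(entries, 1)
    chi2 = n_eff * float(np.sum((f - x_star) ** 2 / x_star))
    p = float(stats.chi2.sf(chi2, df=len(x_star) - 1))
    return chi2, p, n_eff
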