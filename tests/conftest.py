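import numpy as np
import pytest

from driftscape import LandscapeConfig, MarkovLandscapeSpec, generate_landscape


@pytest.fixture(scope="session")
def default_landscape():
    return generate_landscape(LandscapeConfig(seed=1))


@pytest.fixture()
def minimal_spec():
    return MarkovLandscapeSpec(s=0.1, epsilon=0.05, n=2, u_b=1e-3, s_bar=0.1, mu=0.01)


def wright_fisher_fixation_frequency(s, N, trials, seed):
    """Independent oracle: haploid WF simulation of a single mutant lineage.

    A mutant with multiplicative weight e^{s} starts at count 1 in a
    population of N; each generation the count is binomial with
    selection-weighted probability.  Returns the fraction of trials in
    which the mutant fixed.
    """
    rng = np.random.default_rng(seed)
    counts = np.ones(trials, dtype=np.int64)
    w = np.exp(s)
    active = np.ones(trials, dtype=bool)
    while active.any():
        k = counts[active]
        p = (k * w) / (k * w + (N - k))
        counts[active] = rng.binomial(N, p)
        active = (counts > 0) & (counts < N)
    return float(np.mean(counts == N))
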