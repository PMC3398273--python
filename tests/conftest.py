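import numpy as np
import pytest

from cardevol.codonmodel import CodonFrequencies


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61.0)


@pytest.fixture(scope="session")
def uniform_freqs():
    return CodonFrequencies.uniform()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def taylor_expm(Q: np.ndarray, t: float, order: int = 20) -> np.ndarray:
    """Independent series-expansion oracle for exp(Qt)."""
    P = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for k in range(1, order + 1):
        term = term @ (Q * t) / k
        P = P + term
    return P


def wilcoxon_enumeration_oracle(a, b):
    """Exact two-sided Wilcoxon P by full enumeration of labelings (untied
    data): probability that a random labeling is at least as extreme as the
    observed U under the exchangeable null."""
    import itertools

    from scipy import stats

    pooled = np.concatenate([a, b])
    n, na = pooled.size, len(a)
    u_obs = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").statistic
    m_obs = min(u_obs, na * (n - na) - u_obs)
    hits = total = 0
    for idx in itertools.combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = stats.mannwhitneyu(
            pooled[mask], pooled[~mask], alternative="two-sided", method="exact"
        ).statistic
        if min(u, na * (n - na) - u) <= m_obs + 1e-9:
            hits += 1
        total += 1
    return hits / total
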