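import numpy as np
import pandas as pd
import pytest

from dietinfer import FeatureTable


def make_table(counts: dict, taxonomy: dict, diet: dict | None = None,
               tissue: dict | None = None) -> FeatureTable:
    """Small literal FeatureTable: counts = {otu: {sample: n}}."""
    cdf = pd.DataFrame(counts).T.fillna(0).astype(int)
    samples = list(cdf.columns)
    meta = pd.DataFrame(
        {
            "species": ["sp"] * len(samples),
            "tissue_type": [(tissue or {}).get(s, "gut") for s in samples],
            "diet_class": [(diet or {}).get(s, "unknown") for s in samples],
        },
        index=samples,
    )
    return FeatureTable(cdf, pd.Series(taxonomy), meta)


@pytest.fixture
def toy_table():
    """3 OTUs x 2 samples, counts [[600, 0], [1, 10000], [0, 400]], all bacterial."""
    return make_table(
        counts={
            "otu1": {"s1": 600, "s2": 0},
            "otu2": {"s1": 1, "s2": 10000},
            "otu3": {"s1": 0, "s2": 400},
        },
        taxonomy={
            "otu1": "k__Bacteria; p__Cyanobacteria; c__Chloroplast",
            "otu2": "k__Bacteria; p__Firmicutes; c__Bacilli",
            "otu3": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia",
        },
    )


def brute_force_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all C(n1+n2, n1) labelings.

    Counts arrangements whose Mann-Whitney U is at least as extreme
    (in either tail, by symmetry of the null) as the observed one.
    """
    from itertools import combinations

    import scipy.stats as sps

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    u_obs = w_obs - n1 * (n1 + 1) / 2
    m_obs = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    all_ranks = np.arange(1, n1 + n2 + 1)
    for idx in combinations(range(n1 + n2), n1):
        w = all_ranks[list(idx)].sum()
        u = w - n1 * (n1 + 1) / 2
        if min(u, n1 * n2 - u) <= m_obs + 1e-9:
            count += 1
        total += 1
    return count / total
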