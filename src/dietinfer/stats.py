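"""Nonparametric group comparisons for chloroplast prevalence.

Per-sample chloroplast proportions are bounded, heavily tied (carnivore
libraries contain exactly zero chloroplast reads) and small-n, so the
comparisons are rank-based throughout: a Kruskal-Wallis test across diet
classes followed by pairwise two-sided Wilcoxon rank-sum tests with a
multiple-comparison correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

CORRECTIONS = ("holm", "bonferroni", "none")


@dataclass(frozen=True)
class TestResult:
    """One group comparison: method label, statistic, df, p-value."""

    method: str
    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    groups: tuple[str, ...]
    adjusted: bool = False
    p_adjusted: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "groups": " vs ".join(self.groups),
            "statistic": self.statistic,
            "df": self.df if not isinstance(self.df, tuple) else f"{self.df[0]},{self.df[1]}",
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
        }
        return d


def _as_groups(values, groups) -> dict[str, np.ndarray]:
    """Accept (values, labels) arrays or a mapping label -> values."""
    if groups is None:
        if not isinstance(values, dict):
            raise TypeError("pass either a mapping or parallel values/groups arrays")
        out = {str(k): np.asarray(v, dtype=float) for k, v in values.items()}
    else:
        values = np.asarray(values, dtype=float)
        labels = np.asarray(groups)
        if values.shape != labels.shape:
            raise ValueError("values and groups must have equal length")
        out = {str(g): values[labels == g] for g in pd.unique(labels)}
    for name, arr in out.items():
        if arr.size == 0:
            raise ValueError(f"group {name!r} has zero observations")
        if not np.isfinite(arr).all():
            raise ValueError(f"group {name!r} contains non-finite values")
    return out


def kruskal_wallis(values, groups=None) -> TestResult:
    """Kruskal-Wallis H test across k groups (tie-corrected, chi-square df k-1).

    Accepts parallel ``values``/``groups`` arrays or a mapping
    ``{label: values}``.  If every observation is identical the statistic
    is 0 and p = 1 (scipy raises in that degenerate case).
    """
    gd = _as_groups(values, groups)
    if len(gd) < 2:
        raise ValueError("need at least two groups")
    names = tuple(gd)
    k = len(names)
    allv = np.concatenate(list(gd.values()))
    if np.all(allv == allv[0]):
        return TestResult("kruskal-wallis", 0.0, float(k - 1), 1.0, names)
    H, p = sps.kruskal(*gd.values())
    return TestResult("kruskal-wallis", float(H), float(k - 1), float(p), names)


def _ranksum_asymptotic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected normal approximation for the two-sided rank-sum test.

    Returns (z, p).  No continuity correction, so with two tie-free
    groups z**2 equals the Kruskal-Wallis H exactly.
    """
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n - 1) * n * (n + 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term * (n + 1))
    # equivalently n1*n2/12 * (n+1) * (1 - sum(t^3-t)/(n^3-n))
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


@lru_cache(maxsize=128)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Frequencies of the Mann-Whitney U statistic under the tie-free null.

    Uses the standard recurrence N(u; n1, n2) = N(u - n2; n1 - 1, n2)
    + N(u; n1, n2 - 1); cached because the calibration simulations call
    the exact test with the same group sizes thousands of times.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_null_counts(n1 - 1, n2)  # last x-observation beyond all y: U += n2
    b = _u_null_counts(n1, n2 - 1)
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _exact_ranksum_p(u: float, n1: int, n2: int) -> float:
    """Exact two-sided p: doubled smaller tail of the U null, clipped at 1."""
    counts = _u_null_counts(n1, n2)
    m = int(round(min(u, n1 * n2 - u)))
    tail = sum(counts[: m + 1])
    return min(1.0, 2.0 * tail / sum(counts))


def ranksum(x, y, exact: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for two groups.

    ``exact`` is one of ``auto`` (exact null distribution when both
    groups have <= 8 observations and there are no ties, normal
    approximation with tie correction otherwise), ``exact`` or
    ``asymptotic``.  The exact branch enumerates the Mann-Whitney U null
    distribution; the asymptotic branch uses the tie-corrected z without
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if exact == "auto":
        use_exact = len(x) <= 8 and len(y) <= 8 and not has_ties
    elif exact == "exact":
        if has_ties:
            raise ValueError("exact rank-sum null distribution requires tie-free data")
        use_exact = True
    elif exact == "asymptotic":
        use_exact = False
    else:
        raise ValueError(f"unknown exact mode {exact!r}")
    if use_exact:
        n1, n2 = len(x), len(y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
        return TestResult("wilcoxon-ranksum-exact", float(u), None,
                          _exact_ranksum_p(u, n1, n2), ("x", "y"))
    z, p = _ranksum_asymptotic(x, y)
    return TestResult("wilcoxon-ranksum-normal", z, None, p, ("x", "y"))


def adjust_pvalues(pvalues, method: str = "holm") -> np.ndarray:
    """Multiple-comparison correction: ``holm`` (default), ``bonferroni`` or ``none``.

    Holm is the step-down procedure: order the m p-values ascending,
    multiply the i-th by (m - i), take the running maximum and clip at 1.
    It guarantees the same family-wise error level as Bonferroni while
    never being less powerful.
    """
    p = np.asarray(pvalues, dtype=float)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method != "holm":
        raise ValueError(f"unknown correction {method!r}; choose from {CORRECTIONS}")
    order = np.argsort(p, kind="stable")
    factors = np.arange(p.size, 0, -1)
    adj_sorted = np.minimum(np.maximum.accumulate(p[order] * factors), 1.0)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def pairwise_ranksum(values, groups=None, correction: str = "holm",
                     exact: str = "auto") -> list[TestResult]:
    """All unordered pairwise rank-sum tests with corrected p-values.

    Every pair of groups is tested two-sided; the raw p-values are then
    adjusted jointly by ``correction`` and each result carries both the
    raw and the adjusted p-value with ``adjusted=True``.
    """
    gd = _as_groups(values, groups)
    names = list(gd)
    if len(names) < 2:
        raise ValueError("pairwise tests need at least two groups")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    raw = [ranksum(gd[a], gd[b], exact=exact) for a, b in pairs]
    adj = adjust_pvalues([r.p_value for r in raw], correction)
    return [
        TestResult(r.method, r.statistic, r.df, r.p_value, (a, b),
                   adjusted=True, p_adjusted=float(pa))
        for (a, b), r, pa in zip(pairs, raw, adj)
    ]


def group_summary(values, groups=None) -> pd.DataFrame:
    """Per-group n, median, IQR (Q3 - Q1), min and max.

    Quartiles use linear interpolation (R type-7 / numpy default), the
    convention that matters when comparing IQRs across software.
    """
    gd = _as_groups(values, groups)
    rows = {}
    for name, arr in gd.items():
        q1, q3 = np.percentile(arr, [25, 75])
        rows[name] = {
            "n": len(arr),
            "median": float(np.median(arr)),
            "iqr": float(q3 - q1),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["n"] = out["n"].astype(int)
    out.index.name = "group"
    return out


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tidy DataFrame of test results (one row per comparison)."""
    return pd.DataFrame([r.to_dict() for r in results])
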