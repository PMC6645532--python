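"""Two-source stable-isotope mixing model with trophic discrimination free.

A consumer's isotope ratio is modelled as a weighted average of two
dietary sources plus a trophic discrimination (fractionation) offset:

    delta_consumer = f * delta_source1 + (1 - f) * delta_source2 + Delta

where ``f`` is the fraction of the element assimilated from source 1 and
``Delta`` is assumed constant across sources.  With group means for the
consumer and both sources substituted in, solving for ``f`` gives a
*line* in ``Delta``:

    f(Delta) = (consumer - source2 - Delta) / (source1 - source2)
             = intercept + slope * Delta

so the diet fraction and the discrimination cannot be separated from the
means alone; the line itself is the inferential object.  Evaluating the
inverse at f = 1 yields the discrimination a pure source-1 diet would
imply, which can be compared against the range of discrimination factors
reported in feeding trials (roughly 0-4 permil for d15N in insects).

Units: d15N in permil vs atmospheric air, d13C in permil vs VPDB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import TestResult

ROLES = ("consumer", "leaves", "larvae", "reference")


def discrimination(consumer_delta: float, diet_delta: float) -> float:
    """Trophic discrimination Delta = consumer - diet (permil)."""
    return consumer_delta - diet_delta


def mixing_forward(fraction: float, delta_source1: float, delta_source2: float,
                   discrimination: float) -> float:
    """Consumer isotope value under the two-source mixing model.

    ``fraction`` is the source-1 diet fraction; values outside [0, 1] are
    allowed (with a warning) for sensitivity use.
    """
    if not 0.0 <= fraction <= 1.0:
        warnings.warn(f"diet fraction {fraction} outside [0, 1]", stacklevel=2)
    return fraction * delta_source1 + (1.0 - fraction) * delta_source2 + discrimination


@dataclass(frozen=True)
class MixingLine:
    """Linear relation fraction = intercept + slope * Delta for one element.

    ``intercept`` is dimensionless, ``slope`` is per permil.  Optional
    standard errors (delta-method, from the group-mean standard errors)
    ride along when the line was fitted from data.
    """

    element: str  # "N" or "C"
    intercept: float
    slope: float
    source_labels: tuple[str, str] = ("leaves", "larvae")
    intercept_se: float | None = None
    slope_se: float | None = None

    def __post_init__(self):
        if self.element not in ("N", "C"):
            raise ValueError("element must be 'N' or 'C'")
        if not np.isfinite(self.slope) or self.slope == 0.0:
            raise ValueError("mixing line slope must be finite and nonzero")
        if not np.isfinite(self.intercept):
            raise ValueError("mixing line intercept must be finite")


def mixing_line(consumer_mean: float, source1_mean: float, source2_mean: float,
                element: str, source_labels: tuple[str, str] = ("leaves", "larvae"),
                ses: tuple[float, float, float] | None = None) -> MixingLine:
    """Invert the mixing model at group means into a fraction-vs-Delta line.

    intercept = (consumer - source2) / (source1 - source2)
    slope     = -1 / (source1 - source2)

    ``ses``, if given, are the standard errors of (consumer, source1,
    source2) means; delta-method standard errors for the coefficients are
    attached to the returned line.  Equal source means make the fraction
    unidentifiable and raise.
    """
    denom = source1_mean - source2_mean
    if denom == 0.0:
        raise ValueError(
            "degenerate mixing model: the two source means are equal, "
            "so the diet fraction is unidentifiable"
        )
    intercept = (consumer_mean - source2_mean) / denom
    slope = -1.0 / denom
    i_se = s_se = None
    if ses is not None:
        se_c, se_1, se_2 = ses
        # intercept partials: d/dc = 1/denom, d/ds1 = -(c-s2)/denom^2,
        # d/ds2 = (c-s1)/denom^2; slope partials: +-1/denom^2
        gi = np.array([
            1.0 / denom,
            -(consumer_mean - source2_mean) / denom**2,
            (consumer_mean - source1_mean) / denom**2,
        ])
        gs = np.array([0.0, 1.0 / denom**2, -1.0 / denom**2])
        v = np.array([se_c, se_1, se_2], dtype=float) ** 2
        i_se = float(np.sqrt((gi**2 * v).sum()))
        s_se = float(np.sqrt((gs**2 * v).sum()))
    return MixingLine(element, float(intercept), float(slope), source_labels, i_se, s_se)


def fraction_at(line: MixingLine, discrimination: float) -> tuple[float, bool]:
    """Diet fraction the line implies at a given discrimination (permil).

    Returns ``(fraction, in_range)``.  Fractions outside [0, 1] are
    returned unclamped with ``in_range=False`` — the line is a diagnostic
    over a whole range of plausible discriminations, so truncation would
    hide information.
    """
    f = line.intercept + line.slope * discrimination
    return float(f), bool(0.0 <= f <= 1.0)


def discrimination_at(line: MixingLine, fraction: float) -> float:
    """Discrimination (permil) the line implies at a given diet fraction."""
    return (fraction - line.intercept) / line.slope


def group_means(data: pd.DataFrame, roles=None, role_col: str = "role") -> pd.DataFrame:
    """Arithmetic mean, sd, se and n of d15N and d13C per role.

    ``data`` needs columns ``role``, ``d15N``, ``d13C``.  Requested roles
    must be present; the sd of a single measurement is reported as 0 with
    n = 1 so the caller can see the flag.
    """
    if roles is None:
        roles = list(pd.unique(data[role_col]))
    rows = {}
    for role in roles:
        sub = data[data[role_col] == role]
        if sub.empty:
            raise ValueError(f"no measurements for role {role!r}")
        row = {"n": len(sub)}
        for el, col in (("d15N", "d15N"), ("d13C", "d13C")):
            vals = sub[col].to_numpy(dtype=float)
            row[f"{el}_mean"] = float(vals.mean())
            row[f"{el}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            row[f"{el}_se"] = row[f"{el}_sd"] / np.sqrt(len(vals))
        rows[role] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["n"] = out["n"].astype(int)
    out.index.name = "role"
    return out


def welch_t(group_a, group_b, paired: bool = False, pooled: bool = False) -> TestResult:
    """Two-sided t comparison of two samples.

    Unpaired mode defaults to the unequal-variance (Welch) statistic with
    Welch-Satterthwaite fractional degrees of freedom; ``pooled=True``
    switches to the classical equal-variance test.  Paired mode is the
    one-sample t test on the differences with df = n - 1 and requires
    equal-length, order-matched inputs.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length matched samples")
        if len(a) < 2:
            raise ValueError("paired test needs at least two pairs")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            stat, p = (0.0, 1.0) if np.allclose(d.mean(), 0.0) else (np.inf, 0.0)
        else:
            stat, p = sps.ttest_rel(a, b)
        return TestResult("paired-t", float(stat), float(len(a) - 1), float(p), ("A", "B"))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    res = sps.ttest_ind(a, b, equal_var=pooled)
    method = "student-t" if pooled else "welch-t"
    return TestResult(method, float(res.statistic), float(res.df), float(res.pvalue),
                      ("A", "B"))


def oneway_anova(groups: dict[str, "np.ndarray"]) -> TestResult:
    """One-way ANOVA F test across k groups, df = (k-1, N-k).

    A zero within-group sum of squares with nonzero between-group spread
    is reported as F = inf, p = 0 rather than an error.
    """
    names = tuple(groups)
    arrs = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    k = len(arrs)
    n_total = sum(len(a) for a in arrs)
    df = (float(k - 1), float(n_total - k))
    within_ss = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    grand = np.concatenate(arrs).mean()
    between_ss = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    if within_ss == 0.0:
        if between_ss == 0.0:
            return TestResult("one-way-anova", 0.0, df, 1.0, names)
        return TestResult("one-way-anova", np.inf, df, 0.0, names)
    F, p = sps.f_oneway(*arrs)
    return TestResult("one-way-anova", float(F), df, float(p), names)


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------


class TwoSourceMixingModel:
    """Two-source mixing model for one consumer and two dietary sources.

    Parameters
    ----------
    data : DataFrame
        Long-format isotope table with columns ``sample_id``, ``role``,
        ``d15N``, ``d13C`` and optionally ``species`` and ``pairing_id``
        (linking matched consumer/source specimens from one tree).
    consumer, source1, source2 : str
        Role labels; source1 is the focal (plant) source whose diet
        fraction the lines describe.

    Examples
    --------
    >>> model = TwoSourceMixingModel.from_csv("isotopes.csv")
    >>> res = model.fit()
    >>> res.implied_discrimination("N", fraction=1.0)
    """

    def __init__(self, data: pd.DataFrame, consumer: str = "consumer",
                 source1: str = "leaves", source2: str = "larvae"):
        required = {"role", "d15N", "d13C"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"isotope table missing columns: {sorted(missing)}")
        if not np.isfinite(data[["d15N", "d13C"]].to_numpy(dtype=float)).all():
            raise ValueError("d15N/d13C must be finite")
        self.data = data.reset_index(drop=True)
        self.consumer = consumer
        self.source1 = source1
        self.source2 = source2

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TwoSourceMixingModel":
        """Build from a CSV with columns sample_id, role, d15N, d13C[, ...]."""
        return cls(pd.read_csv(path), **kwargs)

    @classmethod
    def from_means(cls, consumer_means: tuple[float, float],
                   source1_means: tuple[float, float],
                   source2_means: tuple[float, float],
                   **kwargs) -> "MixingResults":
        """Fit directly from published (d15N, d13C) group means.

        Bypasses per-specimen data; returns results whose lines carry no
        standard errors.
        """
        rows = []
        for role, (n_val, c_val) in (
            (kwargs.get("consumer", "consumer"), consumer_means),
            (kwargs.get("source1", "leaves"), source1_means),
            (kwargs.get("source2", "larvae"), source2_means),
        ):
            rows.append({"sample_id": role, "role": role, "d15N": n_val, "d13C": c_val})
        model = cls(pd.DataFrame(rows), **kwargs)
        return model.fit(use_ses=False)

    def fit(self, use_ses: bool = True) -> "MixingResults":
        """Estimate group means and both fraction-vs-Delta mixing lines."""
        gm = group_means(self.data, roles=[self.consumer, self.source1, self.source2])
        lines = {}
        for el, col in (("N", "d15N"), ("C", "d13C")):
            ses = None
            if use_ses:
                ses = tuple(gm.loc[r, f"{col}_se"]
                            for r in (self.consumer, self.source1, self.source2))
            lines[el] = mixing_line(
                gm.loc[self.consumer, f"{col}_mean"],
                gm.loc[self.source1, f"{col}_mean"],
                gm.loc[self.source2, f"{col}_mean"],
                element=el,
                source_labels=(self.source1, self.source2),
                ses=ses,
            )
        return MixingResults(self, gm, lines["N"], lines["C"])

    # -- group comparisons ------------------------------------------------

    def _role_values(self, role: str, element: str) -> np.ndarray:
        col = {"N": "d15N", "C": "d13C"}[element]
        sub = self.data[self.data["role"] == role]
        if sub.empty:
            raise ValueError(f"no measurements for role {role!r}")
        return sub[col].to_numpy(dtype=float)

    def compare(self, role_a: str, role_b: str, element: str = "N",
                paired: bool = False, pooled: bool = False) -> TestResult:
        """t comparison of two roles; ``paired=True`` matches on pairing_id."""
        if paired:
            if "pairing_id" not in self.data.columns:
                raise ValueError("paired comparison requires a pairing_id column")
            col = {"N": "d15N", "C": "d13C"}[element]
            a = self.data[self.data["role"] == role_a].set_index("pairing_id")[col]
            b = self.data[self.data["role"] == role_b].set_index("pairing_id")[col]
            a = a[a.index.notna()]
            b = b[b.index.notna()]
            shared = a.index.intersection(b.index)
            unmatched = a.index.symmetric_difference(b.index)
            if len(unmatched):
                raise ValueError(f"unmatched pairing ids: {sorted(map(str, unmatched))}")
            r = welch_t(a.loc[shared].to_numpy(), b.loc[shared].to_numpy(), paired=True)
        else:
            r = welch_t(self._role_values(role_a, element),
                        self._role_values(role_b, element), pooled=pooled)
        return TestResult(r.method, r.statistic, r.df, r.p_value, (role_a, role_b))

    def anova(self, roles, element: str = "N") -> TestResult:
        """One-way ANOVA of an element across several roles."""
        return oneway_anova({r: self._role_values(r, element) for r in roles})


class MixingResults:
    """Fitted two-source mixing model: group means, lines, implied Deltas."""

    def __init__(self, model: TwoSourceMixingModel, group_means: pd.DataFrame,
                 line_n: MixingLine, line_c: MixingLine):
        self.model = model
        self.group_means = group_means
        self.line_n = line_n
        self.line_c = line_c

    def line(self, element: str) -> MixingLine:
        return {"N": self.line_n, "C": self.line_c}[element]

    def fraction_at(self, element: str, discrimination: float) -> tuple[float, bool]:
        """Diet fraction at a given discrimination; unclamped, range-flagged."""
        return fraction_at(self.line(element), discrimination)

    def implied_discrimination(self, element: str, fraction: float = 1.0) -> float:
        """Discrimination (permil) implied by a given diet fraction (default 1:
        the focal source is the sole source of the element)."""
        return discrimination_at(self.line(element), fraction)

    def summary(self) -> str:
        """Human-readable summary table (coefficients to two decimals,
        implied discriminations to one, matching reporting convention)."""
        m = self.model
        out = ["Two-source isotope mixing model", "=" * 47]
        out.append(f"consumer: {m.consumer}   source1: {m.source1}   source2: {m.source2}")
        out.append("")
        out.append(self.group_means.round(3).to_string())
        out.append("")
        out.append("fraction(Delta) = intercept + slope * Delta")
        for el, name in (("N", "d15N"), ("C", "d13C")):
            ln = self.line(el)
            se = ""
            if ln.intercept_se is not None:
                se = f"  (se {ln.intercept_se:.3f} / {ln.slope_se:.3f})"
            out.append(f"  {name}: intercept {ln.intercept:+.2f}, slope {ln.slope:.2f} per permil{se}")
        out.append("")
        for el, name in (("N", "Delta15N"), ("C", "Delta13C")):
            d = self.implied_discrimination(el, 1.0)
            out.append(f"  implied {name} at fraction 1: {d:.1f} permil")
        return "\n".join(out)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-element frame of line coefficients and implied Deltas."""
        rows = []
        for el in ("N", "C"):
            ln = self.line(el)
            rows.append({
                "element": el,
                "intercept": ln.intercept,
                "slope": ln.slope,
                "intercept_se": ln.intercept_se,
                "slope_se": ln.slope_se,
                "implied_discrimination_at_1": self.implied_discrimination(el, 1.0),
            })
        return pd.DataFrame(rows)

    def plot(self, discrimination_range=(-1.0, 5.0), ax=None):
        """Plot fraction vs discrimination for both elements.

        Shades the [0, 1] fraction band; the curves outside it are the
        diagnostic out-of-range region.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5.5, 4))
        d = np.linspace(*discrimination_range, 200)
        for el, label, style in (("N", r"$\Delta^{15}$N", "-"),
                                 ("C", r"$\Delta^{13}$C", "--")):
            ln = self.line(el)
            ax.plot(d, ln.intercept + ln.slope * d, style, label=label)
        ax.axhspan(0, 1, color="0.9", zorder=0)
        ax.axhline(1.0, color="0.6", lw=0.8)
        ax.set_xlabel("discrimination (permil)")
        ax.set_ylabel(f"fraction from {self.model.source1}")
        ax.legend()
        return ax
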