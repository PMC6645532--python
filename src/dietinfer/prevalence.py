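"""Chloroplast-prevalence model: filter, summarise, and test by diet class."""

from __future__ import annotations

import pandas as pd

from . import stats
from .feature_table import FeatureTable, FilterSpec, chloroplast_proportions, filter_feature_table


class ChloroplastPrevalenceModel:
    """Chloroplast read-proportion analysis of a 16S feature table.

    Applies the standard quality filter, computes per-sample chloroplast
    proportions, and compares them across groups (diet classes by
    default) with a Kruskal-Wallis test and corrected pairwise rank-sum
    tests.

    Parameters
    ----------
    table : FeatureTable
        Unfiltered counts + taxonomy + metadata.
    filter_spec : FilterSpec, optional
        Quality thresholds; defaults to the standard
        10-read / 0.01% / 500-read rule set.
    group_by : str
        Metadata column defining the comparison groups
        (``diet_class`` or e.g. ``tissue_type``).
    """

    def __init__(self, table: FeatureTable, filter_spec: FilterSpec | None = None,
                 group_by: str = "diet_class"):
        if group_by not in table.metadata.columns:
            raise ValueError(f"metadata has no column {group_by!r}")
        self.table = table
        self.filter_spec = filter_spec or FilterSpec()
        self.group_by = group_by

    def fit(self, correction: str = "holm") -> "PrevalenceResults":
        """Filter, compute proportions, and run the group comparisons.

        Groups with a single member are kept in summaries; tests run on
        whatever groups remain after filtering (at least two required
        for the Kruskal-Wallis / pairwise stage, which is otherwise
        skipped with ``kruskal=None``).
        """
        filtered = filter_feature_table(self.table, self.filter_spec)
        props = chloroplast_proportions(filtered)
        groups = {
            str(g): sub["proportion"].to_numpy()
            for g, sub in props.groupby(self.group_by, sort=False)
        }
        summary = stats.group_summary(groups) if groups else None
        kw = pw = None
        if len(groups) >= 2:
            kw = stats.kruskal_wallis(groups)
            pw = stats.pairwise_ranksum(groups, correction=correction)
        return PrevalenceResults(self, filtered, props, summary, kw, pw)


class PrevalenceResults:
    """Per-sample proportions plus group summaries and rank tests."""

    def __init__(self, model, filtered_table: FeatureTable, proportions: pd.DataFrame,
                 group_summary: pd.DataFrame | None, kruskal, pairwise):
        self.model = model
        self.filtered_table = filtered_table
        self.proportions = proportions
        self.group_summary = group_summary
        self.kruskal = kruskal          # TestResult or None
        self.pairwise = pairwise or []  # list[TestResult]

    def summary(self) -> str:
        out = ["Chloroplast prevalence analysis", "=" * 47]
        out.append(f"samples retained: {len(self.proportions)}   "
                   f"OTUs retained: {self.filtered_table.n_otus}")
        if self.group_summary is not None:
            gs = self.group_summary.copy()
            gs[["median", "iqr", "min", "max"]] = (gs[["median", "iqr", "min", "max"]] * 100)
            out.append("")
            out.append("per-group chloroplast % of library:")
            out.append(gs.round(1).to_string())
        if self.kruskal is not None:
            k = self.kruskal
            out.append("")
            out.append(f"Kruskal-Wallis: chi2({int(k.df)}) = {k.statistic:.3f}, "
                       f"p = {k.p_value:.4g}")
            for r in self.pairwise:
                out.append(f"  {r.groups[0]} vs {r.groups[1]}: p = {r.p_value:.4g} "
                           f"(adjusted {r.p_adjusted:.4g})")
        return "\n".join(out)

    def tests_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready frame of all test results."""
        rows = []
        if self.kruskal is not None:
            rows.append(self.kruskal)
        rows.extend(self.pairwise)
        return stats.results_to_frame(rows)
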