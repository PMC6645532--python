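"""Feature-table container, lineage handling, filtering, proportions, I/O."""

import numpy as np
import pandas as pd
import pytest

from dietinfer import (FeatureTable, FilterSpec, chloroplast_proportions,
                       filter_feature_table, is_bacterial, is_chloroplast,
                       parse_lineage)
from dietinfer.feature_table import is_mitochondrial

from conftest import make_table


@pytest.mark.parametrize(
    "lineage, expected",
    [
        ("k__Bacteria; p__Cyanobacteria; c__Chloroplast",
         ["Bacteria", "Cyanobacteria", "Chloroplast"]),
        ("k__Bacteria", ["Bacteria"]),
        ("Unassigned", ["Unassigned"]),
        ("k__Bacteria; p__Firmicutes; c__; o__", ["Bacteria", "Firmicutes", "", ""]),
    ],
)
def test_parse_lineage(lineage, expected):
    assert parse_lineage(lineage) == expected


@pytest.mark.parametrize(
    "lineage, chl, bact",
    [
        (["Bacteria", "Cyanobacteria", "Chloroplast"], True, True),
        (["Bacteria", "Firmicutes", "Bacilli"], False, True),
        (["bacteria", "cyanobacteria", "chloroplast", "streptophyta"], True, True),
        (["Archaea", "Euryarchaeota"], False, False),
        (["Unassigned"], False, False),
    ],
)
def test_lineage_classification(lineage, chl, bact):
    assert is_chloroplast(lineage) is chl
    assert is_bacterial(lineage) is bact


def test_mitochondria_not_chloroplast():
    lin = "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria; o__Rickettsiales; f__mitochondria"
    assert is_mitochondrial(lin)
    assert not is_chloroplast(lin)
    assert is_bacterial(lin)


class TestFilter:
    def test_toy_table_hand_derived(self, toy_table):
        """Five-step filter on the documented toy table: with library totals
        601 and 10400, the 0.01% floors are 0.0601 and 1.04, so otu2's
        single read in s1 (1/601 ~ 0.17%) survives and the output equals
        the input."""
        out = filter_feature_table(toy_table, FilterSpec())
        pd.testing.assert_frame_equal(out.counts, toy_table.counts)

    def test_low_total_otu_dropped(self):
        t = make_table(
            counts={"a": {"s1": 9, "s2": 0}, "b": {"s1": 600, "s2": 600}},
            taxonomy={"a": "k__Bacteria; p__X", "b": "k__Bacteria; p__Y"},
        )
        out = filter_feature_table(t)
        assert list(out.counts.index) == ["b"]

    def test_shallow_sample_dropped(self):
        t = make_table(
            counts={"a": {"s1": 499, "s2": 800}},
            taxonomy={"a": "k__Bacteria; p__X"},
        )
        out = filter_feature_table(t)
        assert list(out.counts.columns) == ["s2"]

    def test_non_bacterial_dropped_but_chloroplast_kept(self):
        t = make_table(
            counts={
                "chl": {"s1": 300},
                "arch": {"s1": 300},
                "un": {"s1": 300},
                "bact": {"s1": 300},
            },
            taxonomy={
                "chl": "k__Bacteria; p__Cyanobacteria; c__Chloroplast",
                "arch": "k__Archaea; p__Euryarchaeota",
                "un": "Unassigned",
                "bact": "k__Bacteria; p__Firmicutes",
            },
        )
        out = filter_feature_table(t)
        assert set(out.counts.index) == {"chl", "bact"}

    def test_fraction_rule_zeroes_per_sample(self):
        # 50/1e6 = 0.005% < 0.01% in s1 only; strict less-than
        t = make_table(
            counts={"a": {"s1": 50, "s2": 50}, "b": {"s1": 999950, "s2": 1000}},
            taxonomy={"a": "k__Bacteria; p__X", "b": "k__Bacteria; p__Y"},
        )
        out = filter_feature_table(t)
        assert out.counts.loc["a", "s1"] == 0
        assert out.counts.loc["a", "s2"] == 50

    def test_global_fraction_variant_drops_otu(self):
        t = make_table(
            counts={"a": {"s1": 50, "s2": 1}, "b": {"s1": 999950, "s2": 99999}},
            taxonomy={"a": "k__Bacteria; p__X", "b": "k__Bacteria; p__Y"},
        )
        out = filter_feature_table(t, FilterSpec(per_sample_fraction_rule=False))
        assert list(out.counts.index) == ["b"]

    def test_input_not_modified(self, toy_table):
        before = toy_table.counts.copy()
        with pytest.warns(UserWarning, match="empty"):
            filter_feature_table(toy_table, FilterSpec(min_otu_total=10**6))
        pd.testing.assert_frame_equal(toy_table.counts, before)

    def test_empty_result_warns_not_raises(self, toy_table):
        with pytest.warns(UserWarning, match="empty"):
            out = filter_feature_table(toy_table, FilterSpec(min_otu_total=10**7))
        assert out.n_otus == 0 and out.n_samples == 0

    def test_drop_mitochondrial_flag(self):
        t = make_table(
            counts={"mito": {"s1": 600}, "b": {"s1": 600}},
            taxonomy={"mito": "k__Bacteria; f__mitochondria", "b": "k__Bacteria; p__Y"},
        )
        assert set(filter_feature_table(t).counts.index) == {"mito", "b"}
        out = filter_feature_table(t, FilterSpec(drop_mitochondrial=True))
        assert set(out.counts.index) == {"b"}


@pytest.mark.parametrize(
    "chl, bact, expected",
    [(0, 1200, 0.0), (700, 0, 1.0), (584, 416, 0.584)],
)
def test_proportion_arithmetic(chl, bact, expected):
    t = make_table(
        counts={"c": {"s1": chl}, "b": {"s1": bact}},
        taxonomy={"c": "k__Bacteria; p__Cyanobacteria; c__Chloroplast",
                  "b": "k__Bacteria; p__Firmicutes"},
    )
    props = chloroplast_proportions(t)
    assert props.loc["s1", "proportion"] == pytest.approx(expected)
    assert props.loc["s1", "chloroplast_reads"] + (
        props.loc["s1", "total_reads"] - props.loc["s1", "chloroplast_reads"]
    ) == props.loc["s1", "total_reads"]


def test_proportions_carry_metadata(toy_table):
    props = chloroplast_proportions(toy_table)
    assert set(props.columns) >= {"proportion", "diet_class", "tissue_type", "species"}
    assert ((props["proportion"] >= 0) & (props["proportion"] <= 1)).all()


def test_tsv_roundtrip(tmp_path, toy_table):
    paths = [tmp_path / n for n in ("c.tsv", "t.tsv", "m.tsv")]
    toy_table.to_tsv(*paths)
    back = FeatureTable.from_tsv(*paths)
    pd.testing.assert_frame_equal(back.counts, toy_table.counts)
    pd.testing.assert_series_equal(back.taxonomy, toy_table.taxonomy,
                                   check_names=False)
    pd.testing.assert_frame_equal(back.metadata, toy_table.metadata)


def test_biom_json_roundtrip(tmp_path, toy_table):
    path = tmp_path / "table.biom"
    toy_table.to_biom_json(path)
    back = FeatureTable.from_biom_json(path)
    pd.testing.assert_frame_equal(back.counts, toy_table.counts)
    assert is_chloroplast(back.taxonomy["otu1"])
    assert back.metadata.loc["s1", "diet_class"] == "unknown"


def test_biom_sparse_reader(tmp_path):
    import json
    doc = {
        "format": "Biological Observation Matrix 1.0.0",
        "matrix_type": "sparse", "shape": [2, 2],
        "rows": [{"id": "o1", "metadata": {"taxonomy": ["k__Bacteria", "p__X"]}},
                 {"id": "o2", "metadata": None}],
        "columns": [{"id": "s1", "metadata": {"diet_class": "phytophagous"}},
                    {"id": "s2", "metadata": None}],
        "data": [[0, 0, 5], [1, 1, 7]],
    }
    path = tmp_path / "sparse.biom"
    path.write_text(json.dumps(doc))
    t = FeatureTable.from_biom_json(path)
    assert t.counts.loc["o1", "s1"] == 5 and t.counts.loc["o2", "s2"] == 7
    assert t.counts.loc["o1", "s2"] == 0
    assert t.taxonomy["o2"] == "Unassigned"


def test_invariant_violations_raise():
    with pytest.raises(ValueError, match="taxonomy"):
        make_table(counts={"a": {"s1": 1}}, taxonomy={})
    with pytest.raises(ValueError, match="non-negative"):
        make_table(counts={"a": {"s1": -1}}, taxonomy={"a": "k__Bacteria"})
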