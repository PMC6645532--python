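"""Amplicon feature tables: container, taxonomy helpers, quality filtering, I/O.

A :class:`FeatureTable` bundles the three objects every 16S gut-content
analysis needs: an OTU x sample count matrix, a per-OTU ranked taxonomy
lineage, and per-sample metadata (species, tissue type, diet class).
Universal bacterial 16S primers co-amplify plastid 16S, so chloroplast
reads appear in gut libraries; here they are a diet signal, not
contamination, and the taxonomy helpers below identify them.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIET_CLASSES = ("phytophagous", "aphytophagous", "unknown")
TISSUE_TYPES = ("gut", "whole")

#: Metadata columns every sample record carries.
METADATA_COLUMNS = ("species", "tissue_type", "diet_class")

_RANK_PREFIXES = tuple(f"{r}__" for r in "kpcofgs")


def parse_lineage(lineage: str) -> list[str]:
    """Split a Greengenes-style lineage string into ordered rank tokens.

    Splits on ``;``, strips surrounding whitespace and single-letter rank
    prefixes (``k__`` ... ``s__``), and preserves rank order.  Empty ranks
    (e.g. a bare ``g__``) are retained as empty strings so positional rank
    information survives truncation.  Input without separators comes back
    as a single-token lineage; a warning is logged if it also fails to
    look like a rank token.
    """
    if not isinstance(lineage, str):
        logger.warning("non-string lineage %r treated as unranked", lineage)
        return [str(lineage)]
    parts = [p.strip() for p in lineage.split(";")]
    tokens = []
    for p in parts:
        if p[:3].lower() in _RANK_PREFIXES:
            tokens.append(p[3:].strip())
        else:
            tokens.append(p)
    if len(tokens) == 1 and tokens[0] == lineage.strip() and "__" in lineage:
        logger.warning("lineage %r looks malformed; kept as single token", lineage)
    return tokens


def is_chloroplast(lineage: list[str] | str) -> bool:
    """True if any rank token equals ``chloroplast`` (case-insensitive).

    Matching by token rather than by fixed rank position tolerates
    truncated lineages and the Greengenes convention of placing
    Chloroplast at the class rank under Cyanobacteria.
    """
    if isinstance(lineage, str):
        lineage = parse_lineage(lineage)
    return any(tok.strip().lower() == "chloroplast" for tok in lineage)


def is_mitochondrial(lineage: list[str] | str) -> bool:
    """True if any rank token equals ``mitochondria``/``mitochondrion``."""
    if isinstance(lineage, str):
        lineage = parse_lineage(lineage)
    return any(tok.strip().lower() in ("mitochondria", "mitochondrion") for tok in lineage)


def is_bacterial(lineage: list[str] | str) -> bool:
    """True if the domain rank is ``bacteria`` (case-insensitive).

    Chloroplast lineages sit under domain Bacteria in 16S reference
    taxonomies and therefore count as bacterial: the domain filter must
    keep them, since they carry the diet signal.
    """
    if isinstance(lineage, str):
        lineage = parse_lineage(lineage)
    return bool(lineage) and lineage[0].strip().lower() == "bacteria"


@dataclass(frozen=True)
class FilterSpec:
    """Quality-filter thresholds for a feature table.

    min_otu_total
        Drop OTUs whose summed count across all samples is below this
        (default 10 reads).
    min_sample_fraction
        Zero any per-sample count below this fraction of that sample's
        library (default 1e-4, i.e. 0.01%).  Comparison is strict
        less-than.
    min_library_size
        Drop samples whose filtered library falls below this (default 500
        reads).
    drop_non_bacterial
        Remove OTUs outside domain Bacteria (Archaea, Unassigned, ...).
    drop_mitochondrial
        Optionally remove mitochondrial 16S OTUs as well; off by default,
        in which case they count as ordinary bacterial-domain reads but
        never as chloroplast.
    per_sample_fraction_rule
        If True (default) the 0.01% rule zeroes counts per sample; if
        False an OTU is dropped globally when it fails the rule in every
        sample where it occurs.
    """

    min_otu_total: int = 10
    min_sample_fraction: float = 1e-4
    min_library_size: int = 500
    drop_non_bacterial: bool = True
    drop_mitochondrial: bool = False
    per_sample_fraction_rule: bool = True

    def __post_init__(self):
        if self.min_otu_total < 0 or self.min_library_size < 0:
            raise ValueError("filter thresholds must be >= 0")
        if not (0 <= self.min_sample_fraction < 1):
            raise ValueError("min_sample_fraction must be in [0, 1)")


@dataclass
class FeatureTable:
    """Sample x OTU count matrix with taxonomy and sample metadata.

    counts
        DataFrame of non-negative integers, rows indexed by OTU id,
        columns by sample id.
    taxonomy
        Series mapping OTU id -> lineage string (Greengenes style).
    metadata
        DataFrame indexed by sample id with columns ``species``,
        ``tissue_type`` (gut/whole) and ``diet_class``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    metadata: pd.DataFrame

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative integers")
        missing_tax = self.counts.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValueError(f"OTUs without taxonomy: {list(missing_tax)[:5]}")
        missing_meta = self.counts.columns.difference(self.metadata.index)
        if len(missing_meta):
            raise ValueError(f"samples without metadata: {list(missing_meta)[:5]}")
        for col in METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing column {col!r}")
        # keep auxiliary entries out: align strictly to the count matrix
        self.taxonomy = self.taxonomy.loc[self.counts.index]
        self.metadata = self.metadata.loc[self.counts.columns]
        self.counts.index.name = "otu_id"
        self.counts.columns.name = None
        self.taxonomy.index.name = "otu_id"
        self.metadata.index.name = "sample_id"

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.counts.copy(), self.taxonomy.copy(), self.metadata.copy())

    # -- I/O ------------------------------------------------------------

    def to_tsv(self, counts_path, taxonomy_path, metadata_path) -> None:
        """Write the TSV trio: count matrix, taxonomy map, sample metadata."""
        out = self.counts.copy()
        out.index.name = "otu_id"
        out.to_csv(counts_path, sep="\t")
        tax = self.taxonomy.rename("lineage").to_frame()
        tax.index.name = "otu_id"
        tax.to_csv(taxonomy_path, sep="\t")
        meta = self.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, taxonomy_path, metadata_path) -> "FeatureTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)["lineage"]
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(counts, taxonomy, metadata)

    def to_biom_json(self, path) -> None:
        """Write as a BIOM 1.0 JSON document (dense matrix)."""
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "dietinfer",
            "date": "",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [self.n_otus, self.n_samples],
            "rows": [
                {"id": otu, "metadata": {"taxonomy": parse_lineage(self.taxonomy[otu])}}
                for otu in self.counts.index
            ],
            "columns": [
                {"id": s, "metadata": self.metadata.loc[s].to_dict()}
                for s in self.counts.columns
            ],
            "data": self.counts.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_biom_json(cls, path) -> "FeatureTable":
        """Read a BIOM 1.0 JSON table (dense or sparse matrix type)."""
        with open(path) as fh:
            doc = json.load(fh)
        otu_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        n_r, n_c = doc["shape"]
        mat = np.zeros((n_r, n_c), dtype=np.int64)
        if doc["matrix_type"] == "dense":
            mat[:] = np.asarray(doc["data"], dtype=np.int64)
        elif doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = int(v)
        else:
            raise ValueError(f"unsupported BIOM matrix_type {doc['matrix_type']!r}")
        counts = pd.DataFrame(mat, index=otu_ids, columns=sample_ids)

        def _lineage(row):
            md = row.get("metadata") or {}
            tax = md.get("taxonomy")
            if tax is None:
                return "Unassigned"
            if isinstance(tax, list):
                return "; ".join(str(t) for t in tax)
            return str(tax)

        taxonomy = pd.Series([_lineage(r) for r in doc["rows"]], index=otu_ids)
        meta_rows = {}
        for c in doc["columns"]:
            md = c.get("metadata") or {}
            meta_rows[c["id"]] = {col: md.get(col, "") for col in METADATA_COLUMNS}
        metadata = pd.DataFrame.from_dict(meta_rows, orient="index")
        return cls(counts, taxonomy, metadata)


def filter_feature_table(table: FeatureTable, spec: FilterSpec | None = None) -> FeatureTable:
    """Apply the five-step quality filter; returns a new table.

    Steps, in order:

    1. drop OTUs whose domain is non-bacterial (if enabled), and
       mitochondrial OTUs if ``drop_mitochondrial`` is set;
    2. drop OTUs with total count across all samples < ``min_otu_total``;
    3. zero, per sample, any count strictly below
       ``min_sample_fraction`` x that sample's library total as it stands
       entering this step;
    4. drop OTUs whose counts are now all zero;
    5. drop samples whose remaining library total < ``min_library_size``.

    The input table is never modified.  A table that filters down to
    nothing is returned empty with a warning, not raised.
    """
    if spec is None:
        spec = FilterSpec()
    counts = table.counts.copy()

    # step 1: domain filter
    if spec.drop_non_bacterial or spec.drop_mitochondrial:
        keep = []
        for otu in counts.index:
            lin = parse_lineage(table.taxonomy[otu])
            if spec.drop_non_bacterial and not is_bacterial(lin):
                continue
            if spec.drop_mitochondrial and is_mitochondrial(lin):
                continue
            keep.append(otu)
        counts = counts.loc[keep]

    # step 2: global low-count OTUs
    counts = counts.loc[counts.sum(axis=1) >= spec.min_otu_total]

    # step 3: per-sample relative-abundance floor
    if spec.min_sample_fraction > 0 and counts.size:
        lib = counts.sum(axis=0)
        thresh = spec.min_sample_fraction * lib
        arr = counts.to_numpy()
        below = (arr < thresh.to_numpy()[None, :]) & (arr > 0)
        if spec.per_sample_fraction_rule:
            arr = np.where(below, 0, arr)
            counts = pd.DataFrame(arr, index=counts.index, columns=counts.columns)
        else:
            # global variant: drop OTUs that fail the rule in every sample
            # where they occur at all
            fails_everywhere = ((arr == 0) | below).all(axis=1)
            counts = counts.loc[~fails_everywhere]

    # step 4: all-zero OTUs
    if counts.size:
        counts = counts.loc[counts.sum(axis=1) > 0]

    # step 5: shallow samples
    if counts.size:
        counts = counts.loc[:, counts.sum(axis=0) >= spec.min_library_size]
    else:
        counts = counts.loc[:, []]

    if counts.size == 0:
        warnings.warn("feature table is empty after filtering", stacklevel=2)
    taxonomy = table.taxonomy.loc[counts.index]
    metadata = table.metadata.loc[counts.columns]
    return FeatureTable(counts, taxonomy, metadata)


def chloroplast_proportions(table: FeatureTable) -> pd.DataFrame:
    """Per-sample chloroplast read proportion with metadata labels.

    For each sample, ``proportion`` is the fraction of its retained reads
    assigned to chloroplast OTUs.  The table should already be filtered.
    Returns a DataFrame indexed by sample id with columns
    ``chloroplast_reads``, ``total_reads``, ``proportion``, ``species``,
    ``tissue_type``, ``diet_class``.
    """
    chl_mask = np.array([is_chloroplast(table.taxonomy[o]) for o in table.counts.index])
    chl = table.counts.loc[chl_mask].sum(axis=0) if chl_mask.any() else pd.Series(
        0, index=table.counts.columns, dtype=np.int64
    )
    total = table.counts.sum(axis=0)
    keep = total > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-total sample(s) from proportions",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "chloroplast_reads": chl[keep],
            "total_reads": total[keep],
            "proportion": chl[keep] / total[keep],
        }
    )
    out = out.join(table.metadata.loc[out.index, list(METADATA_COLUMNS)])
    out.index.name = "sample_id"
    return out
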