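"""Synthetic feature tables and isotope datasets for the trophic pipeline.

The amplicon generator emulates the structure of small lycaenid
gut-content 16S studies: per-sample libraries of roughly 15k-47k reads,
chloroplast read fractions that are exactly zero for aphytophagous
(ant-brood / hemipteran-feeding) species and broadly spread (a few
percent up to ~99%) for phytophagous and unknown-diet species, plus a
handful of non-bacterial OTUs (Archaea, unassigned) to exercise the
domain filter.  The isotope generator draws consumer values from the
two-source mixing model plus Gaussian noise, so the mixing-line fit can
be validated by parameter recovery.

Neither generator simulates raw reads, chimeras, sequencing error or
phylogenetic structure among OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import DIET_CLASSES, FeatureTable
from .isotope import mixing_forward

# Taxonomy templates: chloroplast OTUs sit at the class rank under
# Cyanobacteria, as in Greengenes 13_8.
CHLOROPLAST_LINEAGE = (
    "k__Bacteria; p__Cyanobacteria; c__Chloroplast; o__Streptophyta; f__; g__; s__"
)
_BACTERIAL_PHYLA = (
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacteriales"),
    ("Firmicutes", "Bacilli", "Lactobacillales"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales"),
    ("Tenericutes", "Mollicutes", "Entomoplasmatales"),
)
_NON_BACTERIAL_LINEAGES = (
    "k__Archaea; p__Euryarchaeota; c__Methanobacteria",
    "Unassigned",
    "k__Archaea; p__Crenarchaeota",
)


@dataclass(frozen=True)
class FractionDist:
    """Distribution of the true chloroplast read fraction within a diet class.

    kind: ``point`` (all mass at ``value``), ``uniform`` on
    [``low``, ``high``], or ``beta`` with shapes ``a``, ``b``.
    """

    kind: str = "beta"
    value: float = 0.0
    low: float = 0.0
    high: float = 1.0
    a: float = 1.2
    b: float = 0.9

    def __post_init__(self):
        if self.kind not in ("point", "uniform", "beta"):
            raise ValueError(f"chl_fraction_dist: unknown kind {self.kind!r}")
        if self.kind == "point" and not 0.0 <= self.value <= 1.0:
            raise ValueError("chl_fraction_dist: point value must lie in [0, 1]")
        if self.kind == "uniform" and not 0.0 <= self.low <= self.high <= 1.0:
            raise ValueError("chl_fraction_dist: need 0 <= low <= high <= 1")
        if self.kind == "beta" and (self.a <= 0 or self.b <= 0):
            raise ValueError("chl_fraction_dist: beta shapes must be positive")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "point":
            return self.value
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(rng.beta(self.a, self.b))

    @classmethod
    def from_spec(cls, spec) -> "FractionDist":
        """Accept a FractionDist, a bare float (point mass) or a dict spec."""
        if isinstance(spec, FractionDist):
            return spec
        if isinstance(spec, (int, float)):
            return cls(kind="point", value=float(spec))
        if isinstance(spec, dict):
            try:
                return cls(**spec)
            except TypeError as exc:
                raise ValueError(f"chl_fraction_dist: bad spec {spec!r}: {exc}") from exc
        raise ValueError(f"chl_fraction_dist: cannot interpret {spec!r}")


def _default_class_sizes() -> dict[str, int]:
    # mirrors the study design: 8 phytophagous, 6 aphytophagous guts/whole
    # caterpillars and 17 focal-species samples of unknown diet
    return {"phytophagous": 8, "aphytophagous": 6, "unknown": 17}


def _default_fraction_dists() -> dict[str, FractionDist]:
    return {
        "phytophagous": FractionDist("beta", a=1.2, b=0.9),
        "aphytophagous": FractionDist("point", value=0.0),
        "unknown": FractionDist("beta", a=1.2, b=0.9),
    }


@dataclass
class AmpliconSimConfig:
    """Configuration for :func:`generate_feature_table`.

    n_samples_per_class
        Mapping diet class -> sample count (or a single int applied to
        every class in ``diet_classes``).
    chl_fraction_dist
        Per-class distribution of the true chloroplast read fraction.
    library_size_range
        Inclusive integer bounds for per-sample library size, drawn
        uniformly; the default brackets typical post-QC 16S depths.
    n_otus
        Total OTU count, split into a small chloroplast pool,
        ``n_non_bacterial`` non-bacterial OTUs and bacterial OTUs.
    rare_otu_rate
        Fraction of bacterial OTUs whose expected total count falls below
        the standard 10-read filter, to exercise the low-count rule.
    whole_caterpillar_rate
        Fraction of samples labelled tissue_type "whole" instead of "gut".
    """

    n_samples_per_class: dict[str, int] | int = field(default_factory=_default_class_sizes)
    diet_classes: tuple[str, ...] = DIET_CLASSES
    chl_fraction_dist: dict[str, FractionDist] = field(default_factory=_default_fraction_dists)
    library_size_range: tuple[int, int] = (15000, 47000)
    n_otus: int = 60
    n_chloroplast_otus: int = 5
    n_non_bacterial: int = 3
    rare_otu_rate: float = 0.1
    whole_caterpillar_rate: float = 0.15
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.library_size_range
        if lo < 1 or lo > hi:
            raise ValueError("library_size_range: need 1 <= low <= high")
        if self.n_otus < 2:
            raise ValueError("n_otus must be >= 2")
        if self.n_chloroplast_otus < 1 or self.n_non_bacterial < 0:
            raise ValueError("n_chloroplast_otus >= 1 and n_non_bacterial >= 0 required")
        if self.n_chloroplast_otus + self.n_non_bacterial >= self.n_otus:
            raise ValueError("n_otus too small for the requested OTU pools")
        if not 0.0 <= self.rare_otu_rate <= 1.0:
            raise ValueError("rare_otu_rate must lie in [0, 1]")
        if isinstance(self.n_samples_per_class, int):
            self.n_samples_per_class = {c: self.n_samples_per_class for c in self.diet_classes}
        unknown = set(self.n_samples_per_class) - set(self.diet_classes)
        if unknown:
            raise ValueError(f"n_samples_per_class: unknown diet classes {sorted(unknown)}")
        self.chl_fraction_dist = {
            k: FractionDist.from_spec(v) for k, v in self.chl_fraction_dist.items()
        }


def _sample_rng(seed: int, class_idx: int, sample_idx: int) -> np.random.Generator:
    # per-sample stream: adding samples or classes never reshuffles
    # draws for earlier samples
    return np.random.default_rng([seed, class_idx, sample_idx])


def generate_feature_table(cfg: AmpliconSimConfig) -> FeatureTable:
    """Draw a synthetic sample x OTU count table with taxonomy and metadata.

    For each sample: the library size is uniform on
    ``library_size_range``; the chloroplast read count is binomial around
    the class-specific true fraction; a small binomial share of the rest
    goes to non-bacterial OTUs; chloroplast/bacterial/non-bacterial reads
    are spread over their OTU pools multinomially with Dirichlet weights
    fixed per table.  Counts always sum exactly to the library size.
    Deterministic for a fixed seed.
    """
    n_chl = cfg.n_chloroplast_otus
    n_nonb = cfg.n_non_bacterial
    n_bact = cfg.n_otus - n_chl - n_nonb

    otu_ids = [f"OTU{i:04d}" for i in range(cfg.n_otus)]
    lineages = []
    table_rng = np.random.default_rng([cfg.seed, 2**20])
    for i in range(cfg.n_otus):
        if i < n_chl:
            lineages.append(CHLOROPLAST_LINEAGE)
        elif i < n_chl + n_nonb:
            lineages.append(_NON_BACTERIAL_LINEAGES[i % len(_NON_BACTERIAL_LINEAGES)])
        else:
            ph, cl, od = _BACTERIAL_PHYLA[i % len(_BACTERIAL_PHYLA)]
            lineages.append(f"k__Bacteria; p__{ph}; c__{cl}; o__{od}; f__; g__; s__")
    taxonomy = pd.Series(lineages, index=otu_ids)

    # per-table OTU relative weights; rare bacterial OTUs get weights so
    # small their expected table-wide total sits below the 10-read filter
    chl_w = table_rng.dirichlet(np.full(n_chl, 2.0)) if n_chl else np.array([])
    bact_w = table_rng.dirichlet(np.full(n_bact, 1.0)) if n_bact else np.array([])
    n_rare = int(round(cfg.rare_otu_rate * n_bact))
    if n_rare:
        total_samples = sum(cfg.n_samples_per_class.values())
        mean_lib = np.mean(cfg.library_size_range)
        rare_idx = np.argsort(bact_w)[:n_rare]
        # expected total count across the table ~ 5 reads (< 10 threshold)
        target = 5.0 / max(total_samples * mean_lib, 1.0)
        bact_w[rare_idx] = target
        other = np.setdiff1d(np.arange(n_bact), rare_idx)
        if other.size:
            bact_w[other] *= (1.0 - target * n_rare) / bact_w[other].sum()
    nonb_w = table_rng.dirichlet(np.full(n_nonb, 1.0)) if n_nonb else np.array([])

    lo, hi = cfg.library_size_range
    columns = {}
    meta_rows = {}
    for class_idx, diet in enumerate(cfg.diet_classes):
        n_samples = cfg.n_samples_per_class.get(diet, 0)
        try:
            dist = cfg.chl_fraction_dist[diet]
        except KeyError:
            raise ValueError(f"chl_fraction_dist: missing diet class {diet!r}") from None
        for j in range(n_samples):
            rng = _sample_rng(cfg.seed, class_idx, j)
            lib = int(rng.integers(lo, hi + 1))
            frac = dist.draw(rng)
            n_chl_reads = int(rng.binomial(lib, frac))
            n_nonb_reads = int(rng.binomial(lib - n_chl_reads, 0.01)) if n_nonb else 0
            n_bact_reads = lib - n_chl_reads - n_nonb_reads
            col = np.zeros(cfg.n_otus, dtype=np.int64)
            if n_chl and n_chl_reads:
                col[:n_chl] = rng.multinomial(n_chl_reads, chl_w)
            if n_nonb and n_nonb_reads:
                col[n_chl:n_chl + n_nonb] = rng.multinomial(n_nonb_reads, nonb_w)
            if n_bact and n_bact_reads:
                col[n_chl + n_nonb:] = rng.multinomial(n_bact_reads, bact_w)
            sid = f"{diet[:4]}_{j:02d}"
            columns[sid] = col
            meta_rows[sid] = {
                "species": f"sp_{diet[:4]}_{j % 3}",
                "tissue_type": "whole" if rng.random() < cfg.whole_caterpillar_rate else "gut",
                "diet_class": diet,
            }

    counts = pd.DataFrame(columns, index=otu_ids, dtype=np.int64)
    metadata = pd.DataFrame.from_dict(meta_rows, orient="index")
    if metadata.empty:
        metadata = pd.DataFrame(columns=["species", "tissue_type", "diet_class"])
    return FeatureTable(counts, taxonomy, metadata)


# Default source means follow the printed group means of the study system
# (leaves and ant larvae; permil), with a common 0.5 permil noise scale.
# These are simulation defaults, not estimates.
@dataclass
class IsotopeSimConfig:
    """Configuration for :func:`generate_isotope_dataset`.

    true_p / true_q
        True leaf-derived fractions of nitrogen / carbon in [0, 1].
    delta15N_frac / delta13C_frac
        True trophic discrimination values (permil).
    source means / sds
        Gaussian parameters for the two sources; ``consumer_sd`` scales
        the consumer noise around the mixing-model mean.
    n_per_role
        Mapping role -> sample count; defaults follow a realistic field
        design (17 consumers, 47 leaf samples, 20 ant larvae).
    """

    true_p: float = 1.0
    true_q: float = 1.0
    delta15N_frac: float = 1.61
    delta13C_frac: float = 2.8
    leaves_mean_d15N: float = 2.13
    leaves_mean_d13C: float = -28.3
    larvae_mean_d15N: float = 4.12
    larvae_mean_d13C: float = -26.5
    source_sds: float = 0.5
    consumer_sd: float = 0.5
    n_per_role: dict[str, int] = field(
        default_factory=lambda: {"consumer": 17, "leaves": 47, "larvae": 20}
    )
    paired: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.true_p <= 1.0 and 0.0 <= self.true_q <= 1.0):
            raise ValueError("true_p and true_q must lie in [0, 1]")
        if self.source_sds < 0 or self.consumer_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if any(n < 0 for n in self.n_per_role.values()):
            raise ValueError("n_per_role counts must be >= 0")


def generate_isotope_dataset(cfg: IsotopeSimConfig) -> pd.DataFrame:
    """Draw per-specimen isotope measurements from the mixing model.

    Source specimens are Gaussian around their role means; consumer
    specimens are Gaussian around the two-source mixing mean implied by
    ``true_p``/``true_q`` and the true discriminations.  Returns a long
    DataFrame (sample_id, role, species, d15N, d13C, pairing_id);
    ``pairing_id`` links consumer i to leaf/larva i when ``paired`` and
    counts allow.  Deterministic for a fixed seed.
    """
    consumer_mean_n = mixing_forward(cfg.true_p, cfg.leaves_mean_d15N,
                                     cfg.larvae_mean_d15N, cfg.delta15N_frac)
    consumer_mean_c = mixing_forward(cfg.true_q, cfg.leaves_mean_d13C,
                                     cfg.larvae_mean_d13C, cfg.delta13C_frac)
    means = {
        "consumer": (consumer_mean_n, consumer_mean_c, cfg.consumer_sd),
        "leaves": (cfg.leaves_mean_d15N, cfg.leaves_mean_d13C, cfg.source_sds),
        "larvae": (cfg.larvae_mean_d15N, cfg.larvae_mean_d13C, cfg.source_sds),
    }
    species = {"consumer": "focal_lycaenid", "leaves": "host_tree", "larvae": "attendant_ant"}
    rows = []
    for role_idx, (role, n) in enumerate(sorted(cfg.n_per_role.items())):
        if role not in means:
            raise ValueError(f"n_per_role: unknown role {role!r}")
        mu_n, mu_c, sd = means[role]
        rng = np.random.default_rng([cfg.seed, 2**16 + role_idx])
        d15 = mu_n + sd * rng.standard_normal(n)
        d13 = mu_c + sd * rng.standard_normal(n)
        for i in range(n):
            rows.append({
                "sample_id": f"{role}_{i:05d}",
                "role": role,
                "species": species[role],
                "d15N": float(d15[i]),
                "d13C": float(d13[i]),
                "pairing_id": f"tree_{i:05d}" if cfg.paired else None,
            })
    df = pd.DataFrame(rows, columns=["sample_id", "role", "species", "d15N", "d13C",
                                     "pairing_id"])
    return df


def write_isotope_csv(data: pd.DataFrame, path) -> None:
    """Write the isotope table as CSV (sample_id, role, species, d15N, d13C, pairing_id)."""
    data.to_csv(path, index=False)
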