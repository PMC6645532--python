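# dietinfer

Combined-evidence trophic inference for animals that cannot be observed
feeding. `dietinfer` implements the two indirect lines of evidence used
to assess whether a cryptic consumer (the motivating case is an
ant-associated lycaenid caterpillar living inside the swollen thorns of
its host tree) is herbivorous or carnivorous:

1. **Chloroplast 16S prevalence.** Universal bacterial 16S primers
   co-amplify plastid 16S, so plant-derived reads show up in gut-content
   amplicon libraries. After standard feature-table quality filtering
   (drop non-bacterial OTUs, OTUs with < 10 reads overall, per-sample
   counts below 0.01% of the library, samples with < 500 reads), the
   per-sample proportion of chloroplast reads is compared across known
   herbivores, known carnivores and the focal species with a
   Kruskal–Wallis test and Holm-corrected pairwise Wilcoxon rank-sum
   tests.

2. **Two-source stable-isotope mixing with free discrimination.** The
   consumer's isotope ratio is modelled as

   δX<sub>consumer</sub> = f·δX<sub>source1</sub> + (1−f)·δX<sub>source2</sub> + Δ

   for X ∈ {¹⁵N, ¹³C}, where *f* is the fraction of the element
   assimilated from source 1 (host-plant leaves) and Δ is the trophic
   discrimination (fractionation), assumed constant across sources.
   Substituting group means and solving for *f* gives a **line**
   f(Δ) = intercept + slope·Δ per element: fraction and discrimination
   are not separately identifiable from means alone, so the line itself
   is the result. Evaluating its inverse at f = 1 yields the
   discrimination a pure plant diet would imply, which can be compared
   with the 0–4‰ range reported for insect herbivores in feeding trials.

A synthetic-data module generates feature tables and isotope datasets
with the statistical structure the analysis assumes, so the whole
pipeline is testable without any deposited field data.

## Worked example

```python
from dietinfer import TwoSourceMixingModel

res = TwoSourceMixingModel.from_means(
    consumer_means=(3.74, -25.5),   # (d15N, d13C) of the focal caterpillars
    source1_means=(2.13, -28.3),    # host-tree leaves
    source2_means=(4.12, -26.5),    # attendant-ant larvae
)
print(res.summary())
```

prints

```
Two-source isotope mixing model
===============================================
consumer: consumer   source1: leaves   source2: larvae

          n  d15N_mean  d15N_sd  d15N_se  d13C_mean  d13C_sd  d13C_se
role
consumer  1       3.74      0.0      0.0      -25.5      0.0      0.0
leaves    1       2.13      0.0      0.0      -28.3      0.0      0.0
larvae    1       4.12      0.0      0.0      -26.5      0.0      0.0

fraction(Delta) = intercept + slope * Delta
  d15N: intercept +0.19, slope 0.50 per permil
  d13C: intercept -0.56, slope 0.56 per permil

  implied Delta15N at fraction 1: 1.6 permil
  implied Delta13C at fraction 1: 2.8 permil
```

Reading: if the caterpillars took **all** of their nitrogen from leaves
(f = 1), the implied nitrogen discrimination would be ≈ 1.6‰ — squarely
inside the range measured for lepidopteran herbivores — and the implied
carbon discrimination ≈ 2.8‰. A literature-typical full trophic step of
Δ¹⁵N ≈ 3.4‰ would instead imply a leaf fraction ≈ 1.9, flagged as
out-of-range: carnivory is the hypothesis the data strain against.

The amplicon stream works the same way from a feature table:

```python
from dietinfer import AmpliconSimConfig, ChloroplastPrevalenceModel, generate_feature_table

table = generate_feature_table(AmpliconSimConfig(seed=1))
print(ChloroplastPrevalenceModel(table).fit().summary())
```

which on this synthetic table prints per-class chloroplast percentages
(herbivore median 67.6%, carnivore 0%, focal 65.7%), a Kruskal–Wallis
χ²(2) = 14.24 (p = 8.1e-4) and Holm-adjusted pairwise p-values showing
the focal class indistinguishable from herbivores (p = 0.73) but
distinct from carnivores (p = 9.5e-4).

The `dietinfer` command-line tool chains everything
(`simulate`, `prevalence`, `isotope`, `report`/`all`) from a YAML
config and writes a combined JSON + Markdown evidence report with an
explicit, threshold-echoing qualitative call
(herbivory-consistent / carnivory-consistent / ambiguous).

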