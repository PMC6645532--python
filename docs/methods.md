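# Methods

## The inference problem

Direct feeding observations are impossible for consumers that live in
closed microhabitats (here: caterpillars inside ant-occupied domatia of
their host tree). `dietinfer` combines two indirect evidence streams —
plant-derived reads in gut-content 16S libraries, and stable-isotope
mixing — each with its own assumptions and failure modes, and reports
them side by side with an explicit decision rule rather than collapsing
them into a single statistic.

## Chloroplast prevalence from 16S feature tables

Plastid 16S co-amplifies with bacterial 16S under universal primers, so
the fraction of a gut library assigned to chloroplast OTUs is a
semi-quantitative herbivory signal: it measures relative amplicon
abundance, not ingested biomass, and it is legitimately zero in
carnivore guts. The pipeline takes a sample × OTU count matrix with
Greengenes-style ranked lineages and applies a five-step quality
filter, in a fixed documented order:

1. drop OTUs outside domain Bacteria (Archaea, unassigned);
   chloroplast lineages sit *under* Bacteria and are retained —
   dropping them would delete the signal;
2. drop OTUs with fewer than 10 reads summed over all samples;
3. zero any per-sample count strictly below 0.01% of that sample's
   library as it stands entering this step (per-sample zeroing; a
   global-removal variant is available via
   `FilterSpec(per_sample_fraction_rule=False)`);
4. drop OTUs left with all-zero counts;
5. drop samples with fewer than 500 remaining reads.

The order matters because the thresholds interact; fixing it makes the
0.01% rule well-defined. The filter is applied once, not iterated to a
fixed point; re-filtering stability is exercised over 100 random
synthetic tables in the test suite. Proportions are computed after
sample exclusion, so every reported denominator is ≥ 500 reads.
Mitochondrial 16S, if annotated, counts as bacterial-domain organellar
signal but never as chloroplast; a flag can exclude it entirely.

Chloroplast proportions are bounded, small-sample and heavily tied
(carnivore samples are exactly 0), so comparisons are rank-based: a
tie-corrected Kruskal–Wallis test across diet classes (χ² reference,
df = k−1), then all pairwise two-sided Wilcoxon rank-sum tests — exact
null distribution when both groups have ≤ 8 observations and no ties,
otherwise a tie-corrected normal approximation without continuity
correction (chosen so that with two groups the squared z equals the
Kruskal–Wallis H exactly). Pairwise p-values are Holm-adjusted by
default (Bonferroni and no correction available); Holm gives the same
family-wise guarantee as Bonferroni and is uniformly more powerful.
Group summaries report median and IQR with linear-interpolation
(type-7) quartiles — IQRs are convention-dependent, so the convention
is fixed and stated.

## Two-source isotope mixing with discrimination as a free parameter

δ¹⁵N (‰ vs atmospheric air) and δ¹³C (‰ vs VPDB) of a consumer are
modelled as a two-source mixture plus trophic discrimination Δ
(consumer − diet), assumed constant across the two sources within an
element — one Δ per element is a deliberate model property, not an
omission. With group means substituted, inverting for the source-1
fraction gives, per element,

    f(Δ) = (consumer − source2 − Δ) / (source1 − source2)
         = intercept + slope·Δ,

with intercept = (consumer − source2)/(source1 − source2) and
slope = −1/(source1 − source2) per ‰. Because f and Δ trade off
linearly, the package reports the whole line, the fraction implied by
any candidate Δ (unclamped, with an out-of-range flag — truncation
would hide diagnostic information), and the Δ implied by any candidate
fraction, especially f = 1 (single-source diet). Equal source means
make the fraction unidentifiable and raise an error rather than return
an arbitrary value. When the lines are fitted from per-specimen data,
delta-method standard errors for intercept and slope are propagated
from the three group-mean standard errors (independent groups assumed).
Display rounding follows field convention — two decimals for line
coefficients, one for implied discriminations — with full precision
kept internally.

Group comparisons use the unequal-variance t statistic with
Welch–Satterthwaite fractional df by default (a pooled-variance flag
exists); matched consumer/source specimens from one tree are compared
with a paired t on differences, driven by an explicit `pairing_id`
column (unmatched ids are an error listing the offenders, never an
implicit intersection). One-way ANOVA checks homogeneity among
life-stages of a source; a zero within-group sum of squares with
between-group spread is reported as F = ∞, p = 0 instead of dividing
by zero.

## Synthetic data: what it emulates and what it does not

The amplicon generator draws, per sample: a library size uniform on
15,000–47,000 reads (bracketing typical post-QC depths in small
gut-content studies); a true chloroplast fraction from a per-class
distribution — Beta(1.2, 0.9) for phytophagous and unknown classes
(broad, qualitatively matching the observed few-percent-to-98% spread;
the focal class defaults to the herbivore-like distribution because
that is the regime the decision rule must discriminate) and a point
mass at 0 for aphytophagous classes; a binomial chloroplast read count
around that fraction; ~1% of the remainder to non-bacterial OTUs; and
multinomial spreads over OTU pools with Dirichlet weights fixed per
table. A configurable fraction of bacterial OTUs ("rare", default 10%)
gets weights tuned so their expected table-wide total sits below the
10-read filter, exercising the low-count rule. Default class sizes
(8 phytophagous, 6 aphytophagous, 17 unknown) mirror a realistic field
design. Counts always sum exactly to the library size. One global seed
governs everything, with per-sample substreams keyed by (seed, class,
index) so enlarging a class never reshuffles earlier samples.

The generator does **not** simulate raw reads, sequencing error,
chimeras, compositional correlations between taxa, overdispersion
beyond the binomial/multinomial, or phylogenetic structure — so
passing tests demonstrate the statistical pipeline's correctness on
data satisfying its assumptions, not robustness to the artefacts of
real sequencing runs.

The isotope generator draws source specimens Gaussian around role
means (defaults: leaves 2.13‰/−28.3‰, ant larvae 4.12‰/−26.5‰, sd
0.5‰ — simulation defaults chosen near realistic field values, not
estimates) and consumer specimens Gaussian around the mixing-model
mean implied by the true fractions and discriminations (defaults
p = q = 1, Δ¹⁵N = 1.61‰, Δ¹³C = 2.8‰). With all noise at zero the
generate → fit → invert round trip returns the true fraction to
machine precision; this analytic identity anchors the stochastic
recovery tests. Real isotope data additionally carry tissue effects,
seasonal drift and non-Gaussian tails that the generator omits.

## The decision rule

The qualitative call is a codified convention, not an estimator:
*herbivory-consistent* requires the focal-vs-herbivore corrected
p ≥ α, the focal-vs-carnivore corrected p < α (default α = 0.05 on
corrected p-values), and — when isotope data are present — an implied
Δ¹⁵N at f = 1 inside a configurable plausible range (default 0–4‰,
the span of insect feeding-trial values). The mirrored pattern gives
*carnivory-consistent*; anything else, including missing evidence, is
*ambiguous*. Every threshold and input to the rule is echoed verbatim
in the report so the call is auditable.

## Numerical and design choices

- Strict `<` comparisons implement the "fewer than / less than"
  thresholds of the filter.
- Kruskal–Wallis on all-identical data returns H = 0, p = 1 (the
  tie-correction denominator vanishes there).
- The exact rank-sum branch refuses tied data instead of silently
  approximating.
- Problem sizes in the test suite (2,000 null replicates at n = 6 per
  group for calibration; 10,000 specimens per role for recovery; 100
  random tables for the filtering contract) were chosen as the
  smallest sizes at which the binomial/SE bounds being asserted are
  sharp enough to be informative.
- Large-replicate estimates (40,000 null datasets) put the true size
  of the Kruskal–Wallis test near 0.042 and the Holm family-wise rate
  near 0.041 under the calibration conditions: both mildly
  conservative, as expected for a χ² reference at n = 18 and discrete
  exact tests under Holm, and both inside the binomial 99% band that
  the 2,000-replicate suite asserts (a single 2,000-replicate draw has
  Monte Carlo sd ≈ 0.0045 around those rates, so the band check is
  informative but not razor-thin).
- The exact rank-sum null distribution is computed in-package by the
  standard counting recurrence and cached per group-size pair, so
  repeated exact tests in simulations cost microseconds; it is checked
  against both brute-force enumeration of all labelings and an
  independent library implementation.

## Known limitations

- Chloroplast proportions are compositional; the pipeline compares
  them only by ranks and makes no absolute-abundance claims.
- The mixing model is two-source, mean-based and concentration-
  independent; Bayesian multi-source mixing, trophic-position
  estimators and lipid correction are out of scope.
- The decision rule treats "non-significant vs herbivores" as
  compatibility, which at small n is weak evidence; the report
  therefore always carries the underlying p-values.
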