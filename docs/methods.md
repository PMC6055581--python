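# Methods

## The experimental design being modeled

Roots are treated with Nod factors (NF), the auxin analog NAA, their
combination, or solvent control, and transcriptomes are compared by
competitive two-color hybridization on four contrasts: NAA vs control, NF vs
control, NF+NAA vs control, and NF+NAA vs NAA. Each contrast is hybridized
as one dye-swapped technical pair per biological replicate, three biological
replicates, with each gene probed by three spots per array — 24
hybridizations in the default design. The pipeline estimates per-gene log₂
ratios per contrast, tests them, and classifies genes by how the combined
treatment relates to the single treatments.

## Synthetic data generator

The generator plants one response class per gene and derives the three true
condition LFCs (NAA, NF, NF+NAA vs control) from it:

| class | lfc_NAA | lfc_NF | lfc_NF+NAA |
|---|---|---|---|
| null | 0 | 0 | 0 |
| naa_only | ±m | 0 | = lfc_NAA |
| nf_only | 0 | ±m | = lfc_NF |
| additive | ±m | ±m′ | sum |
| syn_group1 | sub-threshold | sub-threshold | ±m |
| syn_group2_enhanced | ±m | 0 | 1.8 × lfc_NAA |
| syn_group2_antagonized | ±2m | 0 | 0.4 × lfc_NAA |
| syn_group3 | 0 | ±m | 0.6 × lfc_NF |

with m = 1.5 log₂ units by default and sub-threshold draws uniform within
±25% of the 0.75 DEG cutoff. Two magnitudes are forced by detectability:
group-2 antagonism is only callable when both the attenuated response and
the attenuation itself clear the fold-change cutoff, which requires the NAA
response of antagonized genes to exceed twice the cutoff (hence ±2m); and
the group-3 attenuation factor 0.6 puts the planted relative difference at
0.34 on the linear fold-change scale, just above the 30% rule, so that
class genuinely exercises the rule's boundary. Class counts follow
largest-remainder rounding of the requested proportions, making split sizes
exactly reproducible.

Signal propagates to spots as: expected M = (lfc_numerator −
lfc_denominator) + biological shift + spot noise + dye bias, where the
biological shift is a per-gene, per-biological-replicate Gaussian
(SD 0.3 log₂ units by default) shared by the technical pair; spot noise is
i.i.d. Gaussian (SD 0.2); and the dye bias is a deterministic function of
mean log intensity A — by default 0.8·tanh((A−10)/2.5), a smooth monotone
curve bounded by ±0.8 log₂ units, applied in the physical red/green frame
so it keeps its sign on swapped arrays while the gene effect flips.
Per-probe baseline intensities are N(10, 1.5²) on the log₂ scale, fixed
across arrays (probe affinity), and intensities are floored at 1.0 with a
flag rather than dropped. The noise magnitudes are calibration choices, not
estimates from any particular dataset.

What the generator does **not** emulate: probe sequence effects, spatial
array artifacts, background/foreground segmentation, print-tip structure,
missing spots, or correlated (batch) biological noise. Passing tests on
these simulations therefore validate the statistical machinery, not
robustness to those real-data pathologies.

## Preprocessing

MA coordinates per spot, then a global intensity-dependent LOESS
normalization of M on A — local-linear fit, span 0.4, three robustifying
(bisquare) iterations — subtracted from M. Arrays below 50 spots fall back
to median centering with a warning. Swapped arrays are sign-corrected, then
probes are averaged within arrays and technical replicates within
biological replicates, so each gene carries exactly one value per
biological replicate and contrast. Span and degree are assumptions (the
design gives none); degree 1 with robust reweighting is the standard
global-normalization choice.

Two practical properties of LOESS worth knowing:

- It is not exactly idempotent: renormalizing already-normalized data moves
  M by ~10⁻² at sparse intensity extremes. Exact idempotence holds only for
  degenerate trends (constant M).
- Its accuracy assumes most genes are unchanged. The fit absorbs signal in
  proportion to the local imbalance of up- vs down-regulated spots; with a
  null majority (≈60–70%) the per-gene error is ≈0.01–0.02 log₂ units on
  average, with rare single-gene excursions of 0.1–0.2 at the intensity
  extremes. Designs where most genes respond violate the assumption and
  bias the 30% rule of group 3 (see validation sizes below).

## Differential expression

Per gene: mean lfc, unbiased variance s², df = n−1 over biological
replicates (genes with fewer than two replicates are excluded with a
warning). The shrinkage prior (d₀, s₀²) is estimated by moment matching on
log s² under the scaled-inverse-χ² hierarchical model: with
e = log s² − ψ(df/2) + log(df/2), the excess of var(e) over the sampling
component ψ′(df/2) identifies d₀ through the trigamma inverse, and s₀²
follows from mean(e). Non-positive excess spread (exchangeable variances)
gives d₀ = ∞ with s₀² = mean(s²); fewer than 100 positive variances
triggers the same fallback with a warning; all-zero variances raise, since
the prior is undefined on noiseless input. The posterior variance is
s̃² = (d₀s₀² + df·s²)/(d₀ + df) and the moderated statistic
t = lfc/√(s̃²/n) is referred to the standard normal by default (a Student-t
reference with df + d₀ degrees of freedom is available by flag; the normal
is slightly anti-conservative at n = 3, which the error-control validation
quantifies). BH step-up adjustment and calls at p_adj ≤ 0.05 and
|lfc| ≥ 0.75, both boundaries inclusive.

Degenerate pipeline input (noiseless data ⇒ all s² = 0) is handled at the
pipeline level: the DE driver proceeds with (d₀ = ∞, s₀² = 0), so t = ±∞
and p = 0 for every gene with nonzero lfc — calls then rest on the
fold-change threshold alone, which is the correct limiting behavior.

## Interaction groups

With DEG(·) the set of genes passing the combined call in a contrast:

- group 1 = DEG(NF+NAA vs CT) minus DEG(NAA vs CT) and DEG(NF vs CT);
  direction from the combined contrast's call.
- group 2 = DEG(NF+NAA vs NAA) ∩ DEG(NAA vs CT) ∩ DEG(NF+NAA vs CT) minus
  DEG(NF vs CT); *enhanced* iff the two vs-control LFCs agree in sign and
  the combined one is larger in magnitude, else *antagonized* (sign
  reversals are antagonism). The rule formalizes the y=x scatter geometry;
  a variant using the direct-contrast LFC is available.
- group 3: candidates = DEG(NF vs CT) ∩ DEG(NF+NAA vs CT) minus
  DEG(NAA vs CT); members additionally satisfy
  |FC_NF+NAA − FC_NF| / |FC_NF| ≥ 0.30 on the linear fold-change scale
  FC = 2^lfc ("expression level" suggests the linear scale; a log-scale
  variant is exposed by flag).

The three groups are pairwise disjoint by construction and this is asserted
on every run. Group-1 ordering for heatmaps uses average-linkage
hierarchical clustering of the three vs-control LFC vectors under Euclidean
distance — deterministic for fixed input, zero-distance duplicates adjacent.

## GO-Slim enrichment

Terms map to every slim category reachable through is_a/part_of edges (a
term that is itself slim maps to itself; multiple parents can contribute
multiple slims, so category counts need not sum to the classified-gene
count). Terms with no slim ancestor fall into a per-aspect "other"
catch-all; genes present in the annotation but without a term in an aspect
fall into that aspect's "unknown" category; both participate in the
statistic. Genes absent from the annotation entirely are unclassified and
excluded from the counts — mirroring the convention that only part of an
input list "could be classified".

Per category: normed frequency
(n_in_class_input/n_classified_input)/(n_in_class_ref/n_classified_ref);
SD over 100 bootstrap resamples (with replacement) of the input set; and a
hypergeometric tail test with the tail chosen by comparing the observed
count to its expectation (ties go to the over tail, deterministically).
Significance is raw p < 0.05 without multiplicity correction, as in the
original web tool (a BH option exists, off by default). Because the tail is
chosen adaptively and each tail is tested at 0.05, the null flag rate of
the procedure lies between 5% and 10% — the validation suite compares the
observed rate to the exact null expectation computed by enumeration rather
than to a nominal 5%. Reports are ranked by normed frequency within aspect
and are byte-reproducible for a fixed seed.

## Validation problem sizes

- Noiseless recovery: 1600 genes, null-majority class mix (65% null,
  ≥ 50 genes per planted class), noise SDs 0, default dye bias. The null
  majority keeps the LOESS signal-absorption bias far below every decision
  boundary, so all planted labels (including directions and sub-labels) are
  recovered exactly.
- Noisy recovery: 20 000 genes, bio SD 0.3, spot SD 0.2, sigmoidal dye
  bias, planted |lfc| 1.5 — scores group-1 recall/precision and the
  fraction of dye bias removed (measured as the mean absolute LOESS trend
  of M minus the known gene effect, before vs after normalization).
- Error control: 20 all-null 20 000-gene replicate matrices for the raw-p
  level and BH zero-call rate; 50 uniform random input sets against a
  simulated annotation for the enrichment null rate.
- Prior recovery: variances simulated from the scaled-inverse-χ² model
  (d₀ = 4, s₀² = 0.04, 20 000 genes, df = 2), median estimates over 10
  replicates.
- Determinism: two complete 300-gene runs under one seed, compared byte by
  byte (the run manifest records no wall-clock timestamp by default for
  this reason).

## Known limitations

- One-sample contrasts only; no linear-model design matrices, array
  weights, or between-array quantile normalization.
- The local-fdr style adjustment sometimes used with moderated t-tests is
  out of scope; BH is the implemented procedure.
- The normal reference for the moderated t is anti-conservative for three
  replicates; the t reference option is provided for comparison.
- Enrichment assumes the input list is a subset of the reference genome
  and does not filter by GO evidence codes.
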