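# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `hybridforge`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and data model

All genomic positions are 1-based and all intervals closed, the VCF
convention; QTL peaks are named `chr{c}.s_{pos}`. Genotypes are
alt-allele dosages {0, 1, 2}; missing is NaN in memory and `NA` in TSV.
Missing data are never silently imputed: the only fills are the
documented mean-fill inside GRM/PCA/scan computations and the modal fill
of `impute_f1_missing`. Every filtering operation logs counts in and
out.

## NC-II design and F1 inference

The factorial is enumerated maternal-major, deterministically. The
training split is (all maternal × "full" testers) ∪ (a maternal subset ×
the remaining testers); its complement is the candidate set.

The five-step SNP filter runs in a fixed order. Criterion 1 flags
heterozygous parental *cells* (the derived F1 call becomes missing)
without removing variants; criteria 2–5 remove variants: excess
heterozygosity (rate ≥ 10% among maternal lines **or** ≥ 1/30 among
paternal testers — a single heterozygous tester suffices), within-pool
monomorphism, joint parental MAF < 0.02, and a minor-homozygote
frequency < 0.5% among the F1 genotypes of the *full* factorial.
Because transmission is purely homozygous, the factorial's homozygote
counts factorize (`count(f1 = 0) = count(m = 0) · count(p = 0)`), which
the filter exploits; a test verifies the factorization against explicit
enumeration. The filter is idempotent.

F1 inference assumes fully inbred parents: residual heterozygous calls
are handled solely by criterion 1 (missing), never by sampling a gamete,
to keep the pipeline deterministic. Missing F1 cells can be filled with
the modal dosage within the half-sib family sharing a tester (ties break
toward the lower dosage). This modal fill is a deliberately simple,
deterministic imputation; it ignores flanking-marker information and is
flagged in the log so downstream users can distinguish observed from
filled calls.

## Phenotypes

Per-line BLUPs come from REML on `value = μ + location + year + line +
ε` with line random, via statsmodels MixedLM; the reported BLUP is the
grand fixed-effect mean plus the shrunken line effect, so in the
balanced no-residual limit it equals the per-line mean.
Genotype-by-environment interaction is omitted; with the few
environments the generator produces it would not be identifiable.

Check-row adjustment subtracts (local check mean − global check mean)
from each plot, the local mean taken over check rows within a window of
the plot's row index (nearest check as fallback). It removes smooth
spatial trends captured by the checks and nothing else.

MPH is computed on BLUP values, before z-scoring (a flag point exists at
the call sites for per-location values); it is symmetric in the parents,
scale-invariant, and undefined (NaN) at zero mid-parent. z-score
transforms are estimated within each F1 population (one tester = one
population) and serialized so the inverse transform is exact.

## gBLUP

The centered GRM is `K = WWᵀ/p` with per-variant mean-centered dosages;
missing dosages are mean-filled only inside this computation. The mixed
model `y = Xβ + u + ε`, `u ~ N(0, Kσ_u²)`, is fitted by REML after a
single eigendecomposition of `K`: the restricted likelihood is profiled
down to the log variance ratio λ = σ_u²/σ_e², minimized on a 41-point
grid over log λ ∈ [−10, 10] and refined by bounded Brent search. This is
deterministic and, unlike a general-purpose mixed-model routine, exact
for an arbitrary dense PSD covariance. When the profile is flat (e.g.,
K ∝ I, where the split is unidentifiable) the tie breaks toward the
smallest ratio. Fixed effects are an intercept plus the maternal and
paternal BLUPs of the same trait — the simplest functional form that
absorbs parental-pool stratification. Candidate hybrids are predicted
via the cross-relationship block, `û_c = λ K_ct (λK_tt + I)^{-1}(y −
Xβ̂)`, and back-converted with the training population's z-score
transform. MPH traits go through the identical machinery as derived
traits.

Two evaluation schemes: leave-one-tester-out (one fold per tester;
folds with fewer than 3 test hybrids are skipped) and the reciprocal
tester-swap design (train on the shared maternal block plus one
tester's extension, predict the other tester's extension, and swap).

## GWAS

Variance components are estimated once under the null per (population,
trait) and reused for every variant — the standard
population-parameters-previously-determined approximation — with the
per-variant residual variance re-estimated from the GLS residuals so
that, with identity kinship and no covariates, the Wald t (df = n − c −
1) reproduces the simple-regression t-test exactly. `exact=True`
re-optimizes the ratio per variant for small panels. Kinship uses all
retained variants including the tested one (no leave-one-chromosome-out),
matching the single-GRM convention of the pipeline. Monomorphic variants
report β = 0, p = 1. Conditional GWAS keeps only the two homozygote
classes at the tag SNP (hets/missing excluded — an inbred-panel
convention), with kinship and null model re-fitted per class and a
minimum class size (default 30).

Significance tiers are fixed in `AnalysisConfig`: 2.2e-7 (genome-wide),
1e-6 (QTL calling), 1e-5 (relaxed, used for simulation-one FDR), and
1e-4 (suggestive).

## QTL summarization

Seed loci are maximal runs of significant SNPs whose *consecutive* gaps
are < 800 kbp (the clumping interpretation of the LD decay length).
Merging is a closure over **all** same-chromosome locus pairs — not just
adjacent ones — repeated until no pair with (any cross-locus r² > 0.1)
and (peak distance < 5 Mbp, measured peak-to-peak) remains; the first
mergeable pair in coordinate order merges each round, which makes the
fixpoint deterministic. LD is computed on the same population whose scan
produced the loci. Loci with ≥ 10 significant SNPs are emitted
(support = significant); smaller loci receive a single ±400 kbp
extension (half the LD length) collecting SNPs at p ≤ 1e-4 and are
emitted as suggestive if the total reaches 10, else dropped. Whether the
extension may repeat is exposed as `max_extensions` (default 1). Peaks
are minimum-p SNPs, ties broken by lowest position.

Cross-population merging is the transitive closure of closed-interval
overlap. Heterotic classification is a total function of the (maternal,
F1, MPH) detection booleans:

| M | F1 | MPH | class |
|---|----|-----|-------|
| 1 | 1  | 0   | additive |
| 1 | 1  | 1   | additive (flag: with-dominance) |
| 1 | 0  | 1   | dominant |
| 1 | 0  | 0   | unclassified (flag: maternal-only) |
| 0 | 1  | 0   | epistatic_DxA |
| 0 | 1  | 1   | epistatic_DxA (flag: subtype-ambiguous) |
| 0 | 0  | 1   | epistatic_DxD |
| 0 | 0  | 0   | unclassified |

The three-way scheme does not itself enumerate the (1,1,1) and (0,1,1)
cells; the flags record that mapping choice. Cumulative class effects
sum |peak β| per (trait, class), averaging each merged QTL's |β| over
the populations where it was detected.

## Synthetic data generator

`gen_inbred_genotypes` emulates a multi-parent inbred panel: 10
chromosomes, evenly spaced SNPs (default 50 kbp), dosages 0/2 with a
small residual-het rate (default 0.5%). LD comes from a per-sample
latent Gaussian AR(1) within blocks of 25 consecutive SNPs, thresholded
at each variant's frequency quantile; frequencies are drawn per block
from the requested spectrum with ±0.02 per-variant jitter, because SNPs
in strong LD have similar allele frequencies and frequency-mismatched
neighbours would otherwise tag a causal variant poorly. What it does
*not* emulate: recombination-driven long-range LD decay, population
substructure and admixture, allele-frequency differences between
heterotic pools, and genotyping error. Passing tests therefore
demonstrate the correctness of the algorithms under a clean
block-structured panel, not their behaviour under real-panel
confounding.

`gen_full_study` plants known architectures at LD-block centers (chosen
among blocks segregating at frequency 0.2–0.8 in the maternal pool):
three additive QTLs (`flowering`), one dominance-complemented QTL plus
one epistatically masked pair (`height`: locus B's additive effect is
gated by a carrier genotype at locus A, rare (4%) among maternal lines
and fixed in the testers), and two small masked pairs (`yield`).
Phenotypes add environment main effects and residual noise per
(location, year) on a baseline of 100 units so mid-parent values stay
positive. Default scale — 250 maternal lines × 4 testers, 2000 SNPs, 2
locations × 2 years — keeps a full pipeline run around two seconds while
leaving the planted loci comfortably detectable.

## Simulation studies

Study one follows the spike-in recipe exactly: 20 QTNs with geometric
effects `β_i = 0.96^i` drawn from the 0.25–0.35 MAF stratum, a purely
genetic "observed" phenotype `y = Σ x_i β_i` (an optional heritability
knob exists for extensions), and predicted phenotypes `y' = y + ε`,
`ε ~ N(0, var(y)(1−r²)/r²)`, so that corr(y, y')² ≈ r². QTN classes
threshold the *normalized* contribution `β f(1−f) / Σ β f(1−f)` at 7%
and 4.5%; the literal `βf(1−f)` is not a variance fraction and could not
meet those boundaries, so normalization is the default with `raw` and
`variance` modes exposed. Scans use fast per-variant regression without
kinship, because the simulated trait has no polygenic background
(`--with-kinship` style scanning is available through the main scan
API). Detection power is read at permutation thresholds (α-quantiles of
per-permutation minimum p over shuffled phenotypes); FDR at p ≤ 1e-5
uses a matching rule the recipe leaves open: significant SNPs are
clustered by the QTL grouping distance, and a cluster is a true
detection if it contains a QTN or any member SNP with r² > 0.1 to one.
QTN positions are redrawn every repetition.

The shipped full configuration is the study grid (six sizes × six
accuracies × 500 reps on 100,000 SNPs). The package's working scale for
tests and the acceptance script is the `reduced()` preset — 2,000
variants, sizes (207, 800), accuracies (1.0, 0.4, 0.1), 50 reps, 100
permutations — chosen as the smallest grid on which the qualitative laws
(power monotone in size and accuracy; FDR not rising as accuracy falls)
are resolvable above Monte-Carlo noise.

Study two shifts the two genotype classes of one random SNP apart by
±(effect × SD of the base phenotype) and counts how often that SNP beats
2.2e-7, over 19 effect gradients (0.1–1.9) × 100 SNPs at full scale and
a 4-gradient × 40-SNP reduced preset.

## Molecular design breeding

Haplotype groups are the observed homozygous genotype combinations over
the chosen loci (hets/missing excluded), labelled Hap1..HapK in
lexicographic dosage order — reproducible, though the numbering is
arbitrary. Group comparisons use Welch's unequal-variance t-test; "not
significantly reduced" for a protected trait means NOT (mean below
reference AND p < 0.05). Selection filters on that constraint and then
ranks lexicographically by the minimized trait means, ties broken by
label. The two-locus interaction contrast is the homozygote-corner
double difference with its standard error from the per-cell variances.

## Numerical choices and degenerate inputs

- REML grid + Brent on log λ: deterministic, bracket-safe; PSD tolerance
  1e-8 on the smallest eigenvalue of K.
- p-values floored at the smallest positive double; monomorphic variants
  p = 1.
- z-score on constant vectors, MPH at zero mid-parent, PCA with too many
  components, empty training splits, and single-class conditional tags
  all raise or flag explicitly rather than returning silent numbers.
- All stochastic operations take explicit seeds and are bit-reproducible.

## Limitations

- The modal F1 imputation is far cruder than haplotype-based imputation;
  at the generator's missingness rates (<1%) this is immaterial, but the
  flag matters for real data.
- Single additive GRM only: no dominance or epistasis relationship
  matrices, no Bayesian-alphabet models, no multi-trait gBLUP.
- The per-population variance-component reuse in scans slightly
  miscalibrates p-values at strongly associated variants; `exact=True`
  exists for small panels.
- Interval-overlap QTL merging across populations inherits the usual
  coarseness of interval methods: distinct linked causal loci can merge.
- The classifier's truth table is a deliberately sharp discretization of
  what is, in the underlying genetics, a continuum of gene action.
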