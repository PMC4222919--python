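# Methods

This note documents the statistical models implemented in `divlink`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model

The unit of observation is a genotyped individual tree carrying a species
label, a plot label and a vector of dominant binary calls: 1 = band present
(the dominant phenotype, "variant 1"), 0 = band absent (only recessive
alleles at the locus, "variant 2"), or missing. Frequencies are computed on
these band-presence **phenotypes**, not on Hardy–Weinberg-transformed allele
frequencies: dominant markers collapse genotype classes, and the analysis
treats the two phenotypic variants as the diversity-bearing units. (The
outlier scan, which needs allele frequencies, models dominance explicitly
instead — see below.) Missing calls reduce the per-locus sample size; no
imputation is performed. Loci with pooled variant-1 frequency < 0.05 or
> 0.95 are excluded before any downstream stage; the boundaries themselves
are retained because the exclusion rule is strict, and both thresholds are
configurable. Filtering is applied per species over that species' pooled
individuals; per-species analyses use only the plots where the species was
sampled.

## Hill-number diversity profiles

For frequencies p with Σp = 1 the effective number of variants of order *a*
is ν_a = (Σ pᵢᵃ)^(1/(1−a)). The package reports the profile at a = 0
(richness), a = 2 (reciprocal Simpson concentration, the "effective number")
and a = ∞ (reciprocal of the largest frequency, the number of prevalent
variants); any finite nonnegative order is accepted. Numerical choices:

- a = 1 is evaluated as the entropy limit exp(−Σ p ln p); the general
  formula is switched out within |a−1| < 1e−9 where it is unstable.
- Zero-frequency variants are dropped before evaluation (0ᵃ = 0 convention);
  they do not count toward richness either.
- Input frequencies must sum to 1 within 1e−6; negative entries are errors.

At a dominant locus the two-variant diversity ν_g,2 = 1/(f₁² + f₂²) lies in
[1, 2]. The default small-sample correction multiplies by N/(N−1) — the
literal form of the correction used with this study design. An alternative
`unbiased_simpson` mode computes 1/[(N·Σf² − 1)/(N − 1)], the reciprocal of
the classical unbiased concentration estimator; both are available because
the two readings coincide only asymptotically. ν_g,2 is computed per locus
within each plot (the plot is the unit of the covariation analysis), and
ν_mean,2 is the unweighted arithmetic mean over retained loci. Plot-level
species profiles use all recorded stems; the adult-census criterion
(DBH ≥ 7 cm) applies only to the abundance variable N used in the
N × diversity covariations.

## Outlier scan

The scan reimplements the multinomial-Dirichlet outlier model for dominant
data. With loci i and populations (plots) j:

- ancestral recessive-allele frequencies pᵢ ~ Uniform(0, 1);
- population frequencies q_ij ~ Beta(θ_ij pᵢ, θ_ij (1−pᵢ)) with
  θ_ij = (1−F_ij)/F_ij and logit(F_ij) = αᵢ + βⱼ;
- dominant likelihood: band-absent counts are Binomial(n_ij, φ_ij) with
  φ = q² + F_IS,j·q(1−q); one F_IS per population, uniform prior on
  configurable bounds (default [0, 1] — unusually wide, but retained as the
  conventional setting for this analysis);
- priors α ~ N(0, 1.8²), β ~ N(−1, 1.8²); a reversible-jump move toggles
  each αᵢ between 0 and free with prior odds 10 for the neutral model. The
  birth proposal draws α from its prior, so only the model odds enter the
  acceptance ratio.

Proposal scales for the five random-walk move classes are adapted during 20
pilot runs toward a 25–45% acceptance window and then fixed; a warning is
emitted if any class ends far outside that window. Default chain lengths
are 20×5,000 pilot sweeps, 50,000 burn-in sweeps and 5,000 retained samples
at thinning 10; `ScanConfig.fast()` divides all lengths by 10 and is the
profile used throughout the test suite. The sweep kernel is numba-compiled;
a fast-profile chain over ~100 loci × 14 plots takes a few seconds.

Posterior summaries per locus: the inclusion probability (share of retained
samples with α in the model), the mean of α over included samples, and a
q-value: loci are ranked by inclusion probability and the q-value is the
running mean of (1 − probability) — the expected false-positive proportion
if the ranked list were cut at that locus. Probabilities of exactly 1 are
floored at 1 − 1/S (S retained samples) before q-values so that finite
sampling resolution is never hidden. Verdicts: `diversifying` for α > 0
with probability > 0.95, `balancing` for α < 0 with probability > 0.95,
otherwise `neutral`. This is a reimplementation of the published model, not
of any particular executable; agreement is assessed by truth recovery on
synthetic data, not bit-identity.

## Covariation C

C = Σ_{i<j}(xᵢ−xⱼ)(yᵢ−yⱼ) / Σ_{i<j}|xᵢ−xⱼ||yᵢ−yⱼ| over all plot pairs.
C = 1 iff every pair co-moves in the same direction, −1 iff strictly
opposite; tied pairs contribute zero to both sums; a zero denominator
(either variable constant) makes C undefined, which is signalled as `None`,
never as a number. C is invariant under strictly increasing affine
transforms of either variable and antisymmetric under order reversal.

The one-sided test permutes y across plots (x, y and pair-label permutation
are equivalent under exchangeability; permuting y keeps the bookkeeping
simple). When n! fits within the permutation budget all orderings are
enumerated and the p-value is the plain tail proportion #{C_perm ≥ C}/n!
(the identity permutation guarantees p > 0); otherwise permutations are
sampled from the seeded generator and the add-one convention
(1 + b)/(1 + B) is used. Permuted datasets with undefined C cannot be
ranked and are excluded from both counts; their number is reported.
Default budget: 5,000 permutations.

## Differentiation δ

For plot j with variant frequencies f_j and pooled complement frequencies
f_{−j}, D_j = ½·Σ_v |f_j(v) − f_{−j}(v)| (the d0 half-L1 distance) and
δ = Σ c_j D_j with c_j the relative plot sizes. δ = 0 iff all plots share
one distribution; δ = 1 iff every plot's variants are absent from its
complement. For community data the variant is the species identity of each
tree (the default mode); for genetic data δ is the unweighted mean of
per-locus values, and the permutation test reassigns whole individuals so
multilocus genotypes stay intact. Reassignments preserve the observed plot
sizes exactly. Significance uses the upper-tail p against the two-sided
Bonferroni level 0.05/(2·6) ≈ 0.004 for the study's six hypotheses.

One non-obvious property: merging two plots with *identical* frequency
distributions can increase δ, because each plot's distance is measured
against its complement and the twin no longer dilutes it. Only the boundary
is invariant (homogeneous communities stay at δ = 0); δ should therefore be
compared across datasets only at a fixed plot partition.

## Staged selection

A locus is a candidate if it passes the scan (q-value < 0.05, inclusion
probability > 0.95, α > 0) **and** at least one of its covariation tests
(three diversity orders × {f_vr, ν_g,2}) is significant at the uncorrected
0.05 level. Survivors are ranked by inclusion probability; the top k = 5
are kept — ties at rank k are all kept and m grows accordingly (the
conservative reading; the procedure's source never addresses ties) — and
every kept locus' covariation p-values then face 0.05/m. With fewer than k
survivors, m is the survivor count (logged). The decisions are a pure
function of their inputs.

## Synthetic data generator

The generator emulates the study design: 14 plots of 0.25 ha; per plot a
species richness uniform on 4–9 drawn from a nine-genus pool with the focal
conifer always present; stem counts Dirichlet-multinomial; an adult census
thinned binomially (fraction 0.6 — a typical adult share for these stands).
Genotype sample sizes per plot default to the study's ranges (17–53 for the
focal species; 3–17, 10–11 and 8–13 for the three associates, on 12, 6 and
7 plots). Loci default to 240 per species with island-model background:
ancestral frequencies uniform on (0.1, 0.9), plot frequencies Beta with
concentration (1−F_ST)/F_ST at background F_ST = 0.05, band phenotypes
drawn through the dominance model at F_IS = 0.1. The truth record keeps
both allele- and phenotype-frequency conventions.

Planted structure:

- **outlier loci** receive a linear per-plot allele-frequency gradient
  (default span 0.05–0.95, i.e. per-plot range ≥ 0.6);
- **coupled loci** tie the recessive-allele frequency (and, through the
  monotone dominance map, the band-absence frequency) to the plot's
  effective species number ν_sp,2 by a rank-based monotone map onto
  0.05–0.95, mixed with the locus' own neutral draw by the coupling weight.
  The rank map keeps the planted differentiation from collapsing when plots
  happen to have similar diversity; using the neutral draw as the noise
  component makes coupling 0 degenerate exactly to the background model.
  Planting acts on the allele scale because dominance masking would
  otherwise compress the low end of the allele range (band-absence counts
  ≈ q² carry little information about small q) and leave the planted signal
  invisible to any allele-frequency-based scan.

What the generator does **not** emulate: spatial autocorrelation between
plots, linkage between loci, scoring error and size homoplasy of real AFLP
fragments, within-plot family structure, and locus-specific F_IS. Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated model, not robustness to those real-data
features.

## Problem sizes and test design

The test suite exercises every stage at sizes chosen to make the
statistical claims sharp while keeping a full run desk-scale: oracle
equivalence of C on 1,000 random series and of δ on an exhaustive grid of
tiny configurations; null level control of the permutation test over 1,000
seeded datasets at 499 permutations; scan truth recovery over 20 seeds at
the fast chain profile with 100 neutral + 3 planted loci; and end-to-end
coupling recovery over 2 × 50 pipeline runs with 100 neutral + 5 coupled
loci at a further-shortened chain (10×250 pilot sweeps, 2,000 burn-in,
300 samples at thinning 7) — chain lengths at which the planted effects are
decisively resolved. `scripts/acceptance.py` recomputes the same
quantities at slightly smaller replicate counts.

## Known limitations

- The scan's q-values inherit the calibration of the posterior inclusion
  probabilities; with very few loci the shared background β absorbs part of
  a large planted fraction (>10% outliers noticeably shrinks α estimates).
- Permutation p-values have resolution 1/(B+1); criteria near 0.004 need
  B ≥ 4,999, and the δ test warns when the budget cannot resolve its level.
- C is undefined for constant series and near-degenerate for heavy ties;
  undefined permutations are dropped rather than imputed, which slightly
  reduces the effective permutation count on tied data.
- The multilocus δ averages per-locus values unweighted; loci unscored in a
  whole plot are skipped rather than error out.
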