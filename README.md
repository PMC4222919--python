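# divlink

Linking plot-level **tree species diversity** to the **genetic structure** of
dominant binary markers (AFLP-style band presence/absence data), for
community-genetics studies built on a network of census plots — the motivating
design is the 14-plot Chihuahua spruce (*Picea chihuahuana*) gallery-forest
community, where four dominant tree species were genotyped at a few hundred
AFLP loci each.

The package answers the question: *is the species diversity of a plot related
to the adaptive genetic structure of the species growing in it?* It does so
with five building blocks:

1. **Hill-number diversity profiles.** For a frequency distribution
   *p₁ … p_k*, the effective number of variants of order *a* is
   ν_a = (Σᵢ pᵢᵃ)^(1/(1−a)), with ν₀ = richness, ν₂ = reciprocal Simpson
   concentration and ν_∞ = 1/max pᵢ. Applied to plot species abundances
   (ν_sp,a) and to the two phenotypic variants of each dominant locus
   (ν_g,2, bias-corrected by N/(N−1); averaged over loci into ν_mean,2).
2. **A Bayesian outlier scan** for loci under differential selection:
   logit(F_ST,ij) = αᵢ + βⱼ with a reversible-jump MCMC toggling each
   locus-specific αᵢ in and out of the model (prior odds 10 for neutrality),
   an explicit dominant-marker likelihood q² + F_IS·q(1−q) for band absence,
   posterior inclusion probabilities and q-values.
3. **The covariation statistic**
   C = Σ_{i<j}(xᵢ−xⱼ)(yᵢ−yⱼ) / Σ_{i<j}|xᵢ−xⱼ||yᵢ−yⱼ| ∈ [−1, 1], sensitive to
   monotone (not necessarily linear) co-movement of two plot-level variables,
   with one-sided permutation tests (exact enumeration for few plots).
4. **The differentiation parameter** δ = Σⱼ cⱼ·Dⱼ, where Dⱼ is the half-L1
   distance between plot j's variant frequencies and the pooled complement of
   all other plots, tested by random reassignment of individuals to plots.
5. **The staged selection procedure**: outlier loci (FDR < 0.05, posterior
   probability > 0.95, α > 0) with at least one nominally significant
   covariation are ranked by posterior probability; the top five face a
   Bonferroni-corrected level 0.05/5 = 0.01 (the δ test uses the two-sided
   0.05/(2·6) ≈ 0.004 criterion).

A seeded synthetic-data generator reproduces the study's statistical
structure — 14 plots, 4–9 tree species per plot, realistic genotype sample
sizes, island-model background differentiation with a small minority of
planted outlier or diversity-coupled loci — so every stage is testable with
known truth and no external downloads.

## Worked example

```python
from divlink import (SimDesign, simulate_dataset, locus_frequencies,
                     filter_loci, ScanConfig, scan, perm_test_C)

# a 14-plot community; 103 loci, three planted diversifying loci
design = SimDesign(seed=7, n_loci=103,
                   outlier_loci=((10, 0.05, 0.95), (50, 0.05, 0.95),
                                 (90, 0.05, 0.95)))
bundle = simulate_dataset(design)
markers = bundle["markers"]["Picea"]

retained, excluded = filter_loci(locus_frequencies(markers))
results, diagnostics = scan(markers, ScanConfig.fast(seed=1), retained=retained)
print(results.loc[["L011", "L051", "L091"]])
```

```
             alpha  post_prob    fdr       verdict
locus_id
L011      1.625907      0.992  0.004  diversifying
L051      2.117952      1.000  0.002  diversifying
L091      2.153863      1.000  0.002  diversifying
```

All three planted loci are recovered with posterior probabilities above 0.99,
positive locus effects α (more differentiated than the genome-wide
background) and q-values (`fdr`) well under 0.05; none of the 89 retained
neutral loci is called. A covariation test between two plot-level series
works the same way:

```python
res = perm_test_C([1, 2, 3, 4, 5], [2, 4, 5, 7, 9], n_perm=5000, seed=0)
print(res.C, res.p_value, res.exact)   # 1.0 0.00833 True
```

With five plots all 120 orderings are enumerated (`exact=True`); the p-value
is the exact tail proportion P(Z ≥ C).

The full pipeline — filter → diversity tables → scan → covariation →
selection ledger → δ test — runs from the command line:

```bash
divlink run-all --seed 11 --fast --out-dir reports/
```

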