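# lrkin — log-ratio PCA for genetic relatedness from IBS sharing

`lrkin` detects and classifies cryptic relatedness between individuals in a
genotyped cohort using only identity-by-state (IBS) information, treated as
compositional data. It is aimed at statistical geneticists doing cohort
quality control (duplicate detection, pedigree verification, unrelated-subset
selection for association studies) in homogeneous populations.

## The idea

For a pair of diploid individuals typed at *k* bi-allelic variants, every
variant falls into one of six unordered genotype-pair categories

```
k00 (AA,AA)  k10 (AA,AB)  k20 (AA,BB)  k11 (AB,AB)  k21 (AB,BB)  k22 (BB,BB)
```

Classical relatedness plots collapse this six-part count vector to two
summary statistics — the mean and SD of IBS sharing (*m, s*), the IBS-class
fractions (*p*₀, *p*₂), or estimated Cotterman coefficients (k̂₀, k̂₁) — and
discard the rest. `lrkin` instead closes the counts to a composition
**x** = (k₀₀, k₁₀, k₂₀, k₁₁, k₂₁, k₂₂)/k, applies the centered log-ratio
transform clr(**x**)ᵢ = ln(xᵢ/gm(**x**)), and performs PCA on the
double-centered clr matrix via the SVD

```
X_cclr = U D V' = F_p G_s'
```

yielding a biplot with up to five informative dimensions. Because the
relationship of an empirical pair is unknown, a *reference set* of pairs
with known relationships (MZ, PO, FS, three-quarter siblings, HS/GG/AV,
first cousins, … , second cousins once removed, unrelated) is generated by
Mendelian gene dropping — either from HWE founders at stated allele
frequencies or by resampling an observed unrelated subset — and the
empirical pairs are projected onto the reference biplot by regression
(F̃_p = Y_cclr G_s). Linear discriminant analysis on the leading principal
components then assigns each pair a relationship with posterior
probabilities. MZ and PO pairs, which carry structural zeros
(k₁₀ = k₂₀ = k₂₁ = 0 for MZ, k₂₀ = 0 for PO), are removed beforehand by the
filter k₂₀/k < 0.005. The procedure can be applied iteratively
(*peel and zoom*): remove the pairs classified into the closest cluster,
refit without that relationship, and resolve remoter relatedness at higher
magnification.

The package also provides the classical machinery for comparison: (*m, s*)
and (*p*₀, *p*₂) summaries, method-of-moments Cotterman estimates, KING
kinship, co-ancestry θ = k₁/2 + k₂ and kinship ϕ = θ/2, greedy
unrelated-subset selection (co-ancestry < 0.05), and variant filters
(missingness, MAF, Hardy–Weinberg exact mid p-value).

## Worked example

```sh
python examples/ibd_estimates.py
```

```
     rel     k0     k1     k2  phi_mom phi_king  phi_exp
      PO  0.000  0.997  0.003    0.251    0.250    0.250
      FS  0.251  0.500  0.249    0.250    0.250    0.250
 3/4S-FS  0.370  0.505  0.125    0.189    0.189    0.188
      HS  0.497  0.498  0.004    0.127    0.127    0.125
      FC  0.746  0.250  0.004    0.064    0.064    0.062
      UN  0.982  0.014  0.004    0.005   -0.002    0.000
```

Each row averages 20 gene-dropped pairs of the given relationship (10,000
SNPs, MAF 0.5): the moment estimator recovers the theoretical IBD-sharing
probabilities (k₀, k₁, k₂), and both kinship routes land on the expected ϕ —
including 3/16 for three-quarter siblings, the value between full (1/4) and
half (1/8) siblings that makes that relationship easy to misread.

`examples/classify_simulated.py` runs a held-out classification study of
third-degree to unrelated pairs; `examples/explore_relatedness.py` screens a
small cohort for MZ/PO structural zeros and shows the first principal
component acting as a relatedness index; `examples/peel_and_zoom_demo.py`
and `examples/method_comparison.py` demonstrate the iterative procedure and
the comparison against the classical plots. A thin command line (`lrkin
filter|compose|simulate-ref|fit|project|classify|peel|compare-methods|fixtures`)
wraps the same functions for shell pipelines.

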