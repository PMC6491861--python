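# Methods

## Genotype-pair compositions

All computations start from the six unordered genotype-pair counts
(k₀₀, k₁₀, k₂₀, k₁₁, k₂₁, k₂₂) of a pair of individuals over k bi-allelic
variants, dosage-coded as the count of the B allele. Variants missing in
either member of a pair are excluded pairwise, so each pair has its own
total k; this extends the complete-variants-only convention to partially
missing data without discarding variants globally. The classical IBS
summaries are derived quantities: p₀ = k₂₀/k, p₁ = (k₁₀+k₂₁)/k,
p₂ = (k₀₀+k₁₁+k₂₂)/k, and m and s are the mean and *population*
(divide-by-k) standard deviation of the per-variant IBS count. The
population form is required for the exact identities m = 1 − p₀ + p₂ and
s² = p₀(1−p₀) + p₂(1−p₂) + 2p₀p₂, which the tests assert for every pair.

## Zero handling and closure

The log-ratio transform requires strictly positive parts. Zero counts are
handled before closure by one of three policies: `replace0.5` (default)
and `replace1` substitute the count, suitable when zeros are few;
`multiplicative` performs ratio-preserving multiplicative replacement with
δ = 0.5/k on the closed scale, preferable when zeros are plentiful. MZ and
PO pairs have *structural* zeros and should not be pushed through the
transform at all: they are removed first by the k₂₀/k < 0.005 screen (pairs
also satisfying (k₁₀+k₂₁)/k < 0.005 are typed MZ, the rest PO). The 0.005
cut is far below the ≈0.125 opposite-homozygote fraction of unrelated pairs
at MAF 0.5, so the screen is essentially noiseless at study scale.

## Log-ratio PCA

Rows of the composition matrix are clr-transformed (equivalently: logs,
then row-centering), the matrix is column-centered, and the SVD
X_cclr = U D V′ taken. Biplot coordinates are the *form* pairing
F_p = U D (principal coordinates of pairs) and G_s = V (standard
coordinates of the six categories); the orthonormality of G_s makes the
regression projection of supplementary compositions,
F̃_p = Y_cclr G_s (G_s′G_s)⁻¹ = Y_cclr G_s, an exact self-projection on
training rows. Numerical choices: natural logarithms; components with
singular value below 1e−10 × the largest are dropped (the clr constraint
guarantees one null dimension, so six parts give rank ≤ 5); the SVD sign
ambiguity is fixed by making each loading column's largest-magnitude entry
positive; a matrix of identical compositions yields a rank-0 fit with a
warning rather than an error. Display scaling of loading arrows in the
biplot is cosmetic and configurable; coordinates themselves are never
rescaled.

## Gene-drop simulator

Founders carry two haplotypes per variant. In HWE mode each allele is an
independent Bernoulli(MAF) draw, which is equivalent to multinomial
genotype sampling at (q², 2pq, p²); in resampling mode founders are rows
drawn without replacement (per pedigree) from an observed unrelated subset,
with heterozygote phase randomized — phase is irrelevant because variants
are transmitted independently. Each non-founder receives one uniformly
chosen allele from each parent, independently per variant; there is no
mutation, genotyping error, linkage or recombination model. Consequently
MZ and PO structural zeros are exact and the simulator emulates an
LD-pruned panel of independent markers, not raw genome-wide data: passing
tests say nothing about performance under residual LD, genotyping error or
population substructure, which real cohorts have. Every founder haplotype
carries a unique integer tag propagated alongside the alleles, so the IBD
state of the target pair at a variant is the count of shared tags —
realized (f₀, f₁, f₂) fractions are exact bookkeeping, not estimates.
Pedigrees for MZ, PO, FS, HS, GG, AV, FC, first cousins once removed,
second cousins, second cousins once removed and UN are built in; both
three-quarter-sibling variants (unshared parents FS, or PO) are provided
and realize kinship 3/16. Founders may be reused across pairs (never
within a pedigree); a single master seed spawns per-pair substreams, so a
reference set is reproducible as a whole.

## IBD estimators

The method-of-moments Cotterman estimator equates observed IBS-class
counts to their HWE expectations (P(IBS0|IBD0) = 2p²q², etc.), solving
sequentially for k̂₀, k̂₁ and taking k̂₂ by complement; negative values are
truncated to zero and the triple renormalized. The finite-sample
correction used by some implementations is omitted because allele
frequencies are known exactly in simulation; monomorphic variants are
excluded. Truncation biases boundary relationships (UN, PO) inward by
roughly one standard error — visible at small SNP counts, negligible at
35,000. KING kinship uses the homogeneous-population form
ϕ̂ = (k₁₁ − 2k₂₀)/(N_het(i) + N_het(j)); the robust between-family variant
is out of scope. Co-ancestry is θ = k₁/2 + k₂, kinship ϕ = θ/2, and the
unrelated subset is chosen greedily: repeatedly delete the individual in
the most pairs with θ > 0.05 (ties to the lower index) until none remain.

## Classification and experiments

LDA uses a pooled within-class covariance and equal priors (the balanced
100-per-class design); the pooled covariance is checked for positive
definiteness and a singular one raises with a hint to use fewer
components. Classes are ordered by degree of relationship so exact
posterior ties resolve toward the more related class — the conservative
choice for QC, where a missed relative costs more than a false flag.
Classification rates are computed on an independently simulated held-out
test set of the same size and settings (resubstitution is available as an
option); three principal components are the default for high-MAF panels
and all five are needed at low MAF. The method comparison feeds identical
train/test pairs to LDA on (m, s), (p₀, p₂), moment-estimated (k̂₀, k̂₁)
and the lr-PCA scores, averaging over replicates (default 25, reducible).
Note that (m, s) and (p₀, p₂) are linked by smooth but non-affine
identities, so their LDA outputs virtually coincide without being bitwise
identical: on a shared split a handful of borderline pairs (≲1 in 100) may
flip between the two feature sets.

Peel-and-zoom regenerates the simulated reference set at every iteration
without the peeled relationships, refits the lr-PCA and reclassifies the
surviving empirical pairs; classical per-pair statistics are invariant
under peeling, whereas the lr-PCA geometry changes — which is precisely
what lets later rounds magnify remoter structure.

## Variant filters

Default QC keeps complete variants (missingness 0) with MAF strictly above
0.40 and Hardy–Weinberg exact mid p-value strictly above 0.05. The HWE
test uses the Levene–Haldane distribution of the heterozygote count given
the allele counts; the mid p-value adds half the probability of outcomes
exactly as probable as the observed one (equality judged at relative
tolerance 1e−9), and a monomorphic variant — a one-point distribution —
is assigned mid-p 0.5. LD pruning is deliberately external: inputs are
assumed pre-pruned.

## Problem sizes

The packaged experiments run at the study scale that the method targets:
35,000 independent variants, 100 pairs per relationship, held-out
evaluation, three to five replicate seeds (five in the acceptance script).
One replicate of the five-class experiment takes a few seconds, so the
whole reproduction completes in about a minute on one CPU. Unit and
property tests use 500–8,000 variants, which keeps Monte-Carlo standard
errors small enough for 3-SE checks while staying fast.

## Known limitations

Only bi-allelic autosomal variants are supported; no X-chromosome
handling, no multi-allelic sites. The simulator's independence assumption
stands in for LD pruning rather than modelling haplotypes; phased,
recombination-aware simulation would be the natural extension. Only the
three Cotterman coefficients are used (no inbreeding, no nine-coefficient
condensed identity states), and the posterior probabilities from LDA do
not propagate the extra uncertainty of a resampled training set.
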