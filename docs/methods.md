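# Methods

## Data model

A genotype table holds per-sample allele calls at named X-STR loci, with
sex recorded per sample. Validation enforces X-chromosome ploidy — two
calls per locus for females, one for males — and STR nomenclature for
allele labels (integer repeat count, optional partial-repeat suffix such as
`24.1`). Labels are categorical text end to end; numeric ordering uses the
(integer, fractional) key, so microvariants never collapse to floats. A
male call recorded as `15/15` is accepted as the hemizygous `15` (a common
typing-software artifact); `15/16` in a male is an error. Missing calls
(empty cell or `NA`) drop the sample from that locus's counts only.

Frequency vectors are the common currency: a per-locus allele distribution
with its chromosome count N, or a per-linkage-group male haplotype
distribution with the male count. All forensic formulas are agnostic to
which of the two they receive.

## Frequency estimation

Allele frequencies are maximum-likelihood counting per stratum: each typed
female contributes two chromosomes, each typed male one, so a fully typed
locus in 265 females and 248 males rests on N = 778 chromosomes pooled.
Loci untyped in a stratum are omitted rather than zero-filled.

Haplotypes are counted in males only, by direct counting: a hemizygous
genotype is an observed, fully phased haplotype. A male enters a group's
count only when typed at every locus of the group (no imputation), and
females are excluded because their gametic phase is unknown. Haplotype
labels join allele labels with `-` in the group's map order; a singleton is
a haplotype seen exactly once.

## Forensic parameters

With s_k = Σ p_i^k over a frequency vector:

* GD/HD = N/(N−1)·(1−s₂) — the bias-corrected probability two random
  chromosomes differ; MP = s₂; PD_m = 1−s₂; PD_f = 1−2s₂²+s₄;
  PIC = 1−s₂−s₂²+s₄.
* Observed heterozygosity Ho is the fraction of heterozygous typed females;
  expected He uses the small-sample correction 2n/(2n−1)·(1−Σp̂²) on
  female-only frequencies (n = typed females), the standard unbiased
  estimator.
* Mean exclusion chances. The autosomal-style trio form (Krüger) is
  Σp(1−p)² − Σ_{i<j}(p_i p_j)²(4−3(p_i+p_j)). For an X trio with a
  daughter, we derived the exact exclusion chance by enumeration over
  mother genotype × paternal allele × maternal segregation × random
  alleged-father allele; it reduces exactly to 1−s₂−s₂²+s₄, i.e. the PIC —
  which is why published tables show the Desmarais column equal to the PIC
  column. The Kishida variant is evaluated through the case decomposition
  (homozygous daughter: s₂−s₃; heterozygous daughter with identified
  paternal allele: 1−3s₂+3s₃−s₄; the mother-equals-daughter double
  heterozygote ambiguity: s₂−s₂²−2s₃+2s₄), which sums to the same exact
  quantity; historical software disagrees with the PIC only in the fourth
  decimal. The duo form is 1−2s₂+s₃. Each closed form is checked in the
  test suite against an independent exhaustive enumeration (grids of all
  frequency vectors with ≤5 alleles at step 0.05, tolerance 1e−10; the
  trio-with-daughter forms at the conventional 5e−4 band).
* Combined powers 1−Π(1−x) are stored as the complement product and
  rendered through decimal arithmetic, so a value like
  0.999999999997106 keeps its full run of nines in text output instead of
  rounding to 1.0 in binary floating point.
* Human-readable tables round at 4 decimals, half away from zero; the JSON
  bundle keeps full precision.

## Exact tests

**Hardy–Weinberg (females).** The test statistic is the conditional
probability of the genotype table given the allele counts,
P(table) ∝ 2^H/∏n_ij! (H = number of heterozygotes). Sampling uses an
allele-swap Markov chain over *ordered* allele arrangements: pick two
individuals, pick one allele of each, swap. That proposal is symmetric on
ordered arrangements and every swap is accepted; the uniform stationary law
over arrangements induces exactly the conditional table distribution, so
the chain targets the same law as the classical count-level switch chain
with Metropolis ratios. The p-value is the post-burn-in fraction of states
whose conditional probability is ≤ the observed table's (probability
ordering, ties extreme, absolute log-tolerance 1e−7 with periodic
re-anchoring of the running log-probability). Default chain length is
1,000,000 with 100,000 burn-in steps. Monomorphic loci return the
degenerate p = 1.

**LD in females.** Two-locus haplotype frequencies are estimated by EM on
unphased genotype pairs (first start at the product of marginals, further
starts random; convergence when the log-likelihood gain drops below 1e−7,
max 1000 iterations — both unstated upstream, fixed here for determinism).
The statistic is 2·(LL_EM − LL_independence). The null permutes the second
locus's whole genotype column across individuals — genotypes, not alleles,
so within-locus genotypic structure is preserved and only gametic
association is tested. Defaults: 10,000 permutations, 2 EM starts.

**LD in males.** Male genotypes are phased haplotypes, so the pair of loci
gives an allele × allele contingency table with fixed margins,
P(table) ∝ 1/∏n_ij!. A Markov chain over tables (random 2×2 submatrix
± swaps, Metropolis acceptance by the factorial ratio) yields the
probability-ordered p-value; the 2×2 case is cross-checked against
Fisher's exact test. Defaults: chain 10,000, burn-in 1,000.

**Sex differentiation.** Per locus, Fst = (H_T − H_S)/H_T with
H = 1 − Σp² and H_S the chromosome-count-weighted mean of the two strata;
the p-value permutes sex labels over pooled chromosomes. A monomorphic
locus defines Fst = 0 with p = 1.

Monte-Carlo p-values are plain proportions (no +1 correction), so p = 0 is
representable; the reported standard error sqrt(p(1−p)/draws) signals the
resolution. All results are bit-reproducible given (config, seed).
Bonferroni control uses α/m with m the number of tests (171 for 19 loci).

## Population comparison

Nei's (1972) standard distance D = −ln I with I = J_AB/√(J_A·J_B), the J's
being arithmetic across-locus means of Σp², Σp_A p_B (Nei's original
aggregation: means before the ratio). Allele spaces are unioned per locus
with absent alleles at 0; identical tables give D = 0, fully disjoint
allele sets give +∞ with a warning.

PCA is column-centered covariance PCA on the concatenated per-allele
frequency vectors (union allele set, 0-filled), with percent variance as
eigenvalue shares. MDS is the classical Torgerson construction
(double-centering, eigendecomposition, negative eigenvalues clipped),
reporting stress-1 so a nonmetric alternative can be compared. Both use a
deterministic sign convention: the largest-magnitude loading of each axis
is positive.

Neighbor joining follows Saitou–Nei with the Q criterion; ties within
1e−12 break to the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest leaf name), making the topology
deterministic. Negative branch lengths are clamped to 0 with a warning
(disable with `clamp_negative=False`). NJ is exact on additive matrices,
property-tested on random trees up to 8 leaves and cross-checked against
scikit-bio's implementation.

## Synthetic data

The generator draws gametes: per linkage group with a declared haplotype
distribution, a full group haplotype at a time; other loci independently
from their allele frequencies. Females are the random union of two gametes
(i.e. HWE at the haplotype level — matching the null models of the tests),
with an optional per-locus inbreeding coefficient F making the second
allele identical by descent with probability F. Males are single gametes.
Multi-population frequency tables follow the Balding–Nichols construction:
Dirichlet draws around the ancestral vector with concentration
p·(1−Fst)/Fst, so Fst = 0 copies the ancestral frequencies.

The study-sized fixture emulates the survey design the pipeline targets:
265 females + 248 males at the 19-locus panel, per-locus allele richness
from 5 (DXS7423) to 26 (DXS10135), interleaved `.1` microvariant labels at
the microvariant-rich loci, and the seven default linkage groups with
within-group LD induced by a mixture haplotype distribution (weight 0.6 on
a drawn core haplotype set, the remainder on a large sample from the
product-of-marginals background). The richness values and group structure
are the study conditions; the LD weight and unimodal frequency shapes are
package choices meant to land diversities and haplotype counts in a
realistic range.

What the generator does *not* emulate: mutation, genotyping dropout and
artifacts, relatedness between samples, and realistic inter-locus
frequency correlations. Passing tests therefore demonstrate correctness of
the estimators and tests under their stated models, not robustness to real
typing error.

## Run sizes

Default chain and permutation sizes are the conventional ones above. The
test suite and `scripts/acceptance.py` run reduced sizes chosen to keep
Monte-Carlo error well inside the asserted tolerances: HWE chains of
3,000–100,000 states (null-calibration suites at 200 replicates), EM
permutation tests at 99–1,000 permutations, male-LD chains of
4,000–300,000 states, and the study-sized acceptance run at HWE 100,000 /
male LD 10,000 / 200 EM permutations with the female EM test restricted to
the 18 within-linkage-group pairs, where the LD signal lives. The
`ld_scope` switch makes that restriction explicit configuration rather
than a hidden default: the full 171-pair battery remains the pipeline
default.

## Known limitations

* The female LD test's permutation null conditions on observed single-locus
  genotypes; it does not test for departures from HWE (the HWE test does).
* Fst uses the allele-frequency (gene-identity) form, not a haplotypic
  AMOVA; with strong within-group LD the two can differ.
* Nei distances on small panels are noisy; the NJ tree inherits that noise
  and near-zero branches may clamp to 0.
* The EM likelihood surface can be multimodal for pathological inputs;
  multiple starts mitigate but do not eliminate the risk of a local
  optimum.
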