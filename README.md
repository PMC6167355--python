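# xstrkit

Forensic and population-genetic analysis of X-chromosomal STR panels.

X-STRs are short-tandem-repeat loci on the X chromosome: diploid in
females, hemizygous in males. That inheritance pattern makes them the
marker of choice for deficiency kinship cases (e.g. a missing alleged
father replaced by a paternal grandmother, or father–daughter duos), but it
also means every statistic has to be sex-aware: males contribute one
chromosome per locus and their genotypes are directly phased haplotypes,
females contribute two and their two-locus phase is latent. `xstrkit`
implements the full workflow of a population survey on such a panel —
built around the 19-locus panel grouped into seven linkage groups
(LG1 DXS10148–DXS10135–DXS8378, …, LG7 DXS10134–DXS7423), but generic over
loci and groups:

* **Frequencies** — allele frequencies per stratum (female / male / pooled;
  a fully typed locus in *n*f females and *n*m males has N = 2·*n*f + *n*m
  chromosomes) and male linkage-group haplotype frequencies by direct
  counting.
* **Forensic parameters** — with p the allele or haplotype frequencies and
  s*k* = Σ p^k:

  | quantity | formula |
  |---|---|
  | gene / haplotype diversity | GD = N/(N−1) · (1 − s₂) |
  | match probability | MP = s₂ |
  | power of discrimination | PD_m = 1 − s₂, PD_f = 1 − 2s₂² + s₄ |
  | polymorphism information content | PIC = 1 − s₂ − s₂² + s₄ |
  | MEC Krüger (autosomal-style trio) | Σpᵢ(1−pᵢ)² − Σᵢ<ⱼ(pᵢpⱼ)²(4−3(pᵢ+pⱼ)) |
  | MEC Kishida / Desmarais (X trio, daughter) | exact trio exclusion = PIC |
  | MEC Desmarais duo | 1 − 2s₂ + s₃ |

  plus combined powers 1 − Π(1−x) held in extended precision so the long
  runs of nines survive into the report. Every exclusion-chance closed form
  is guarded by an exhaustive enumeration oracle in the test suite.
* **Exact tests** — Hardy–Weinberg in females via a Guo–Thompson-style
  Markov chain over genotype tables with fixed allele margins; pairwise LD
  in females (EM haplotype frequencies + permutation likelihood-ratio test)
  and in males (Markov-chain exact test on the haplotype contingency
  table); per-locus male/female differentiation Fst with permutation
  p-values; Bonferroni control over the C(19,2) = 171 pair family.
* **Population comparison** — Nei (1972) standard genetic distance,
  covariance PCA on per-allele frequency vectors, classical (Torgerson)
  MDS, and a neighbor-joining tree with deterministic tie-breaking.
* **Synthetic data** — a generator for hemizygous-male / diploid-female
  genotype tables with microvariant allele labels ("24.1"), optional
  inbreeding-F departure from HWE, within-group haplotype LD, and
  Balding–Nichols multi-population divergence, so the whole pipeline is
  testable without any genotype download.

## Worked example

```python
from xstrkit import (allele_frequencies, combined_power, diversity,
                     match_probability, pic, power_sums)
from xstrkit.core import DEFAULT_LINKAGE_GROUPS
from xstrkit.frequencies import haplotype_frequencies, singleton_fraction
from xstrkit.simulate import gelao_like_fixture

g = gelao_like_fixture(1)               # 265 females + 248 males, 19 loci
pooled = allele_frequencies(g, "pooled")
lf = pooled["DXS10135"]
ps = power_sums(lf.freqs)
print(len(lf.alleles), lf.n, round(diversity(ps, lf.n), 4),
      round(pic(ps), 4), round(match_probability(ps), 4))
# 20 778 0.9175 0.9102 0.0837

haps = haplotype_frequencies(g, DEFAULT_LINKAGE_GROUPS)
gh = haps["LG1"]
print(gh.n_distinct, gh.n_singletons, round(singleton_fraction(haps, "LG1"), 4))
# 118 80 0.678
```

The most informative locus of the simulated panel carries 20 observed
alleles on 778 chromosomes, giving gene diversity 0.9175 and PIC 0.9102;
LG1 yields 118 distinct male haplotypes of which 80 are singletons.
Combining per-group discrimination powers:

```python
cp = combined_power([1 - mp for mp in
                     (0.0070, 0.0271, 0.0078, 0.0326, 0.0565, 0.0153, 0.0694)])
print(cp.text(15))   # 0.999999999997106
```

The CLI mirrors the pipeline stages
(`xstrkit simulate | freqs | haplotypes | forensic | hwe | ld | compare |
report`); `xstrkit report --seed 1 --out out/ genotypes.csv` writes the
per-locus and per-group parameter tables, the HWE/LD/Fst battery with
Bonferroni flags, the combined-power block, and a machine-readable
`results.json`, byte-identical under a fixed seed.

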