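"""Independent brute-force oracles used by the test suite.

Each oracle enumerates genotype configurations directly from the model
definition and never calls the closed forms it is used to check.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np


def _paternal_candidates(child: tuple[int, int], mother: tuple[int, int]) -> set[int]:
    """Alleles that could be the child's paternal allele given the mother."""
    x, y = child
    poss = set()
    if x == y:
        if x in mother:
            poss.add(x)
    else:
        if y in mother:
            poss.add(x)
        if x in mother:
            poss.add(y)
    return poss


def trio_exclusion_autosomal(p) -> float:
    """Trio exclusion chance with a diploid alleged father (HWE everywhere):
    enumerate mother genotype x paternal allele x maternal segregation, and
    exclude an alleged father whose two random alleles both miss the
    paternal-candidate set."""
    k = len(p)
    tot = 0.0
    for a, b, f in product(range(k), repeat=3):
        w = p[a] * p[b] * p[f]
        for m in (a, b):
            miss = 1.0 - sum(p[c] for c in _paternal_candidates((m, f), (a, b)))
            tot += 0.5 * w * miss**2
    return tot


def trio_exclusion_x_daughter(p) -> float:
    """X trio with a daughter: the alleged father contributes one allele."""
    k = len(p)
    tot = 0.0
    for a, b, f in product(range(k), repeat=3):
        w = p[a] * p[b] * p[f]
        for m in (a, b):
            miss = 1.0 - sum(p[c] for c in _paternal_candidates((m, f), (a, b)))
            tot += 0.5 * w * miss
    return tot


def duo_exclusion(p) -> float:
    """Father/daughter duo: exclude a random male allele absent from the
    daughter's genotype."""
    k = len(p)
    tot = 0.0
    for m, f in product(range(k), repeat=2):
        tot += p[m] * p[f] * (1.0 - sum(p[c] for c in {m, f}))
    return tot


def discrimination_female(p) -> float:
    """Probability two random HWE diploid genotypes differ (ordered pairs)."""
    k = len(p)
    tot = 0.0
    for a, b, c, d in product(range(k), repeat=4):
        g1 = tuple(sorted((a, b)))
        g2 = tuple(sorted((c, d)))
        if g1 != g2:
            tot += p[a] * p[b] * p[c] * p[d]
    return tot


def pic_definition(p) -> float:
    """PIC from its definition: 1 - sum p_i^2 - sum_{i != j} p_i^2 p_j^2."""
    k = len(p)
    s2 = sum(x * x for x in p)
    cross = sum(p[i] ** 2 * p[j] ** 2 for i in range(k) for j in range(k) if i != j)
    return 1.0 - s2 - cross


def hwe_exact_biallelic(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Full enumeration of biallelic genotype tables with the observed allele
    margins; probability-ordered exact p-value."""
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab

    def logp(h: int) -> float:
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return h * math.log(2) - math.lgamma(aa + 1) - math.lgamma(h + 1) - math.lgamma(bb + 1)

    hs = list(range(n_a % 2, min(n_a, n_b) + 1, 2))
    lps = {h: logp(h) for h in hs}
    mx = max(lps.values())
    z = sum(math.exp(v - mx) for v in lps.values())
    obs = lps[n_ab]
    return sum(math.exp(v - mx) for v in lps.values() if v <= obs + 1e-9) / z


def frequency_grid(max_alleles: int, step: float = 0.05):
    """All frequency vectors with 2..max_alleles strictly positive entries on
    a grid of the given step (compositions of 1/step)."""
    m = round(1.0 / step)

    def comps(total: int, parts: int):
        if parts == 1:
            if total >= 1:
                yield (total,)
            return
        for first in range(1, total - parts + 2):
            for rest in comps(total - first, parts - 1):
                yield (first,) + rest

    for k in range(2, max_alleles + 1):
        for c in comps(m, k):
            yield np.array(c, dtype=float) * step


def weir_fst_from_freqs(tables_freqs: list[dict]) -> float:
    """Population-level Fst estimate from per-population frequency vectors
    (no sampling correction): ratio of mean allele-frequency variance to
    mean p(1-p), pooled over loci and alleles."""
    num = 0.0
    den = 0.0
    loci = tables_freqs[0].keys()
    for locus in loci:
        alleles = sorted({a for t in tables_freqs for a in t[locus]})
        mat = np.array([[t[locus].get(a, 0.0) for a in alleles] for t in tables_freqs])
        pbar = mat.mean(axis=0)
        num += float(np.sum(mat.var(axis=0)))
        den += float(np.sum(pbar * (1 - pbar)))
    return num / den
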