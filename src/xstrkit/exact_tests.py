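"""Exact and permutation tests: Hardy-Weinberg, linkage disequilibrium, and
male/female differentiation.

* HWE in females uses a Guo-Thompson-style Markov chain over genotype
  tables with fixed allele margins.  The chain swaps one allele between two
  random individuals; over *ordered* allele arrangements this walk is
  symmetric and its uniform stationary law induces exactly the conditional
  table probability  P(table) ~ 2^H N! / prod n_ij!  (H = heterozygote
  count), so every swap is accepted.  The p-value is the fraction of
  post-burn-in states whose conditional probability does not exceed the
  observed table's (probability ordering; ties count as extreme).

* LD between loci is tested two ways, as the sexes demand: in females by a
  likelihood-ratio statistic from EM-estimated two-locus haplotype
  frequencies, with a permutation null that shuffles one locus's genotype
  column across individuals; in males, whose hemizygous genotypes are phased
  haplotypes, by a Markov-chain exact test on the allele x allele
  contingency table with fixed margins.

* Gender differentiation per locus uses allele-frequency Fst
  (H_T - H_S)/H_T with a sex-label permutation p-value.

Monte-Carlo p-values are plain proportions (no +1 correction), so p = 0.0
is representable; the standard-error field signals the resolution.
All results are bit-reproducible given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "McmcConfig", "PermConfig", "TestResult",
    "hwe_exact_test", "ld_em_permutation_test", "ld_exact_test_haploid",
    "bonferroni_threshold", "fst_gender", "em_haplotype_frequencies",
]

_LOG2 = math.log(2.0)
_TIE_TOL = 1e-7  # absolute tolerance when comparing log table probabilities


@dataclass(frozen=True)
class McmcConfig:
    """Markov-chain settings: total post-burn-in length and burn-in steps."""

    chain_length: int = 1_000_000
    dememorization: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chain_length > self.dememorization >= 0:
            raise ValueError("need chain_length > dememorization >= 0")


@dataclass(frozen=True)
class PermConfig:
    """Permutation-test settings for the EM-based female LD test."""

    permutations: int = 10_000
    em_initial_conditions: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.permutations < 1 or self.em_initial_conditions < 1:
            raise ValueError("permutations and em_initial_conditions must be >= 1")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    se: float        # Monte-Carlo standard error sqrt(p(1-p)/draws)
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} out of [0,1]")


def _mc_result(stat: float, hits: int, draws: int, method: str) -> TestResult:
    p = hits / draws
    return TestResult(stat, p, math.sqrt(p * (1.0 - p) / draws), method)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Guo-Thompson chain)

def _table_logprob(cells: dict, n_het: int) -> float:
    return n_het * _LOG2 - sum(math.lgamma(c + 1) for c in cells.values())


def hwe_exact_test(genotype_counts: dict, cfg: McmcConfig) -> TestResult:
    """HWE exact test from female genotype counts at one locus.

    ``genotype_counts`` maps unordered genotypes (allele-label pairs) to
    counts.  Returns the observed table's conditional log-probability as the
    statistic.  A monomorphic locus returns the degenerate p = 1.
    """
    labels = sorted({a for g in genotype_counts for a in g})
    if len(labels) < 2 or sum(genotype_counts.values()) == 0:
        return TestResult(0.0, 1.0, 0.0, "monomorphic")
    idx = {a: i for i, a in enumerate(labels)}

    genos: list[list[int]] = []
    for (a, b), c in genotype_counts.items():
        i, j = sorted((idx[a], idx[b]))
        genos.extend([i, j] for _ in range(c))
    n = len(genos)

    cells: dict[tuple[int, int], int] = {}
    n_het = 0
    for i, j in genos:
        cells[(i, j)] = cells.get((i, j), 0) + 1
        n_het += i != j
    logp_obs = _table_logprob(cells, n_het)
    logp = logp_obs

    rng = np.random.default_rng(cfg.seed)
    total = cfg.dememorization + cfg.chain_length
    # pre-draw randomness in blocks for speed
    hits = 0
    block = 100_000
    done = 0
    while done < total:
        m = min(block, total - done)
        ii = rng.integers(0, n, size=m)
        jj = rng.integers(0, n - 1, size=m)
        pick = rng.integers(0, 4, size=m)   # which allele of each genotype swaps
        for t in range(m):
            i1 = int(ii[t])
            j1 = int(jj[t])
            if j1 >= i1:
                j1 += 1
            g1, g2 = genos[i1], genos[j1]
            pk = pick[t]
            u, ku = (g1[0], 0) if pk & 1 else (g1[1], 1)
            v, kv = (g2[0], 0) if pk & 2 else (g2[1], 1)
            if u == v:
                pass  # identical alleles: the swap is a no-op, state repeats
            else:
                o1 = g1[1 - ku]
                o2 = g2[1 - kv]
                c1 = (g1[0], g1[1])
                c2 = (g2[0], g2[1])
                c1n = (o1, v) if o1 <= v else (v, o1)
                c2n = (o2, u) if o2 <= u else (u, o2)
                delta: dict[tuple[int, int], int] = {}
                for c in (c1, c2):
                    delta[c] = delta.get(c, 0) - 1
                for c in (c1n, c2n):
                    delta[c] = delta.get(c, 0) + 1
                logr = _LOG2 * ((c1n[0] != c1n[1]) + (c2n[0] != c2n[1])
                                - (c1[0] != c1[1]) - (c2[0] != c2[1]))
                for c, d in delta.items():
                    if d == 0:
                        continue
                    nc = cells.get(c, 0)
                    logr += math.lgamma(nc + 1) - math.lgamma(nc + d + 1)
                    nc += d
                    if nc:
                        cells[c] = nc
                    else:
                        cells.pop(c, None)
                genos[i1] = [c1n[0], c1n[1]]
                genos[j1] = [c2n[0], c2n[1]]
                logp += logr
            if done + t >= cfg.dememorization and logp <= logp_obs + _TIE_TOL:
                hits += 1
        done += m
        # re-anchor the running log-probability against float drift
        het = sum(c for (a, b), c in cells.items() if a != b)
        logp = _table_logprob(cells, het)
    return _mc_result(logp_obs, hits, cfg.chain_length, "guo-thompson")


# ---------------------------------------------------------------------------
# Female LD: EM haplotype frequencies + permutation LR test

def em_haplotype_frequencies(a1, a2, b1, b2, ka: int, kb: int,
                             rng: np.random.Generator,
                             n_starts: int = 2, tol: float = 1e-7,
                             max_iter: int = 1000) -> tuple[np.ndarray, float]:
    """Two-locus haplotype frequencies from unphased diploid genotypes by EM.

    ``a1, a2`` / ``b1, b2`` are integer-coded allele pairs per individual.
    The first start is the product of marginal allele frequencies; further
    starts are random.  Returns (haplotype matrix ka x kb, log-likelihood up
    to a phase-independent constant).
    """
    n = len(a1)
    pa = np.bincount(np.concatenate([a1, a2]), minlength=ka) / (2 * n)
    pb = np.bincount(np.concatenate([b1, b2]), minlength=kb) / (2 * n)
    best_h, best_ll = None, -np.inf
    for start in range(n_starts):
        if start == 0:
            h = np.outer(pa, pb)
        else:
            h = rng.dirichlet(np.ones(ka * kb)).reshape(ka, kb)
        ll_prev = -np.inf
        for _ in range(max_iter):
            w1 = h[a1, b1] * h[a2, b2]
            w2 = h[a1, b2] * h[a2, b1]
            s = w1 + w2
            s = np.where(s <= 0, 1e-300, s)
            ll = float(np.sum(np.log(s)))
            r1 = w1 / s
            r2 = 1.0 - r1
            counts = np.zeros((ka, kb))
            np.add.at(counts, (a1, b1), r1)
            np.add.at(counts, (a2, b2), r1)
            np.add.at(counts, (a1, b2), r2)
            np.add.at(counts, (a2, b1), r2)
            h = counts / (2 * n)
            if ll - ll_prev < tol:
                break
            ll_prev = ll
        if ll > best_ll:
            best_ll, best_h = ll, h
    return best_h, best_ll


def _ll_under(h, a1, a2, b1, b2) -> float:
    s = h[a1, b1] * h[a2, b2] + h[a1, b2] * h[a2, b1]
    s = np.where(s <= 0, 1e-300, s)
    return float(np.sum(np.log(s)))


def ld_em_permutation_test(pairs, cfg: PermConfig) -> TestResult:
    """LD test between two loci from female two-locus genotypes.

    ``pairs`` is a sequence of ((a1, a2), (b1, b2)) allele-label genotype
    pairs.  Statistic: 2 * (LL of EM haplotype frequencies - LL under the
    product of single-locus allele frequencies).  Null distribution: the
    second locus's genotype column is permuted across individuals.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 individuals")
    la = sorted({a for (ga, _) in pairs for a in ga})
    lb = sorted({b for (_, gb) in pairs for b in gb})
    if len(la) < 2 or len(lb) < 2:
        return TestResult(0.0, 1.0, 0.0, "monomorphic")
    ia = {a: i for i, a in enumerate(la)}
    ib = {b: i for i, b in enumerate(lb)}
    a1 = np.array([ia[ga[0]] for ga, _ in pairs])
    a2 = np.array([ia[ga[1]] for ga, _ in pairs])
    b1 = np.array([ib[gb[0]] for _, gb in pairs])
    b2 = np.array([ib[gb[1]] for _, gb in pairs])
    ka, kb = len(la), len(lb)
    n = len(pairs)

    rng = np.random.default_rng(cfg.seed)
    pa = np.bincount(np.concatenate([a1, a2]), minlength=ka) / (2 * n)
    pb = np.bincount(np.concatenate([b1, b2]), minlength=kb) / (2 * n)
    h0 = np.outer(pa, pb)

    def lr_stat(bb1, bb2) -> float:
        _, ll1 = em_haplotype_frequencies(a1, a2, bb1, bb2, ka, kb, rng,
                                          cfg.em_initial_conditions)
        ll0 = _ll_under(h0, a1, a2, bb1, bb2)
        return 2.0 * (ll1 - ll0)

    obs = lr_stat(b1, b2)
    hits = 0
    for _ in range(cfg.permutations):
        perm = rng.permutation(n)
        if lr_stat(b1[perm], b2[perm]) >= obs - 1e-9:
            hits += 1
    res = _mc_result(obs, hits, cfg.permutations, "em-permutation")
    return res


# ---------------------------------------------------------------------------
# Male LD: exact test on the haplotype contingency table

def ld_exact_test_haploid(table, cfg: McmcConfig) -> TestResult:
    """Exact LD test for hemizygous males: Markov chain over allele x allele
    contingency tables with fixed margins, probability-ordered p-value."""
    t = np.asarray(table, dtype=np.int64)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    r, c = t.shape
    if r < 2 or c < 2:
        return TestResult(0.0, 1.0, 0.0, "degenerate")

    cur = t.copy()
    logp_obs = -float(np.sum([math.lgamma(x + 1) for x in t.ravel()]))
    logp = logp_obs
    rng = np.random.default_rng(cfg.seed)
    total = cfg.dememorization + cfg.chain_length
    hits = 0
    block = 100_000
    done = 0
    while done < total:
        m = min(block, total - done)
        ri = rng.integers(0, r, size=m)
        rk = rng.integers(0, r - 1, size=m)
        cj = rng.integers(0, c, size=m)
        cl = rng.integers(0, c - 1, size=m)
        sgn = rng.integers(0, 2, size=m) * 2 - 1
        acc = rng.random(size=m)
        for s in range(m):
            i = int(ri[s]); k = int(rk[s])
            if k >= i:
                k += 1
            j = int(cj[s]); l = int(cl[s])
            if l >= j:
                l += 1
            d = int(sgn[s])
            nij, nkl, nil, nkj = cur[i, j], cur[k, l], cur[i, l], cur[k, j]
            if (d > 0 and (nil == 0 or nkj == 0)) or (d < 0 and (nij == 0 or nkl == 0)):
                pass  # off-boundary proposal rejected; state repeats
            else:
                if d > 0:
                    logr = (math.log(nil) + math.log(nkj)
                            - math.log(nij + 1) - math.log(nkl + 1))
                else:
                    logr = (math.log(nij) + math.log(nkl)
                            - math.log(nil + 1) - math.log(nkj + 1))
                if acc[s] < math.exp(min(logr, 0.0)):
                    cur[i, j] += d; cur[k, l] += d
                    cur[i, l] -= d; cur[k, j] -= d
                    logp += logr
            if done + s >= cfg.dememorization and logp <= logp_obs + _TIE_TOL:
                hits += 1
        done += m
        logp = -float(np.sum([math.lgamma(x + 1) for x in cur.ravel()]))
    return _mc_result(logp_obs, hits, cfg.chain_length, "haploid-exact")


# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _het(p: np.ndarray) -> float:
    return 1.0 - float(np.sum(p**2))


def fst_gender(male_freqs: dict, female_freqs: dict, n_male: int, n_female: int,
               permutations: int = 10_000, seed: int = 0) -> TestResult:
    """Allele-frequency Fst between male and female strata at one locus.

    Frequencies are given as allele-label -> frequency mappings; counts are
    reconstructed as frequency * chromosome count.  Fst = (H_T - H_S)/H_T
    with H = 1 - sum p^2 and H_S the count-weighted stratum mean.  The
    p-value permutes sex labels over the pooled chromosomes.
    """
    labels = sorted(set(male_freqs) | set(female_freqs))
    cm = np.array([round(male_freqs.get(a, 0.0) * n_male) for a in labels], dtype=np.int64)
    cf = np.array([round(female_freqs.get(a, 0.0) * n_female) for a in labels], dtype=np.int64)
    nm, nf = int(cm.sum()), int(cf.sum())
    pooled = cm + cf
    p_t = pooled / pooled.sum()
    h_t = _het(p_t)
    if h_t == 0.0:
        return TestResult(0.0, 1.0, 0.0, "monomorphic")

    def fst(cm_, cf_) -> float:
        h_m = _het(cm_ / nm)
        h_f = _het(cf_ / nf)
        h_s = (nm * h_m + nf * h_f) / (nm + nf)
        return (h_t - h_s) / h_t

    obs = fst(cm, cf)
    chroms = np.repeat(np.arange(len(labels)), pooled)
    rng = np.random.default_rng(seed)
    hits = 0
    k = len(labels)
    for _ in range(permutations):
        rng.shuffle(chroms)
        cm_ = np.bincount(chroms[:nm], minlength=k)
        cf_ = np.bincount(chroms[nm:], minlength=k)
        if fst(cm_, cf_) >= obs - 1e-12:
            hits += 1
    res = _mc_result(obs, hits, permutations, "fst-permutation")
    return res
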