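"""Exact-test battery: chains vs enumeration oracles, calibration, power."""

import numpy as np
import pytest
import scipy.stats

from _oracles import hwe_exact_biallelic
from xstrkit import (
    McmcConfig,
    PermConfig,
    bonferroni_threshold,
    fst_gender,
    hwe_exact_test,
    ld_em_permutation_test,
    ld_exact_test_haploid,
)
from xstrkit.exact_tests import em_haplotype_frequencies


def _hwe_counts_from_geno(genos):
    counts = {}
    for g in genos:
        k = tuple(sorted(g))
        counts[k] = counts.get(k, 0) + 1
    return counts


class TestHweExact:
    def test_equilibrium_table_not_rejected(self):
        res = hwe_exact_test({("A", "A"): 25, ("A", "B"): 50, ("B", "B"): 25},
                             McmcConfig(50_000, 5_000, 1))
        exact = hwe_exact_biallelic(25, 50, 25)
        assert exact == pytest.approx(1.0)
        assert abs(res.p_value - exact) <= max(3 * res.se, 1e-3)

    def test_all_heterozygote_table_rejected(self):
        res = hwe_exact_test({("A", "B"): 50}, McmcConfig(50_000, 5_000, 1))
        assert hwe_exact_biallelic(0, 50, 0) < 1e-3
        assert res.p_value < 1e-3

    def test_monomorphic_degenerate(self):
        res = hwe_exact_test({("A", "A"): 40}, McmcConfig(1000, 100, 0))
        assert (res.p_value, res.method) == (1.0, "monomorphic")

    @pytest.mark.parametrize("table", [(30, 40, 30), (10, 20, 70), (12, 40, 8)])
    def test_chain_converges_to_enumeration(self, table):
        aa, ab, bb = table
        exact = hwe_exact_biallelic(aa, ab, bb)
        res = hwe_exact_test({("A", "A"): aa, ("A", "B"): ab, ("B", "B"): bb},
                             McmcConfig(100_000, 10_000, 3))
        # autocorrelated draws: allow a few naive standard errors
        assert abs(res.p_value - exact) < max(6 * res.se, 5e-3)

    def test_three_allele_case_against_full_enumeration(self):
        # enumerate all genotype tables with the margins of this 3-allele table
        import itertools, math

        obs = {("A", "A"): 6, ("A", "B"): 10, ("B", "B"): 5,
               ("A", "C"): 4, ("B", "C"): 6, ("C", "C"): 2}
        n = sum(obs.values())
        margins = {}
        for (a, b), c in obs.items():
            margins[a] = margins.get(a, 0) + c
            margins[b] = margins.get(b, 0) + c

        def logprob(t):
            h = sum(c for (a, b), c in t.items() if a != b)
            return h * math.log(2) - sum(math.lgamma(c + 1) for c in t.values())

        # brute-force enumeration over heterozygote cell counts
        tables = []
        na, nb, nc = margins["A"], margins["B"], margins["C"]
        for ab in range(min(na, nb) + 1):
            for ac in range(min(na, nc) + 1):
                for bc in range(min(nb, nc) + 1):
                    aa2, bb2, cc2 = na - ab - ac, nb - ab - bc, nc - ac - bc
                    if aa2 < 0 or bb2 < 0 or cc2 < 0:
                        continue
                    if aa2 % 2 or bb2 % 2 or cc2 % 2:
                        continue
                    t = {("A", "A"): aa2 // 2, ("B", "B"): bb2 // 2,
                         ("C", "C"): cc2 // 2, ("A", "B"): ab,
                         ("A", "C"): ac, ("B", "C"): bc}
                    if sum(t.values()) == n:
                        tables.append(t)
        lps = np.array([logprob(t) for t in tables])
        w = np.exp(lps - lps.max())
        p_exact = float(w[lps <= logprob(obs) + 1e-9].sum() / w.sum())
        res = hwe_exact_test(obs, McmcConfig(100_000, 10_000, 4))
        assert abs(res.p_value - p_exact) < max(6 * res.se, 5e-3)

    def test_reproducible_given_seed(self):
        cfg = McmcConfig(20_000, 2_000, 42)
        t = {("A", "A"): 30, ("A", "B"): 40, ("B", "B"): 30}
        assert hwe_exact_test(t, cfg) == hwe_exact_test(t, cfg)

    def test_power_under_inbreeding(self):
        """Heterozygote deficit (F = 0.3) is detected >= 80% of the time."""
        rng = np.random.default_rng(11)
        rejected = 0
        reps = 100
        for rep in range(reps):
            genos = []
            for _ in range(265):
                a = "A" if rng.random() < 0.5 else "B"
                if rng.random() < 0.3:
                    b = a
                else:
                    b = "A" if rng.random() < 0.5 else "B"
                genos.append((a, b))
            res = hwe_exact_test(_hwe_counts_from_geno(genos),
                                 McmcConfig(3_000, 500, rep))
            rejected += res.p_value <= 0.05
        assert rejected / reps >= 0.80


class TestLdFemaleEm:
    def test_em_equals_direct_counting_when_phase_known(self, rng):
        """All-homozygote input has no latent phase: EM = direct counting."""
        # 60 individuals homozygous at both loci
        a = np.repeat([0, 0, 1], 20)
        b = np.repeat([0, 1, 1], 20)
        h, ll = em_haplotype_frequencies(a, a, b, b, 2, 2, rng, n_starts=2)
        direct = np.zeros((2, 2))
        for x, y in zip(a, b):
            direct[x, y] += 1
        np.testing.assert_allclose(h, direct / direct.sum(), atol=1e-9)

    def test_monomorphic_degenerate(self):
        pairs = [((("15", "15")), ("8", "8"))] * 10
        res = ld_em_permutation_test(pairs, PermConfig(10, 1, 0))
        assert (res.p_value, res.method) == (1.0, "monomorphic")

    def test_perfect_coupling_detected(self):
        pairs = ([(("10", "10"), ("8", "8"))] * 50
                 + [(("11", "11"), ("9", "9"))] * 50)
        res = ld_em_permutation_test(pairs, PermConfig(1000, 2, 1))
        assert res.p_value <= 0.001


class TestLdMaleExact:
    def test_extreme_table_matches_fisher(self):
        t = np.array([[10, 0], [0, 10]])
        _, p_fisher = scipy.stats.fisher_exact(t)
        assert p_fisher == pytest.approx(2 / 184756, rel=1e-6)
        res = ld_exact_test_haploid(t, McmcConfig(300_000, 30_000, 2))
        assert res.p_value < 1e-3  # exact p ~ 1.1e-5; chain resolution-limited

    def test_balanced_table_p_one(self):
        res = ld_exact_test_haploid(np.array([[5, 5], [5, 5]]),
                                    McmcConfig(20_000, 2_000, 2))
        assert res.p_value >= 0.99

    def test_2x2_matches_fisher_oracle(self):
        t = np.array([[5, 1], [4, 8]])
        _, p_fisher = scipy.stats.fisher_exact(t)
        res = ld_exact_test_haploid(t, McmcConfig(200_000, 20_000, 5))
        assert abs(res.p_value - p_fisher) < max(6 * res.se, 0.01)

    def test_zero_margin_degenerate(self):
        res = ld_exact_test_haploid(np.array([[5, 0], [7, 0]]),
                                    McmcConfig(1000, 100, 0))
        assert (res.p_value, res.method) == (1.0, "degenerate")


class TestBonferroni:
    def test_reported_threshold(self):
        from xstrkit.forensic import round_half_up

        assert round_half_up(bonferroni_threshold(0.05, 171)) == 0.0003

    def test_identities(self):
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.05, 19 * 18 // 2) == bonferroni_threshold(0.05, 171)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestFstGender:
    def test_identical_frequencies_zero(self):
        f = {"15": 0.5, "16": 0.5}
        res = fst_gender(f, f, 200, 400, permutations=200, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_is_one(self):
        res = fst_gender({"15": 1.0}, {"16": 1.0}, 100, 100,
                         permutations=100, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_monomorphic(self):
        res = fst_gender({"15": 1.0}, {"15": 1.0}, 100, 100,
                         permutations=10, seed=0)
        assert (res.statistic, res.p_value, res.method) == (0.0, 1.0, "monomorphic")


def test_mc_pvalues_have_standard_errors():
    res = hwe_exact_test({("A", "A"): 10, ("A", "B"): 20, ("B", "B"): 10},
                         McmcConfig(5_000, 500, 7))
    assert res.se == pytest.approx(
        np.sqrt(res.p_value * (1 - res.p_value) / 5_000))
    assert -0.01 <= res.p_value - 3 * res.se <= res.p_value + 3 * res.se <= 1.01
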