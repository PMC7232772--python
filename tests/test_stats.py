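"""Differentiation and diversity statistics against independent oracles.

The oracle implementations below are deliberately written as plain scalar
loops from the textbook variance-component formulas, independent of the
vectorized code paths they check.
"""

import numpy as np
import pytest

from ciscopop import stats as cst
from ciscopop.genotypes import GenotypeMatrix

from conftest import gm_from_counts, random_biallelic


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_theta(pop_calls):
    """Weir-Cockerham theta from per-population lists of genotype tuples.

    ``pop_calls`` is a list (one entry per population) of lists of (a, b)
    allele pairs; missing genotypes are simply absent. Scalar transcription
    of the variance-component formulas, one allele at a time.
    """
    alleles = sorted({a for pop in pop_calls for g in pop for a in g})
    r = len(pop_calls)
    num = den = 0.0
    n_loci_alleles = 0
    for allele in alleles:
        n = [len(pop) for pop in pop_calls]
        p = [sum((g.count(allele)) for g in pop) / (2 * len(pop))
             for pop in pop_calls]
        h = [sum(1 for g in pop if g.count(allele) == 1 and g[0] != g[1]) / len(pop)
             for pop in pop_calls]
        nbar = sum(n) / r
        nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = nbar / nc * (
            s2 - 1 / (nbar - 1) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
            )
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
        n_loci_alleles += 1
    return num / den


def calls_by_pop(gm, locus=0):
    out = []
    for pop in gm.pops():
        idx = gm.pop_indices(pop)
        out.append([
            tuple(gm.calls[i, locus]) for i in idx if gm.calls[i, locus, 0] >= 0
        ])
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

class TestWcFst:
    def test_fixed_difference_is_one(self):
        gm = gm_from_counts([{0: 6}, {2: 6}])
        res = cst.wc_fst(gm)
        assert res.theta == pytest.approx(1.0)

    def test_null_case_near_zero_large_n(self, rng):
        # two copies of one panmictic population, n = 500 per group
        p = rng.uniform(0.1, 0.9, 300)
        dos = rng.binomial(2, p, size=(1000, 300)).astype(float)
        labels = ["a"] * 500 + ["b"] * 500
        gm = GenotypeMatrix.from_dosage(dos, pop_labels=labels)
        assert abs(cst.wc_fst(gm).theta) < 0.01

    def test_two_pop_toy_matches_oracle(self):
        gm = gm_from_counts([{0: 4, 1: 2}, {1: 2, 2: 4}])
        expected = oracle_theta(calls_by_pop(gm))
        assert cst.wc_fst(gm).theta == pytest.approx(expected, abs=1e-10)

    def test_random_fixture_matches_oracle_per_locus(self, rng):
        gm = random_biallelic(rng, n_ind=10, n_loci=6, missing=0.1)
        res = cst.wc_fst(gm)
        for l in range(6):
            pops = calls_by_pop(gm, locus=l)
            if any(len(p) < 2 for p in pops):
                continue
            flat = [a for pop in pops for g in pop for a in g]
            if len(set(flat)) < 2:
                assert np.isnan(res.per_locus[l])
                continue
            assert res.per_locus[l] == pytest.approx(
                oracle_theta(pops), abs=1e-10
            )

    def test_multiallelic_matches_oracle(self, rng):
        # 3-allele locus, two pops, built directly from call pairs
        from ciscopop.genotypes import LocusTable
        import pandas as pd
        calls = np.array([
            [[0, 0]], [[0, 1]], [[1, 2]], [[2, 2]], [[0, 2]],
            [[1, 1]], [[0, 1]], [[2, 2]], [[1, 2]], [[0, 0]],
        ], dtype=np.int16)
        df = pd.DataFrame({"locus_id": ["m1"], "alleles": [["1", "2", "3"]]})
        gm = GenotypeMatrix(
            [f"i{k}" for k in range(10)], ["p1"] * 5 + ["p2"] * 5,
            LocusTable(df), calls,
        )
        expected = oracle_theta(calls_by_pop(gm))
        assert cst.wc_fst(gm).theta == pytest.approx(expected, abs=1e-10)

    def test_invariant_to_orderings(self, rng):
        gm = random_biallelic(rng, n_ind=30, n_loci=50, missing=0.05)
        t0 = cst.wc_fst(gm).theta
        perm_l = rng.permutation(50)
        perm_i = rng.permutation(30)
        t1 = cst.wc_fst(gm.subset(ind_idx=perm_i, locus_idx=perm_l)).theta
        assert t1 == pytest.approx(t0, abs=1e-12)


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

class TestDiversity:
    def test_all_homozygous_group(self):
        gm = gm_from_counts([{0: 3, 2: 3}, {1: 4}])
        div = cst.diversity_summary(gm)
        assert div.loc["pop1", "Ho"] == 0.0
        assert div.loc["pop1", "G_IS"] == pytest.approx(1.0)

    def test_single_heterozygote_unbiased_he(self):
        # one individual, heterozygous: Ho = 1 and the n=1 correction
        # 2n/(2n-1) * 2pq = 2 * 0.5 = 1 makes He = 1 as well
        gm = gm_from_counts([{1: 1}])
        div = cst.diversity_summary(gm)
        assert div.loc["pop1", "Ho"] == 1.0
        assert div.loc["pop1", "He"] == pytest.approx(1.0)

    def test_allele_percentage(self):
        gm = gm_from_counts([{0: 2, 1: 2}, {0: 4}])
        div = cst.diversity_summary(gm)
        assert div.loc["pop1", "A_pct"] == 100.0   # carries both alleles
        assert div.loc["pop2", "A_pct"] == 50.0


# ---------------------------------------------------------------------------
# standardized differentiation
# ---------------------------------------------------------------------------

def oracle_gppst(pop_dosages):
    """Nei-Chesser Hs/Ht and the Meirmans-Hedrick G''ST, scalar route."""
    k = len(pop_dosages)
    ns = [len(d) for d in pop_dosages]
    ntilde = k / sum(1.0 / n for n in ns)
    ps = [sum(d) / (2 * len(d)) for d in pop_dosages]
    ho = [sum(1 for x in d if x == 1) / len(d) for d in pop_dosages]
    ho_m = sum(ho) / k
    sum_p2 = [p * p + (1 - p) * (1 - p) for p in ps]
    hs = ntilde / (ntilde - 1) * (1 - sum(sum_p2) / k - ho_m / (2 * ntilde))
    pbar = sum(ps) / k
    ht = 1 - (pbar**2 + (1 - pbar) ** 2) + hs / (k * ntilde) - ho_m / (2 * k * ntilde)
    return k * (ht - hs) / ((k * ht - hs) * (1 - hs))


class TestStandardizedGst:
    def test_no_differentiation_near_zero(self, rng):
        # two large samples from one panmictic pool: H_S ~ H_T, G''ST ~ 0
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 200),
                           size=(1000, 200)).astype(float)
        gm = GenotypeMatrix.from_dosage(
            dos, pop_labels=["a"] * 500 + ["b"] * 500
        )
        assert abs(cst.standardized_gst(gm)) < 0.02

    def test_fixed_difference_is_one(self):
        gm = gm_from_counts([{0: 8}, {2: 8}])
        assert cst.standardized_gst(gm) == pytest.approx(1.0)

    def test_toy_matches_hand_formula(self):
        # p = 0.9 vs 0.1, n = 50 each, HWE-exact genotype counts
        gm = gm_from_counts([
            {2: 40, 1: 10, 0: 0},       # p_alt = 0.9
            {2: 0, 1: 10, 0: 40},       # p_alt = 0.1
        ])
        pops = [
            [2.0] * 40 + [1.0] * 10,
            [1.0] * 10 + [0.0] * 40,
        ]
        assert cst.standardized_gst(gm) == pytest.approx(
            oracle_gppst(pops), abs=1e-10
        )

    def test_gpp_at_least_gst_style_fst(self, rng):
        gm = random_biallelic(rng, n_ind=40, n_loci=60, n_pops=2, missing=0)
        assert cst.standardized_gst(gm) >= cst.wc_fst(gm).theta - 0.05


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

class TestPermutation:
    def test_fixed_difference_minimum_p(self):
        gm = gm_from_counts([{0: 10}, {2: 10}])
        p = cst.permutation_differentiation_test(
            gm, ("pop1", "pop2"), n_perm=99, seed=1
        )
        assert p == pytest.approx(1.0 / 100.0)

    def test_null_p_is_not_extreme(self, rng):
        # one population split at random: p should look uniform, so very
        # small values are rare
        dos = rng.binomial(2, rng.uniform(0.2, 0.8, 50), size=(30, 50)).astype(float)
        labels = ["a"] * 15 + ["b"] * 15
        gm = GenotypeMatrix.from_dosage(dos, pop_labels=labels)
        ps = [
            cst.permutation_differentiation_test(
                gm, ("a", "b"), n_perm=49, seed=s
            )
            for s in range(8)
        ]
        assert min(ps) > 0.02      # 1/50 would be the floor
        assert np.mean(ps) > 0.2
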