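"""Forward simulator: drift expectations, migration mixing, ancestry tracking."""

import numpy as np
import pytest

from ciscopop import sim as csim
from ciscopop.stats import wc_fst


class TestConfig:
    @pytest.mark.parametrize("kw", [
        dict(m=1.5), dict(deme_size=0), dict(n_allelic_states=1),
        dict(migration_model="ring"),
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            csim.SimConfig(**kw)


class TestBurnin:
    def test_full_mixing_keeps_demes_identical(self):
        cfg = csim.SimConfig(n_demes=2, deme_size=5000, m=0.5, n_loci=300,
                             burnin_generations=40, seed=3)
        freqs, traj = csim.burnin_allele_frequencies(cfg)
        # complete exchange each generation: inter-deme differences stay at
        # sampling noise, FST trajectory hugs zero
        assert np.abs(freqs[0] - freqs[1]).mean() < 0.02
        assert traj.max() < 0.01

    def test_isolated_demes_match_drift_prediction(self):
        # m=0: E[FST(t)] = 1 - (1 - 1/2N)^t for two isolated demes
        N, t = 50, 500
        cfg = csim.SimConfig(n_demes=2, deme_size=N, m=0.0, n_loci=1000,
                             burnin_generations=t, mu=0.0, seed=7)
        freqs, traj = csim.burnin_allele_frequencies(cfg)
        expected = 1.0 - (1.0 - 1.0 / (2 * N)) ** t
        # Monte-Carlo tolerance: per-locus FST is noisy, the 1,000-locus mean
        # should sit within a few points of the prediction
        assert traj[-1] == pytest.approx(expected, abs=0.05)

    def test_deterministic_given_seed(self):
        cfg = csim.SimConfig(n_demes=3, deme_size=100, n_loci=50,
                             burnin_generations=20, seed=11)
        f1, t1 = csim.burnin_allele_frequencies(cfg)
        f2, t2 = csim.burnin_allele_frequencies(cfg)
        np.testing.assert_array_equal(f1, f2)
        np.testing.assert_array_equal(t1, t2)

    def test_multistate_frequency_engine_unsupported(self):
        cfg = csim.SimConfig(n_allelic_states=4)
        with pytest.raises(NotImplementedError):
            csim.burnin_allele_frequencies(cfg)


class TestInstantiate:
    def test_fixed_locus_all_alt(self, rng):
        freqs = np.array([[1.0, 0.0, 0.3]])
        pop = csim.instantiate_individuals(freqs, 200, seed=rng)
        d = pop.calls.sum(axis=2)
        assert (d[:, 0] == 2).all() and (d[:, 1] == 0).all()

    def test_binomial_moments(self, rng):
        freqs = np.full((1, 1), 0.3)
        pop = csim.instantiate_individuals(freqs, 10000, seed=rng)
        mean_d = pop.calls.sum(axis=2).mean()
        se = np.sqrt(2 * 0.3 * 0.7 / 10000)
        assert abs(mean_d - 0.6) < 3 * se

    def test_ancestry_one_hot(self, rng):
        pop = csim.instantiate_individuals(np.full((3, 5), 0.5), 10, seed=rng)
        assert ((pop.ancestry == 0) | (pop.ancestry == 1)).all()
        np.testing.assert_array_equal(pop.ancestry.sum(axis=1), 1.0)
        np.testing.assert_array_equal(pop.ancestry.argmax(axis=1), pop.deme)


class TestHybridization:
    def _pop(self, rng, d=2, N=200, L=50):
        return csim.instantiate_individuals(np.full((d, L), 0.5), N, seed=rng)

    def test_no_migration_keeps_ancestry_pure(self, rng):
        pop = self._pop(rng)
        res = csim.hybridization_phase(pop, "island", 0.0, 3, seed=1,
                                       sample_per_deme=50)
        assert ((res.ancestry == 0) | (res.ancestry == 1)).all()

    def test_f1_fraction_matches_expectation(self, rng):
        # island, 2 demes, migrate-then-mate, one generation at m = 0.5:
        # post-migration each deme holds ~50% immigrants, so the expected
        # mixed-parent (F1) fraction is 2 f (1 - f) ~ 0.5
        pop = self._pop(rng, N=1000)
        res = csim.hybridization_phase(
            pop, "island", 0.5, 1, seed=2, life_cycle="migrate_mate",
        )
        anc = res.ancestry
        f1 = ((anc > 0) & (anc < 1)).any(axis=1).mean()
        # binomial-ish tolerance on 2,000 offspring plus migrant-count noise
        assert f1 == pytest.approx(0.5, abs=0.06)

    def test_mate_then_migrate_delays_mixing_one_generation(self, rng):
        pop = self._pop(rng, N=500)
        res = csim.hybridization_phase(pop, "island", 0.2, 1, seed=3,
                                       life_cycle="mate_migrate")
        # first-generation offspring predate any gene flow
        assert ((res.ancestry == 0) | (res.ancestry == 1)).all()

    def test_ancestry_convex_and_sizes_constant(self, rng):
        pop = self._pop(rng, d=3, N=120)
        res = csim.hybridization_phase(pop, "stepping_stone_1d", 0.1, 4,
                                       seed=4, sample_per_deme=None,
                                       life_cycle="migrate_mate")
        anc = res.ancestry
        np.testing.assert_allclose(anc.sum(axis=1), 1.0, atol=1e-12)
        assert (anc >= 0).all() and (anc <= 1).all()
        gm = res.genotypes
        labels = np.asarray(gm.pop_labels)
        assert {(labels == f"P{k+1}").sum() for k in range(3)} == {120}

    def test_stepping_stone_keeps_distal_pairs_rare(self, rng):
        # in the linear arrangement a P1 x P3 mating needs two migrants to
        # meet in the middle deme (order m^2), so adjacent-pair mixing must
        # dominate distal-pair mixing
        pop = self._pop(rng, d=3, N=500)
        res = csim.hybridization_phase(
            pop, "stepping_stone_1d", 0.1, 1, seed=5,
            life_cycle="migrate_mate",
        )
        anc = res.ancestry
        mixed13 = ((anc[:, 0] > 0) & (anc[:, 2] > 0)).sum()
        mixed12 = ((anc[:, 0] > 0) & (anc[:, 1] > 0)).sum()
        assert mixed13 < mixed12 / 4

    def test_seed_reproducibility(self, rng):
        pop1 = self._pop(np.random.default_rng(9))
        pop2 = self._pop(np.random.default_rng(9))
        r1 = csim.hybridization_phase(pop1, "island", 0.1, 2, seed=42)
        r2 = csim.hybridization_phase(pop2, "island", 0.1, 2, seed=42)
        np.testing.assert_array_equal(r1.genotypes.calls, r2.genotypes.calls)
        np.testing.assert_array_equal(r1.ancestry, r2.ancestry)

    def test_heterozygosity_decay_rate(self):
        # closed deme, no mutation: E[He] decays by (1 - 1/2N) per generation
        N, t = 60, 80
        rng = np.random.default_rng(12)
        pop = csim.instantiate_individuals(np.full((1, 800), 0.5), N, seed=rng)
        res = csim.hybridization_phase(pop, "island", 0.0, t, seed=13,
                                       deme_size=N)
        d = res.genotypes.dosage()
        p = d.mean(axis=0) / 2
        he = 2 * np.mean(p * (1 - p))
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        assert he == pytest.approx(expected, rel=0.15)


class TestErosion:
    def test_monotone_in_migration_and_decline(self):
        common = dict(generations=5, n_replicates=4, n_loci=300,
                      deme_size=300, sample_per_deme=80,
                      burnin_generations=300)
        lo = csim.run_erosion_experiment("a", 0.01, seed=21, **common)
        hi = csim.run_erosion_experiment("a", 0.10, seed=21, **common)
        f0_lo = lo[lo.generation == 0]["fst"].mean()
        f5_lo = lo[lo.generation == 5]["fst"].mean()
        f0_hi = hi[hi.generation == 0]["fst"].mean()
        f5_hi = hi[hi.generation == 5]["fst"].mean()
        assert f5_hi / f0_hi < f5_lo / f0_lo        # stronger gene flow erodes faster
        assert f5_lo < f0_lo                        # but even m=0.01 declines


class TestFixtures:
    def test_planted_island_contrast(self):
        gm, island = csim.make_planted_island_genome(
            n_loci=600, island_fst=0.4, background_fst=0.05, seed=8
        )
        per_locus = wc_fst(gm).per_locus
        assert np.nanmean(per_locus[island]) > np.nanmean(
            np.delete(per_locus, island)
        )

    def test_zero_span_plants_nothing(self):
        gm, island = csim.make_planted_island_genome(
            n_loci=200, island_span_cm=0.0, seed=9
        )
        assert len(island) <= 1    # a locus can land exactly on the midpoint

    def test_known_ne_population_shape(self):
        gm = csim.make_known_ne_population(Ne=80, sample_n=30, n_loci=300,
                                           n_lg=10, seed=10, generations=20)
        assert gm.n_individuals == 30
        assert set(gm.pop_labels) == {"P1"}
        p = np.nanmean(gm.dosage(), axis=0) / 2
        assert ((p > 0) & (p < 1)).all()            # monomorphic loci dropped
        assert len(set(gm.loci.linkage_groups)) == 10

    def test_paralog_depth_moments(self):
        gm, dep, is_par = csim.make_paralog_depths(
            n_ind=300, n_loci=200, paralog_fraction=0.1, mean_depth=30, seed=11
        )
        mean_single = dep.total[:, ~is_par].mean()
        assert mean_single == pytest.approx(30.0, abs=3 * np.sqrt(30 / 270))
        het = gm.het_mask()
        assert het[:, is_par].mean(axis=0).mean() > 0.55
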