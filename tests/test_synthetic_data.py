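import dataclasses

import numpy as np
import pytest

from benguela.amova_phist import amova
from benguela.mtdna_diversity import distance_matrix, nucleotide_diversity
from benguela.msat_stats import wc_fst
from benguela.rng import derive_rng
from benguela.synthetic_data import (
    ScenarioConfig,
    simulate_coalescent_pairwise,
    simulate_expansion_sequences,
    simulate_msat_genotypes,
    simulate_two_pop_sequences,
)


SMALL = dataclasses.replace(
    ScenarioConfig(),
    ne=(1000.0, 1000.0),
    ne_ancestral=1000.0,
    split_generations=20_000.0,
    sample_sizes=(12, 12),
    sites_per_deme=((12,), (12,)),
    sequence_length=400,
    mu_per_site=5e-6,
)


class TestDeterminism:
    def test_same_seed_identical_sequences(self):
        cfg = dataclasses.replace(SMALL, seed=42)
        a1, p1 = simulate_two_pop_sequences(cfg)
        a2, p2 = simulate_two_pop_sequences(cfg)
        assert a1 == a2
        assert dict(p1.individual_to_site) == dict(p2.individual_to_site)

    def test_same_seed_identical_genotypes(self):
        cfg = dataclasses.replace(ScenarioConfig(seed=7), msat_sample_sizes=(20, 20),
                                  msat_sites_northern=1)
        g1, _ = simulate_msat_genotypes(cfg)
        g2, _ = simulate_msat_genotypes(cfg)
        assert np.array_equal(g1.calls, g2.calls)

    def test_different_seeds_differ(self):
        a1, _ = simulate_two_pop_sequences(dataclasses.replace(SMALL, seed=1))
        a2, _ = simulate_two_pop_sequences(dataclasses.replace(SMALL, seed=2))
        assert a1.sequences != a2.sequences


class TestCoalescentExpectations:
    def test_pairwise_diversity_matches_theta(self):
        rng = derive_rng(0, "epi-check")
        pis = [simulate_coalescent_pairwise(20, 4.0, rng)["theta_pi"] for _ in range(200)]
        assert np.mean(pis) == pytest.approx(4.0, rel=0.15)

    def test_watterson_segregating_sites(self):
        n, theta = 15, 3.0
        a_n = sum(1.0 / i for i in range(1, n))
        rng = derive_rng(0, "watterson-check")
        ss = [simulate_coalescent_pairwise(n, theta, rng)["segregating_sites"] for _ in range(300)]
        assert np.mean(ss) == pytest.approx(theta * a_n, rel=0.15)

    def test_panmictic_sequences_pi_matches_theta_site(self):
        # single panmictic population: split at 0 with equal sizes
        total = 0.0
        reps = 60
        for s in range(reps):
            cfg = dataclasses.replace(
                SMALL, seed=1000 + s, split_generations=0.0,
                ne_ancestral=1000.0, sequence_length=500, mu_per_site=1e-5,
                sample_sizes=(10, 10), sites_per_deme=((10,), (10,)),
            )
            aln, _ = simulate_two_pop_sequences(cfg)
            total += nucleotide_diversity(aln)
        theta_site = 2 * 1000.0 * 1e-5
        assert total / reps == pytest.approx(theta_site, rel=0.15)


class TestMsprimeCrossCheck:
    """The hand-written coalescent agrees with an established simulator on
    the distribution of pairwise diversity (independent oracle, not a
    dependency of the package itself)."""

    def test_mean_pairwise_diversity_agrees(self):
        msprime = pytest.importorskip("msprime")
        n, theta, reps = 20, 5.0, 150
        rng = derive_rng(0, "msprime-cross")
        ours = [
            simulate_coalescent_pairwise(n, theta, rng)["theta_pi"]
            for _ in range(reps)
        ]
        theirs = []
        for s in range(reps):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=500, random_seed=s + 1
            )
            mts = msprime.sim_mutations(
                ts, rate=theta / (2 * 500), random_seed=s + 1, discrete_genome=False
            )
            theirs.append(mts.diversity(mode="site") * mts.sequence_length)
        assert np.mean(ours) == pytest.approx(np.mean(theirs), rel=0.12)


class TestStructure:
    def test_deep_split_high_phist(self):
        hits = 0
        reps = 20
        for s in range(reps):
            cfg = dataclasses.replace(SMALL, seed=2000 + s)
            aln, pm = simulate_two_pop_sequences(cfg)
            dist = distance_matrix(aln, "differences")
            res = amova(dist, pm, grouping=1, n_perm=0)
            hits += res.phi_st > 0.8
        assert hits >= 0.95 * reps

    def test_no_split_phist_near_zero(self):
        phis = []
        for s in range(20):
            cfg = dataclasses.replace(SMALL, seed=3000 + s, split_generations=0.0)
            aln, pm = simulate_two_pop_sequences(cfg)
            dist = distance_matrix(aln, "differences")
            phis.append(amova(dist, pm, grouping=1, n_perm=0).phi_st)
        assert abs(np.mean(phis)) < 0.08


class TestMsatGenerator:
    def test_no_drift_theta_centred_on_zero(self):
        thetas = []
        for s in range(15):
            cfg = dataclasses.replace(
                ScenarioConfig(seed=s),
                msat_region_generations=0, msat_site_generations=0,
                msat_sample_sizes=(40, 40), msat_sites_northern=1,
                msat_n_loci=6,
            )
            gm, pm = simulate_msat_genotypes(cfg)
            thetas.append(wc_fst(gm, pm, n_perm=0, pairwise=False).global_value)
        assert abs(np.mean(thetas)) < 0.01

    def test_calibrated_drift_reaches_target_fst(self):
        # per-branch drift t generations at Ne: E[theta] ~ 1-(1-1/(2Ne))^(2t)
        thetas = []
        for s in range(15):
            cfg = dataclasses.replace(
                ScenarioConfig(seed=100 + s),
                msat_region_generations=26, msat_site_generations=0,
                msat_ne=500.0, msat_mutation_rate=0.0,
                msat_sample_sizes=(60, 60), msat_sites_northern=1,
                msat_n_loci=10, msat_base_alleles=12,
            )
            gm, pm = simulate_msat_genotypes(cfg)
            thetas.append(wc_fst(gm, pm, n_perm=0, pairwise=False).global_value)
        expected = 1 - (1 - 1 / 1000) ** 26
        assert np.mean(thetas) == pytest.approx(expected, abs=0.015)

    def test_drift_preserves_mean_allele_frequency(self):
        # martingale property of multinomial resampling
        from benguela.synthetic_data import _drift_freqs

        rng = derive_rng(0, "martingale")
        start = {100: 0.3, 102: 0.7}
        means = []
        for _ in range(400):
            out = _drift_freqs(dict(start), 10, 200, 0.0, 2, rng)
            means.append(out.get(100, 0.0))
        assert np.mean(means) == pytest.approx(0.3, abs=0.02)

    def test_null_allele_injection_detected(self):
        from benguela.msat_stats import hwe_test, null_allele_em

        cfg = dataclasses.replace(
            ScenarioConfig(seed=5),
            msat_region_generations=0, msat_site_generations=0,
            msat_sample_sizes=(200,), msat_sites_northern=1,
            msat_n_loci=1, msat_null_freq=0.10, msat_base_alleles=6,
        )
        gm, pm = simulate_msat_genotypes(cfg)
        p = hwe_test(gm, pm, "loc1", n_reps=300, seed=1)["P1"]
        assert p < 0.05
        scored = gm.calls[~gm.missing_mask()[:, 0], 0, :]
        freq, _ = null_allele_em(scored)
        assert freq > 0.04


class TestExpansionScenario:
    def test_strong_expansion_negative_d_on_average(self):
        from benguela.demography import neutrality_tests

        ds = []
        for s in range(25):
            cfg = dataclasses.replace(
                ScenarioConfig(seed=s), expansion_sample_size=30,
                expansion_n_current=500_000.0, expansion_n_ancestral=2_000.0,
                expansion_generations=50_000.0,
            )
            aln = simulate_expansion_sequences(cfg)
            res = neutrality_tests(aln, n_sims=0)
            if np.isfinite(res.tajimas_d):
                ds.append(res.tajimas_d)
        assert np.mean(ds) < -0.5
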