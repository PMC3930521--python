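import dataclasses

import numpy as np
import pytest

from benguela.io_formats import GenotypeMatrix, PopulationMap
from benguela.msat_stats import (
    allelic_richness,
    drift_generations,
    hwe_test,
    jost_dest,
    ld_test,
    locus_summary,
    null_allele_em,
    power_simulation,
    sequential_bonferroni,
    unbiased_expected_het,
    wc_fst,
)
from benguela.synthetic_data import ScenarioConfig, simulate_msat_genotypes
from oracles import brute_wc_theta


class TestLocusSummary:
    def test_rarefaction_combinatorial_value(self):
        assert allelic_richness([2, 2], 2) == pytest.approx(2 * (1 - 1 / 6))

    def test_rarefaction_at_full_sample_returns_na(self):
        counts = [5, 3, 2]
        assert allelic_richness(counts, 10) == pytest.approx(3.0)

    def test_unbiased_he(self):
        # 2 alleles at 50:50 from 5 individuals: He = 10/9 * 0.5
        assert unbiased_expected_het([5, 5]) == pytest.approx(10 / 9 * 0.5)

    def test_all_heterozygotes_ho_one(self, toy_genotypes):
        gm, popmap = toy_genotypes
        ids = tuple(f"h{i}" for i in range(4))
        calls = np.array([[[100, 102]], [[100, 102]], [[100, 102]], [[100, 102]]])
        gm2 = GenotypeMatrix(ids, ("L1",), calls)
        pm = PopulationMap({i: "Z" for i in ids}, {"Z": "g"})
        stats = locus_summary(gm2, pm)
        assert stats.table.loc[("L1", "Z"), "H_O"] == 1.0

    def test_summary_shapes_and_ranges(self, toy_genotypes):
        gm, popmap = toy_genotypes
        stats = locus_summary(gm, popmap)
        assert set(stats.table.columns) == {"n", "Na", "AR", "H_E", "H_O", "F_IS"}
        vals = stats.table[["H_E", "H_O"]].to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        assert (stats.table["AR"] <= stats.table["Na"] + 1e-12).all()


class TestHWE:
    def test_perfect_proportions_not_significant(self):
        # exact HWE proportions for p=0.5: 1/4, 1/2, 1/4 in 20 individuals
        calls = [(100, 100)] * 5 + [(100, 102)] * 10 + [(102, 102)] * 5
        ids = tuple(f"i{k}" for k in range(20))
        gm = GenotypeMatrix(ids, ("L",), np.array([[c] for c in calls]))
        pm = PopulationMap({i: "A" for i in ids}, {"A": "g"})
        p = hwe_test(gm, pm, "L", n_reps=500, seed=1)["A"]
        assert p > 0.2

    def test_strong_homozygote_excess_detected(self):
        calls = [(100, 100)] * 9 + [(102, 102)] * 9 + [(100, 102)] * 2
        ids = tuple(f"i{k}" for k in range(20))
        gm = GenotypeMatrix(ids, ("L",), np.array([[c] for c in calls]))
        pm = PopulationMap({i: "A" for i in ids}, {"A": "g"})
        p = hwe_test(gm, pm, "L", n_reps=500, seed=1)["A"]
        assert p < 0.01

    def test_few_genotype_classes_flagged_p_one(self):
        calls = [(100, 100)] * 5
        ids = tuple(f"i{k}" for k in range(5))
        gm = GenotypeMatrix(ids, ("L",), np.array([[c] for c in calls]))
        pm = PopulationMap({i: "A" for i in ids}, {"A": "g"})
        assert hwe_test(gm, pm, "L", n_reps=100, seed=0)["A"] == 1.0


class TestLD:
    def test_duplicated_locus_boundary_p(self):
        rng = np.random.default_rng(0)
        geno = [tuple(sorted(rng.choice([100, 102, 104], 2))) for _ in range(30)]
        calls = np.array([[g, g] for g in geno])
        ids = tuple(f"i{k}" for k in range(30))
        gm = GenotypeMatrix(ids, ("L1", "L2"), calls)
        pm = PopulationMap({i: "A" for i in ids}, {"A": "g"})
        n_reps = 200
        p = ld_test(gm, pm, ("L1", "L2"), n_reps=n_reps, seed=2)["A"]
        assert p <= 5 / (n_reps + 1)

    def test_independent_loci_not_significant(self):
        rng = np.random.default_rng(1)
        calls = np.array(
            [
                [tuple(sorted(rng.choice([100, 102], 2))), tuple(sorted(rng.choice([200, 202], 2)))]
                for _ in range(40)
            ]
        )
        ids = tuple(f"i{k}" for k in range(40))
        gm = GenotypeMatrix(ids, ("L1", "L2"), calls)
        pm = PopulationMap({i: "A" for i in ids}, {"A": "g"})
        p = ld_test(gm, pm, ("L1", "L2"), n_reps=200, seed=3)["A"]
        assert p > 0.05


class TestNullAlleles:
    def test_hwe_consistent_data_near_zero(self):
        rng = np.random.default_rng(4)
        alleles = [100, 102, 104, 106]
        p = np.array([0.4, 0.3, 0.2, 0.1])
        calls = rng.choice(alleles, size=(400, 2), p=p)
        freq, converged = null_allele_em(calls)
        assert converged
        assert freq < 0.03

    def test_recovers_injected_null_frequency(self):
        rng = np.random.default_rng(5)
        alleles = [100, 102, 104, 106, 108]
        p = np.array([0.25, 0.25, 0.2, 0.2, 0.1])
        true_null = 0.10
        full = np.append(p * (1 - true_null), true_null)
        draws = rng.choice(len(full), size=(500, 2), p=full)
        out = []
        for a, b in draws:
            if a == 5 and b == 5:
                continue  # failed amplification
            if a == 5:
                out.append((alleles[b], alleles[b]))
            elif b == 5:
                out.append((alleles[a], alleles[a]))
            else:
                out.append((alleles[a], alleles[b]))
        freq, converged = null_allele_em(np.array(out))
        assert converged
        assert freq == pytest.approx(true_null, abs=0.03)


class TestDifferentiation:
    def test_theta_matches_independent_oracle(self, toy_genotypes):
        gm, popmap = toy_genotypes
        labels = popmap.site_labels(gm.sample_ids)
        for l, locus in enumerate(gm.locus_names):
            sub = GenotypeMatrix(gm.sample_ids, (locus,), gm.calls[:, [l], :])
            res = wc_fst(sub, popmap, n_perm=0, pairwise=False)
            oracle = brute_wc_theta(
                {
                    p: [tuple(c) for c in gm.calls[labels == p, l, :].tolist()]
                    for p in ("X", "Y")
                }
            )
            assert res.global_value == pytest.approx(oracle, abs=1e-10)

    def test_fixed_differences_theta_one(self):
        ids = tuple(f"i{k}" for k in range(8))
        calls = np.array(
            [[[100, 100], [200, 200]]] * 4 + [[[120, 120], [220, 220]]] * 4
        )
        gm = GenotypeMatrix(ids, ("L1", "L2"), calls)
        pm = PopulationMap(
            {ids[k]: ("A" if k < 4 else "B") for k in range(8)},
            {"A": "g1", "B": "g2"},
        )
        res = wc_fst(gm, pm, n_perm=0, pairwise=False)
        assert res.global_value == pytest.approx(1.0)

    def test_dest_fixed_alleles_one_locus_is_one(self):
        ids = tuple(f"i{k}" for k in range(8))
        calls = np.array([[[100, 100]]] * 4 + [[[120, 120]]] * 4)
        gm = GenotypeMatrix(ids, ("L1",), calls)
        pm = PopulationMap(
            {ids[k]: ("A" if k < 4 else "B") for k in range(8)},
            {"A": "g1", "B": "g2"},
        )
        res = jost_dest(gm, pm, pairwise=False)
        assert res.global_value == pytest.approx(1.0)

    def test_dest_identical_frequencies_zero(self):
        ids = tuple(f"i{k}" for k in range(8))
        block = [[[100, 120]], [[100, 100]], [[120, 120]], [[100, 120]]]
        calls = np.array(block + block)
        gm = GenotypeMatrix(ids, ("L1",), calls)
        pm = PopulationMap(
            {ids[k]: ("A" if k < 4 else "B") for k in range(8)},
            {"A": "g1", "B": "g2"},
        )
        res = jost_dest(gm, pm, pairwise=False)
        assert res.global_value == pytest.approx(0.0, abs=1e-12)

    def test_permutation_p_significant_for_structured_data(self, toy_genotypes):
        gm, popmap = toy_genotypes
        res = wc_fst(gm, popmap, n_perm=500, seed=7, pairwise=False)
        assert res.global_value > 0
        assert res.global_p < 0.05


class TestPower:
    def test_drift_generations_closed_form(self):
        assert drift_generations(0.05, 500) == 52
        assert drift_generations(0.0, 500) == 0

    def test_power_monotone_in_target_fst(self):
        rng = np.random.default_rng(11)
        base = [rng.dirichlet(np.ones(8)) for _ in range(5)]
        powers = [
            power_simulation(base, 500, f, [50, 50], reps=60, seed=13).power
            for f in (0.0, 0.02, 0.08)
        ]
        assert powers[2] >= powers[1] >= powers[0] - 0.1
        assert powers[2] > 0.9

    def test_strong_signal_detected(self):
        rng = np.random.default_rng(12)
        base = [rng.dirichlet(np.ones(10)) for _ in range(7)]
        res = power_simulation(base, 500, 0.05, [50, 50], reps=50, seed=17)
        assert res.t_generations == 52
        assert res.power > 0.95


class TestSequentialBonferroni:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.04], [True, True, True]),
            ([0.04, 0.04, 0.04], [False, False, False]),
            ([0.04], [True]),
            ([0.001, 0.5, 0.9], [True, False, False]),
        ],
    )
    def test_holm_hand_cases(self, pvals, expected):
        assert sequential_bonferroni(pvals, 0.05).tolist() == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sequential_bonferroni([0.5, 1.2])
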