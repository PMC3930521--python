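import dataclasses
from fractions import Fraction

import numpy as np
import pytest

from benguela.demography import (
    ClockConfig,
    ewens_k_distribution,
    expected_mismatch,
    fit_sudden_expansion,
    fus_fs,
    log_stirling_first,
    mismatch_observed,
    net_divergence_time,
    neutrality_tests,
    rate_conversions,
    tajimas_d_from_counts,
    time_since_expansion,
)
from benguela.io_formats import SequenceAlignment
from benguela.rng import derive_rng
from benguela.synthetic_data import ScenarioConfig, simulate_expansion_sequences


def _aln(seqs: list) -> SequenceAlignment:
    return SequenceAlignment.from_records([f"s{i}" for i in range(len(seqs))], seqs)


class TestTajimasD:
    def test_published_constants_toy_value(self):
        assert tajimas_d_from_counts(10, 5, 1.5) == pytest.approx(-0.607, abs=1e-3)

    def test_undefined_without_segregating_sites(self):
        with pytest.raises(ValueError):
            tajimas_d_from_counts(10, 0, 0.0)

    def test_neutral_constant_size_mean_near_zero(self):
        from benguela.synthetic_data import simulate_coalescent_pairwise

        rng = derive_rng(0, "neutral-null")
        ds = []
        for _ in range(300):
            sim = simulate_coalescent_pairwise(15, 4.0, rng)
            if sim["segregating_sites"] >= 1:
                ds.append(
                    tajimas_d_from_counts(15, sim["segregating_sites"], sim["theta_pi"])
                )
        assert abs(np.mean(ds)) < 0.15


class TestFusFs:
    def test_exact_rational_toy(self):
        # n=4, theta=1: rising factorial 24; P(K>=3) = (6+1)/24 = 7/24
        assert fus_fs(4, 3, 1.0) == pytest.approx(float(np.log(7 / 17)), abs=1e-10)

    def test_stirling_recurrence_matches_exact_rationals(self):
        # exact unsigned Stirling numbers via integer recurrence
        for n in range(2, 13):
            exact = [[Fraction(0)] * (n + 1) for _ in range(n + 1)]
            exact[0][0] = Fraction(1)
            for m in range(1, n + 1):
                for k in range(1, m + 1):
                    exact[m][k] = (m - 1) * exact[m - 1][k] + exact[m - 1][k - 1]
            log_s = log_stirling_first(n)
            for k in range(1, n + 1):
                assert log_s[k] == pytest.approx(
                    float(np.log(float(exact[n][k]))), abs=1e-10
                )

    def test_single_haplotype_infinite(self):
        assert fus_fs(10, 1, 2.0) == float("inf")

    def test_many_haplotypes_small_theta_strongly_negative(self):
        assert fus_fs(20, 20, 0.5) < -20

    def test_ewens_distribution_normalised(self):
        p = ewens_k_distribution(25, 3.7)
        assert p.sum() == pytest.approx(1.0)
        assert (p >= 0).all()


class TestMismatch:
    def test_identical_sequences_point_mass_at_zero(self):
        mm = mismatch_observed(_aln(["ACGT", "ACGT", "ACGT"]))
        assert mm.tolist() == [1.0]

    def test_two_sequences_three_differences(self):
        mm = mismatch_observed(_aln(["AAAA", "TTTA"]))
        assert mm[3] == 1.0 and mm[:3].sum() == 0.0

    def test_hand_counted_four_sequences(self):
        # pairwise diffs: s0-s1:1, s0-s2:2, s0-s3:1, s1-s2:1, s1-s3:2, s2-s3:3
        mm = mismatch_observed(_aln(["AAAA", "AAAT", "AATT", "TAAA"]))
        expected = np.array([0, 3, 2, 1]) / 6
        assert np.allclose(mm, expected)

    def test_expected_curve_normalised_and_tau0_mean(self):
        em = expected_mismatch(0.0, 2.5, 30.0, 600)
        assert em.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.arange(601) * em).sum() == pytest.approx(2.5, abs=1e-6)

    def test_expected_curve_large_tau_approaches_theta1_equilibrium(self):
        em = expected_mismatch(150.0, 1.0, 8.0, 2000)
        j = np.arange(2001)
        eq = np.exp(j * np.log(8.0) - (j + 1) * np.log(9.0))
        assert np.allclose(em, eq, atol=1e-6)


class TestExpansionFit:
    def test_recovers_parameters_from_model_curve(self):
        truth = (3.0, 1.0, 20.0)  # tau, theta0, theta1
        curve = expected_mismatch(*truth, max_diff=40)
        fit = fit_sudden_expansion(curve, n=50, n_boot=0)
        assert fit.ssd < 1e-8
        assert fit.tau == pytest.approx(3.0, abs=0.2)
        assert fit.theta0 == pytest.approx(1.0, abs=0.3)

    def test_simulated_expansion_gives_negative_d_and_unimodal_fit(self):
        cfg = dataclasses.replace(ScenarioConfig(seed=21), expansion_sample_size=50,
                                  expansion_n_current=500_000.0,
                                  expansion_n_ancestral=5_000.0)
        aln = simulate_expansion_sequences(cfg)
        neut = neutrality_tests(aln, n_sims=0)
        assert neut.tajimas_d < 0
        fit = fit_sudden_expansion(mismatch_observed(aln), aln.n, n_boot=50, seed=2)
        assert fit.p_ssd is None or fit.p_ssd > 0.01

    def test_needs_two_distinct_counts(self):
        with pytest.raises(ValueError):
            fit_sudden_expansion(np.array([1.0]), n=10, n_boot=0)


class TestClock:
    def test_tau_zero_gives_zero(self):
        clock = ClockConfig(3.6, 583, 2.2)
        assert time_since_expansion(0.0, clock).years == 0.0

    def test_linear_in_tau_and_inverse_in_rate_and_length(self):
        c1 = ClockConfig(3.6, 583, 2.2)
        c2 = ClockConfig(7.2, 583, 2.2)
        c3 = ClockConfig(3.6, 1166, 2.2)
        t1 = time_since_expansion(2.0, c1).years
        assert time_since_expansion(4.0, c1).years == pytest.approx(2 * t1)
        assert time_since_expansion(2.0, c2).years == pytest.approx(t1 / 2)
        assert time_since_expansion(2.0, c3).years == pytest.approx(t1 / 2)

    def test_study_scale_conversion(self):
        # tau = 2.492 on a 583 bp fragment at 3.6%/My divergence:
        # ~119 Ky in years, ~54 thousand generations at 2.2 y/generation
        clock = ClockConfig(3.6, 583, 2.2)
        out = time_since_expansion(2.492, clock)
        assert out.years == pytest.approx(2.492 / (2 * 1.8e-8 * 583), rel=1e-12)
        assert out.generations == pytest.approx(out.years / 2.2)

    def test_ci_propagation(self):
        clock = ClockConfig(3.6, 583, 2.2)
        out = time_since_expansion(2.0, clock, tau_ci=(1.0, 4.0))
        assert out.years_ci[0] == pytest.approx(out.years / 2)
        assert out.years_ci[1] == pytest.approx(out.years * 2)


class TestRateConversions:
    def test_zero_migration(self):
        rc = rate_conversions(0.01, 0.0, 1.0, 1e-5)
        assert rc.m == 0.0 and rc.migrants_theta_M == 0.0

    def test_direct_arithmetic(self):
        rc = rate_conversions(0.004, 100.0, 4.0, 1e-4)
        assert rc.ne == pytest.approx(10.0)
        rc2 = rate_conversions(0.004, 100.0, 4.0, 1e-5)
        assert rc2.m == pytest.approx(1e-3)

    def test_zero_mutation_rate_rejected(self):
        with pytest.raises(ValueError):
            rate_conversions(0.01, 1.0, 1.0, 0.0)


class TestNetDivergence:
    def test_zero_net_divergence(self):
        assert net_divergence_time(0.008, 0.008, 0.008, 3.6) == (0.0, False)

    def test_negative_net_divergence_flagged(self):
        t, flagged = net_divergence_time(0.004, 0.008, 0.008, 3.6)
        assert t == 0.0 and flagged

    def test_direct_arithmetic(self):
        t, flagged = net_divergence_time(0.05, 0.008, 0.008, 3.6)
        assert not flagged
        assert t == pytest.approx(0.042 / 0.036)
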