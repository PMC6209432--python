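"""Double-exponential uptake fits, global shared-rate fits, intrinsic rates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memstab import (
    PeptideID,
    UptakeSeries,
    double_exponential,
    fit_uptake,
    fit_uptake_global,
    gen_uptake,
    gen_uptake_melt_series,
    intrinsic_reference,
    max_exchangeable,
    slow_fraction_curve,
)
from memstab.hdx_rates import _FACTORS, _LOG_KA, _LOG_KB, _LOG_KW, _PKD


class TestMaxExchangeable:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GSA", 2), ("GPA", 1), ("GP", 0), ("AAAA", 3), ("PAAP", 2)],
    )
    def test_first_amide_and_prolines_excluded(self, seq, expected):
        assert max_exchangeable(seq) == expected

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            max_exchangeable("")

    def test_peptide_id_consistency(self):
        pep = PeptideID(sequence="GPAL", start=10, end=13, charge=2)
        assert pep.max_exchangeable == 2
        with pytest.raises(ValueError, match="span"):
            PeptideID(sequence="GPAL", start=10, end=14, charge=2)


class TestIntrinsicReference:
    def test_gp_dipeptide_has_no_exchangeable_amide(self):
        ref = intrinsic_reference("GP")
        assert ref.overall_rate == 0.0
        assert np.all(ref.predicted_curve([10.0, 100.0]) == 0.0)

    def test_dipeptide_rates_match_direct_table_evaluation(self):
        # independent inline evaluation of the published-factor scheme for
        # the single amide of Ala-Leu at pD 7.4, 20 C (free termini)
        la_acid, _, la_base, _ = _FACTORS["L"]
        _, ra_acid, _, ra_base = _FACTORS["A"]
        log_fa = la_acid + ra_acid + (-1.32) + 0.96  # N-term rho + C-term lambda
        log_fb = la_base + ra_base + 1.62 + (-1.80)
        ka = 10.0 ** (_LOG_KA + log_fa) * 10.0 ** (-7.4)
        kb = 10.0 ** (_LOG_KB + log_fb) * 10.0 ** (7.4 - _PKD)
        kw = 10.0 ** (_LOG_KW + log_fb)
        expected = (ka + kb + kw) / 60.0
        ref = intrinsic_reference("AL", pD=7.4, temperature_C=20.0)
        assert ref.per_amide[2] == pytest.approx(expected, rel=0.05)

    def test_unstructured_10mer_saturates_well_under_10s(self):
        ref = intrinsic_reference("GLSAKEQTVA", pD=7.4, temperature_C=20.0)
        uptake_10s = float(ref.predicted_curve(10.0))
        assert uptake_10s > 0.9 * ref.n_exchangeable
        # interior amides exchange in well under a second; only the
        # termini-adjacent amides are slowed by the charged-end factors
        interior = [k for pos, k in ref.per_amide.items()
                    if 3 <= pos <= len(ref.sequence) - 1]
        assert min(interior) > 0.5

    def test_temperature_correction_accelerates_exchange(self):
        cold = intrinsic_reference("GLSA", temperature_C=0.0).overall_rate
        warm = intrinsic_reference("GLSA", temperature_C=20.0).overall_rate
        assert warm > 2 * cold

    def test_single_exponential_mode_uses_summed_rate(self):
        ref = intrinsic_reference("GLSA")
        t = np.array([1e-6])
        # both modes have initial slope = overall rate
        slope_sum = ref.predicted_curve(t, mode="sum")[0] / 1e-6
        assert slope_sum == pytest.approx(ref.overall_rate, rel=1e-3)

    def test_rate_order_dependence_on_neighbors(self):
        # permuting unequal residues changes the overall rate (neighbor
        # factors are positional), while a homopolymer is permutation-proof
        assert intrinsic_reference("ASLG").overall_rate != pytest.approx(
            intrinsic_reference("AGLS").overall_rate
        )
        assert intrinsic_reference("AAAA").overall_rate == pytest.approx(
            intrinsic_reference("AAAA").overall_rate
        )

    def test_untabulated_residue_rejected(self):
        with pytest.raises(ValueError, match="tabulated"):
            intrinsic_reference("AXB")


class TestFitUptake:
    def test_all_zero_series_returns_zero_amplitudes(self, peptide):
        series = UptakeSeries(
            peptide=peptide, condition=20.0,
            times_s=np.array([10.0, 60.0, 300.0, 1800.0]),
            uptake_Da=np.zeros(4),
        )
        fit = fit_uptake(series, amplitude_ceiling=5.5)
        assert (fit.a0, fit.a1, fit.a2) == (0.0, 0.0, 0.0)

    def test_noiseless_parameters_recovered_within_one_percent(self, peptide):
        truth = dict(a0=0.5, a1=2.0, a2=3.0, k1=0.05, k2=5e-4)
        series, _ = gen_uptake(
            peptide, {20.0: (truth["a0"], truth["a1"], truth["a2"])},
            (truth["k1"], truth["k2"]), seed=0,
        )
        fit = fit_uptake(series[20.0], amplitude_ceiling=5.5)
        for name in truth:
            assert getattr(fit, name) == pytest.approx(truth[name], rel=0.01)
        # constraint holds exactly
        assert fit.a0 + fit.a1 + fit.a2 == pytest.approx(5.5, abs=1e-12)

    def test_recovered_rates_fall_in_expected_regimes(self, peptide):
        series, _ = gen_uptake(peptide, {20.0: (0.3, 2.5, 4.0)}, (0.02, 3e-4),
                               noise_sd=0.05, seed=8)
        fit = fit_uptake(series[20.0], amplitude_ceiling=6.8)
        assert 1e-2 <= fit.k1 <= 1e-1
        assert fit.k2 < 1e-3

    def test_ceiling_below_observed_uptake_rejected(self, peptide):
        series, _ = gen_uptake(peptide, {20.0: (0.5, 2.0, 3.0)}, (0.05, 5e-4), seed=0)
        with pytest.raises(ValueError, match="ceiling"):
            fit_uptake(series[20.0], amplitude_ceiling=2.0)

    def test_too_few_time_points_rejected(self, peptide):
        series = UptakeSeries(
            peptide=peptide, condition=20.0,
            times_s=np.array([10.0, 60.0, 300.0]), uptake_Da=np.array([1.0, 2.0, 3.0]),
        )
        with pytest.raises(ValueError, match="4 time points"):
            fit_uptake(series, amplitude_ceiling=5.0)

    def test_fitted_model_is_monotone_in_time(self, peptide):
        series, _ = gen_uptake(peptide, {20.0: (0.5, 2.0, 3.0)}, (0.05, 5e-4),
                               noise_sd=0.1, seed=2)
        fit = fit_uptake(series[20.0], amplitude_ceiling=6.0)
        t = np.linspace(0, 5000, 400)
        assert np.all(np.diff(fit.predict(t)) >= 0)


class TestGlobalFit:
    def test_six_temperature_noiseless_recovery_within_two_percent(self, peptide):
        temps = [20.0, 30.0, 40.0, 50.0, 60.0, 65.0]
        series, truth = gen_uptake_melt_series(
            peptide, t50=50.0, h=-15.0, temperatures_C=temps, seed=0
        )
        g = fit_uptake_global(series, saturating_max=truth["total_uptake"])
        assert g.k1 == pytest.approx(0.05, rel=0.02)
        assert g.k2 == pytest.approx(5e-4, rel=0.02)
        for t in temps:
            want = truth["per_temperature_params"][t]
            got = g.amplitudes[t]
            for w, v in zip(want, got):
                assert v == pytest.approx(w, rel=0.02, abs=0.02)

    def test_identical_conditions_get_identical_amplitudes(self, peptide):
        s, _ = gen_uptake(peptide, {20.0: (0.5, 2.0, 3.0)}, (0.05, 5e-4), seed=0)
        base = s[20.0]
        twin = UptakeSeries(peptide=peptide, condition=21.0, times_s=base.times_s,
                            uptake_Da=base.uptake_Da.copy())
        g = fit_uptake_global({20.0: base, 21.0: twin}, saturating_max=5.5)
        np.testing.assert_allclose(g.amplitudes[20.0], g.amplitudes[21.0], rtol=1e-6)
        single = fit_uptake(base, amplitude_ceiling=5.5)
        assert g.rss == pytest.approx(2 * single.rss, abs=1e-10)

    def test_shared_rate_constraint_never_beats_free_fits(self, peptide):
        # different true rates per condition: sharing must cost RSS
        sa, _ = gen_uptake(peptide, {20.0: (0.5, 2.0, 3.0)}, (0.08, 8e-4),
                           noise_sd=0.05, seed=1)
        sb, _ = gen_uptake(peptide, {50.0: (2.0, 2.5, 1.0)}, (0.02, 2e-4),
                           noise_sd=0.05, seed=2)
        series = {20.0: sa[20.0], 50.0: sb[50.0]}
        g = fit_uptake_global(series, saturating_max=5.6)
        free = sum(fit_uptake(s, amplitude_ceiling=5.6).rss for s in series.values())
        assert g.rss >= free - 1e-9

    def test_single_condition_rejected(self, peptide):
        s, _ = gen_uptake(peptide, {20.0: (0.5, 2.0, 3.0)}, (0.05, 5e-4), seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            fit_uptake_global(s, saturating_max=5.5)

    def test_twenty_peptide_noisy_panel_recovery(self):
        """k1, k2 within 15%, slow fractions within 0.05 at 0.05 Da noise, 3 reps."""
        rng = np.random.default_rng(7)
        temps = np.arange(20.0, 65.1, 5.0)
        for _ in range(20):
            L = int(rng.integers(8, 15))
            seq = "".join(rng.choice(list("ACDEFGHIKLMNQRSTVWY"), L))
            pep = PeptideID(sequence=seq, start=100, end=100 + L - 1, charge=2)
            k1 = float(rng.uniform(0.01, 0.06))
            k2 = float(rng.uniform(2e-4, 8e-4))
            series, truth = gen_uptake_melt_series(
                pep, t50=float(rng.uniform(38, 55)), h=float(rng.uniform(-18, -6)),
                temperatures_C=temps, shared_rates=(k1, k2),
                noise_sd=0.05, n_replicates=3, seed=int(rng.integers(2**31)),
            )
            ceiling = max(float(s.uptake_Da.max()) for s in series.values())
            g = fit_uptake_global(series, saturating_max=ceiling)
            assert g.k1 == pytest.approx(k1, rel=0.15)
            assert g.k2 == pytest.approx(k2, rel=0.15)
            for t, (a0, a1, a2) in truth["per_temperature_params"].items():
                true_frac = a2 / (a0 + a1 + a2)
                assert g.slow_fractions[t] == pytest.approx(true_frac, abs=0.05)


class TestSlowFractionCurve:
    def test_reference_normalizes_to_exactly_one(self, peptide):
        series, truth = gen_uptake_melt_series(
            peptide, t50=50.0, h=-15.0, temperatures_C=[20.0, 40.0, 50.0, 60.0], seed=0
        )
        g = fit_uptake_global(series, saturating_max=truth["total_uptake"])
        norm = slow_fraction_curve(g, reference_condition=20.0)
        assert norm[20.0] == 1.0

    def test_normalization_arithmetic(self, peptide):
        from memstab.hdx_kinetics import GlobalExpFit

        g = GlobalExpFit(
            peptide=peptide, k1=0.05, k2=5e-4,
            amplitudes={20.0: (0.1, 0.1, 0.8), 50.0: (0.3, 0.3, 0.4)},
            constraint_max=1.0, rss=0.0, dof=1, success=True,
        )
        norm = slow_fraction_curve(g, 20.0)
        assert norm[20.0] == pytest.approx(1.0)
        assert norm[50.0] == pytest.approx(0.5)

    def test_zero_reference_fraction_flags_unanalyzable(self, peptide):
        from memstab.hdx_kinetics import GlobalExpFit

        g = GlobalExpFit(
            peptide=peptide, k1=0.05, k2=5e-4,
            amplitudes={20.0: (0.5, 0.5, 0.0), 50.0: (0.3, 0.3, 0.4)},
            constraint_max=1.0, rss=0.0, dof=1, success=True,
        )
        with pytest.raises(ValueError, match="unanalyzable"):
            slow_fraction_curve(g, 20.0)


@given(
    a0=st.floats(0.0, 2.0),
    a1=st.floats(0.0, 3.0),
    a2=st.floats(0.0, 3.0),
    k1=st.floats(1e-3, 1.0),
    k2=st.floats(1e-6, 1e-3),
)
def test_double_exponential_monotone_and_bounded(a0, a1, a2, k1, k2):
    t = np.linspace(0.0, 5000.0, 200)
    y = double_exponential(t, a0, a1, a2, k1, k2)
    assert np.all(np.diff(y) >= -1e-12)
    assert y[0] == pytest.approx(a0, abs=1e-9) or t[0] > 0
    assert np.all(y <= a0 + a1 + a2 + 1e-9)
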