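"""Reduced spectral density mapping: inversion accuracy, the
single-correlation-time locus, τc estimation, exchange detection and the
two-protein comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pindyn.io import records_from_relax
from pindyn.relaxmap import (
    ResidueRelaxationRecord,
    SpectralDensityTriple,
    compare_proteins,
    estimate_tau_c,
    exchange_excess,
    hnoe_from_pair,
    map_table,
    reduced_spectral_densities,
    theoretical_JwN,
)
from pindyn.synthdata import (
    MotionModel,
    lorentzian_J,
    relaxation_rates,
    simulate_relaxation,
)


def _record_from_motion(motion, ctx, rid=1):
    r1, r2, noe = relaxation_rates(motion, ctx)
    return ResidueRelaxationRecord(rid, r1, 0.02 * r1, r2, 0.02 * r2,
                                   noe, 0.02)


def _triple(rid, j0, jwn=None, jwh=0.002, err=0.05):
    jwn = theoretical_JwN(j0) if jwn is None else jwn
    return SpectralDensityTriple(rid, j0, err, jwn, err, jwh, err)


class TestMapping:
    def test_rigid_forward_then_invert(self, ctx):
        # mapping approximation error stays below 5% relative on J0
        for tc in (5e-9, 9.75e-9, 15e-9):
            rec = _record_from_motion(MotionModel(tau_c=tc), ctx)
            t = reduced_spectral_densities(rec, ctx, mc_draws=0)
            assert t.J0 == pytest.approx(0.4 * tc * 1e9, rel=0.05)

    def test_rigid_9p75ns_maps_close_to_3p9(self, ctx):
        rec = _record_from_motion(MotionModel(tau_c=9.75e-9), ctx)
        t = reduced_spectral_densities(rec, ctx, mc_draws=0)
        assert t.J0 == pytest.approx(3.9, rel=0.005)

    def test_hnoe_of_one_gives_zero_jwh(self, ctx):
        rec = ResidueRelaxationRecord(1, 1.2, 0.0, 16.0, 0.0, 1.0, 0.0)
        t = reduced_spectral_densities(rec, ctx, mc_draws=0)
        assert t.Jwh == 0.0

    def test_zero_mc_draws_reports_zero_errors(self, ctx):
        rec = _record_from_motion(MotionModel(tau_c=9.8e-9), ctx)
        t0 = reduced_spectral_densities(rec, ctx, mc_draws=0)
        t1 = reduced_spectral_densities(rec, ctx, mc_draws=200, seed=4)
        assert t0.J0_err == 0.0 and t1.J0_err > 0.0
        assert t0.J0 == t1.J0  # point value untouched by Monte-Carlo

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            ResidueRelaxationRecord(1, np.nan, 0.0, 16.0, 0.0, 0.9, 0.0)

    def test_points_lie_on_locus_for_rigid_residues(self, ctx):
        # mapped (J0, JwN) of rigid synthetic residues fall on the
        # single-correlation-time curve within the mapping approximation
        for tc in np.linspace(6e-9, 14e-9, 9):
            rec = _record_from_motion(MotionModel(tau_c=tc), ctx)
            t = reduced_spectral_densities(rec, ctx, mc_draws=0)
            assert t.JwN == pytest.approx(theoretical_JwN(t.J0, ctx),
                                          rel=0.02)


class TestTheoreticalLocus:
    @given(st.floats(min_value=1e-3, max_value=10.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_identity_with_rigid_lorentzian(self, j0):
        # J(wN) locus == rigid Lorentzian evaluated at tau_c = 2.5*J0
        from pindyn.context import SpectrometerContext
        ctx = SpectrometerContext()
        locus = theoretical_JwN(j0, ctx)
        lorentz = lorentzian_J(MotionModel(tau_c=2.5 * j0 * 1e-9),
                               ctx.omega_N) * 1e9
        assert locus == pytest.approx(lorentz, rel=1e-12)

    def test_zero_frequency_identity(self):
        from pindyn.context import SpectrometerContext
        ctx = SpectrometerContext(proton_frequency_hz=1.0)  # omega_N ~ 0
        assert theoretical_JwN(3.9, ctx) == pytest.approx(3.9, rel=1e-9)

    def test_zero_maps_to_zero(self, ctx):
        assert theoretical_JwN(0.0, ctx) == 0.0


class TestTauCEstimate:
    def test_zero_variance_selects_everything(self):
        triples = [_triple(i, 3.9) for i in range(1, 6)]
        est = estimate_tau_c(triples)
        assert len(est.selected_residues) == 5
        assert est.tau_c == pytest.approx(2.5 * 3.9, rel=1e-12)

    def test_selection_band_is_half_sigma(self):
        # one far outlier widens sigma but is excluded from the re-average
        j0s = [3.9] * 10 + [6.0]
        triples = [_triple(i, j) for i, j in enumerate(j0s, 1)]
        est = estimate_tau_c(triples)
        assert 11 not in est.selected_residues
        assert est.reaveraged_J0 == pytest.approx(3.9, rel=1e-9)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            estimate_tau_c([_triple(1, 3.9), _triple(2, 3.9)])

    @pytest.mark.parametrize("tc_ns", [8.0, 9.8, 12.0])
    def test_tau_c_recovery_under_noise(self, tc_ns):
        # 100-residue rigid protein, 2% noise: median estimate within 3%
        estimates = []
        for seed in range(25):
            models = [MotionModel(tau_c=tc_ns * 1e-9)] * 100
            df = simulate_relaxation(models, noise_fraction=0.02, seed=seed)
            trips = map_table(records_from_relax(df), mc_draws=0)
            estimates.append(estimate_tau_c(trips).tau_c)
        assert np.median(estimates) == pytest.approx(tc_ns, rel=0.03)


class TestExchangeExcess:
    def test_threshold_arithmetic(self):
        j0s = [3.8, 3.9, 4.0, 3.9, 3.9]
        triples = [_triple(i, j) for i, j in enumerate(j0s, 1)]
        est = estimate_tau_c(triples)
        cut = est.mean_J0_all + 0.5 * est.sigma_J0
        flagged = {e.residue_id for e in exchange_excess(triples, est)
                   if e.is_outlier}
        expected = {t.residue_id for t in triples if t.J0 > cut}
        assert flagged == expected

    def test_rex_residue_flagged_with_positive_excess(self, ctx):
        models = [MotionModel(tau_c=9.8e-9)] * 50
        models[10] = MotionModel(tau_c=9.8e-9, R_ex=5.0)
        df = simulate_relaxation(models, noise_fraction=0.005, seed=3)
        trips = map_table(records_from_relax(df), ctx, mc_draws=0)
        est = estimate_tau_c(trips)
        excess = {e.residue_id: e for e in exchange_excess(trips, est)}
        assert excess[11].is_outlier and excess[11].delta_J0 > 0.5

    def test_rigid_protein_deltas_near_zero(self, ctx):
        # without exchange, excess values scatter around zero within a few
        # noise widths and only the expected upper-tail fraction is flagged
        n_flagged, deltas = 0, []
        for seed in range(40):
            models = [MotionModel(tau_c=9.8e-9)] * 50
            df = simulate_relaxation(models, noise_fraction=0.01, seed=seed)
            trips = map_table(records_from_relax(df), ctx, mc_draws=0)
            est = estimate_tau_c(trips)
            for e in exchange_excess(trips, est):
                n_flagged += e.is_outlier
                deltas.append(e.delta_J0)
        # +0.5 sigma one-sided cut on ~Gaussian scatter flags ~31% of
        # residues (upper-tail P(Z > 0.5))
        frac = n_flagged / len(deltas)
        assert 0.2 < frac < 0.4
        assert abs(np.mean(deltas)) < 0.05


class TestOrderParameterBounds:
    def test_high_hnoe_implies_high_order_parameter(self, ctx):
        # scan over tau_e where the hNOE resolves internal motion at this
        # field: any (S0, tau_e) with hNOE > 0.80 must have S0 > 0.9
        for te in np.linspace(55e-12, 100e-12, 10):
            for s0 in np.linspace(0.5, 1.0, 26)[:-1]:
                _, _, hnoe = relaxation_rates(
                    MotionModel(tau_c=9.8e-9, S0=s0, tau_e=te), ctx)
                if hnoe > 0.80:
                    assert s0 > 0.9, (s0, te, hnoe)

    def test_rigid_limit_bias_below_ten_percent_for_s0_above_0p9(self):
        # using the rigid J_calc(0) = (2/5) tau_c underestimates the
        # exchange excess by (1-S0)(1-tau_l/tau_c) <= 10% when S0 >= 0.9
        for s0 in np.linspace(0.9, 1.0, 11):
            for te in np.linspace(1e-12, 100e-12, 10):
                m = MotionModel(tau_c=9.8e-9, S0=s0, tau_e=te)
                rigid = lorentzian_J(MotionModel(tau_c=9.8e-9), 0.0)
                bias = (rigid - lorentzian_J(m, 0.0)) / rigid
                assert 0.0 <= bias <= 0.10 + 1e-12


class TestHnoeFromPair:
    def test_equal_intensities_give_unity(self):
        assert hnoe_from_pair(5.0, 5.0, 0.0)[0] == 1.0

    def test_simple_ratio(self):
        assert hnoe_from_pair(0.8, 1.0, 0.0) == (0.8, 0.0)

    def test_reference_consistent_with_zero_rejected(self):
        with pytest.raises(ValueError):
            hnoe_from_pair(0.5, 0.05, noise_std=0.02)

    def test_error_formula_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        i_sat, i_ref, noise = 0.85, 1.0, 0.02
        _, analytic = hnoe_from_pair(i_sat, i_ref, noise)
        draws = (i_sat + rng.normal(0, noise, 200_000)) / \
                (i_ref + rng.normal(0, noise, 200_000))
        assert analytic == pytest.approx(np.std(draws), rel=0.05)


class TestCompareProteins:
    def test_identical_tables_give_zero_deltas_no_flags(self):
        trips = [_triple(i, 3.9 + 0.01 * i) for i in range(1, 11)]
        df = compare_proteins(trips, trips)
        assert np.allclose(df.dJwN, 0.0)
        assert not df.dJwN_flag.any()
        assert not df.dJwh_flag.any()

    def test_missing_residues_dropped(self):
        a = [_triple(i, 3.9) for i in (1, 2, 3)]
        b = [_triple(i, 3.9) for i in (2, 3, 4)]
        df = compare_proteins(a, b)
        assert list(df.residue) == [2, 3]

    def test_no_shared_residues_rejected(self):
        with pytest.raises(ValueError):
            compare_proteins([_triple(1, 3.9)], [_triple(2, 3.9)])

    def test_extra_ps_motion_flagged_against_trend(self, ctx):
        # mutant tumbles faster (dJwN positive overall); one residue with
        # added fast internal motion moves the other way and is flagged
        wt_models = [MotionModel(tau_c=9.8e-9)] * 30
        mut_models = [MotionModel(tau_c=9.3e-9)] * 30
        mut_models[12] = MotionModel(tau_c=9.3e-9, S0=0.75, tau_e=80e-12)
        wt = map_table(records_from_relax(
            simulate_relaxation(wt_models, noise_fraction=0.002, seed=1)),
            ctx, mc_draws=50, seed=1)
        mut = map_table(records_from_relax(
            simulate_relaxation(mut_models, noise_fraction=0.002, seed=2)),
            ctx, mc_draws=50, seed=2)
        df = compare_proteins(mut, wt).set_index("residue")
        assert np.median(df.dJwN) > 0
        assert df.loc[13, "dJwN"] < 0
        assert bool(df.loc[13, "dJwN_flag"])
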