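"""Model-free spectral densities, rate prediction, decay fits and selection."""

import math

import numpy as np
import pytest

from nmrens.modelfree import (
    DecaySeries,
    FieldConfig,
    MotionalParams,
    RelaxationRecord,
    fit_decay,
    fit_model,
    mc_errors,
    noe_ratio,
    predict_rates,
    select_model,
    spectral_density,
)
from nmrens.synthetic import T1_DELAYS

OMEGA_GRID = np.logspace(7, 10, 25)  # rad/s, spans 0 .. above the 1H frequency


class TestSpectralDensity:
    def test_rigid_rotor_closed_form_at_zero_frequency(self):
        p = MotionalParams(model_id=1, S2=1.0, tau_m=5.67)
        assert spectral_density(p, 0.0) == pytest.approx(0.4 * 5.67e-9, rel=1e-12)

    def test_vanishing_internal_time_reduces_model2_to_model1(self):
        p1 = MotionalParams(model_id=1, S2=0.8, tau_m=5.0)
        p2 = MotionalParams(model_id=2, S2=0.8, tau_m=5.0, tau_e=0.0)
        np.testing.assert_allclose(
            spectral_density(p2, OMEGA_GRID), spectral_density(p1, OMEGA_GRID), rtol=1e-12
        )

    def test_extended_model_with_unit_fast_order_equals_model2(self):
        """Algebraically, Sf²=1 turns the (Sf²−S²) term into (1−S²)."""
        p2 = MotionalParams(model_id=2, S2=0.6, tau_m=5.0, tau_e=300.0)
        p5 = MotionalParams(model_id=5, S2=0.6, S2_f=1.0, tau_m=5.0, tau_e=300.0)
        np.testing.assert_allclose(
            spectral_density(p5, OMEGA_GRID), spectral_density(p2, OMEGA_GRID), rtol=1e-12
        )

    @pytest.mark.parametrize(
        "params",
        [
            MotionalParams(model_id=1, S2=1.0, tau_m=5.67),
            MotionalParams(model_id=2, S2=0.85, tau_m=5.67, tau_e=50.0),
            MotionalParams(model_id=5, S2=0.4, S2_f=0.8, tau_m=5.67, tau_e=1200.0),
        ],
    )
    def test_nonnegative_and_decreasing_in_frequency(self, params):
        J = spectral_density(params, OMEGA_GRID)
        assert np.all(J >= 0)
        assert np.all(np.diff(J) <= 1e-30)


class TestPredictRates:
    def test_exchange_enters_r2_only(self, cfg):
        p1 = MotionalParams(model_id=1, S2=0.85, tau_m=5.67)
        p3 = MotionalParams(model_id=3, S2=0.85, tau_m=5.67, R_ex=5.0)
        r1a, r2a, noea = predict_rates(p1, cfg)
        r1b, r2b, noeb = predict_rates(p3, cfg)
        assert r1b == pytest.approx(r1a, rel=1e-12)
        assert noeb == pytest.approx(noea, rel=1e-12)
        assert r2b == pytest.approx(r2a + 5.0, rel=1e-12)

    def test_against_independent_textbook_formulas(self, cfg):
        """Re-derive R1/R2/NOE from scratch with literal constants and compare."""
        tau_m = 5.67e-9
        mu0_4pi, hbar = 1e-7, 1.054571817e-34
        gh, gn = 2.6752218708e8, -2.7126189e7
        r = 1.02e-10
        wh = 2 * math.pi * 600.13e6
        wn = wh * gn / gh
        d = mu0_4pi * hbar * gh * gn / r**3
        csa = -160e-6
        c2 = (wn * csa) ** 2 / 3.0

        def j(w):
            return 0.4 * tau_m / (1.0 + (w * tau_m) ** 2)

        r1 = (d * d / 4) * (j(wh - wn) + 3 * j(wn) + 6 * j(wh + wn)) + c2 * j(wn)
        r2 = (d * d / 8) * (
            4 * j(0) + j(wh - wn) + 3 * j(wn) + 6 * j(wh) + 6 * j(wh + wn)
        ) + (c2 / 6) * (4 * j(0) + 3 * j(wn))
        noe = 1 + (d * d / (4 * r1)) * (gh / gn) * (6 * j(wh + wn) - j(wh - wn))

        got = predict_rates(MotionalParams(model_id=1, S2=1.0, tau_m=5.67), cfg)
        assert got[0] == pytest.approx(r1, rel=1e-6)
        assert got[1] == pytest.approx(r2, rel=1e-6)
        assert got[2] == pytest.approx(noe, rel=1e-6)
        assert got[1] / got[0] == pytest.approx(r2 / r1, rel=1e-6)

    def test_extreme_narrowing_noe_limit(self, cfg):
        """For τm → 0 all J(ω) coincide and the NOE has a closed form."""
        d2, c2 = cfg.d2, cfg.c2
        expected = 1.0 + (cfg.gamma_h / cfg.gamma_n) * (5 * d2 / 4) / (10 * d2 / 4 + c2)
        _, _, noe = predict_rates(MotionalParams(model_id=1, S2=1.0, tau_m=1e-4), cfg)
        assert noe == pytest.approx(expected, rel=1e-3)

    def test_slow_tumbling_keeps_r2_above_r1(self, cfg):
        for tau_m in (1.0, 2.0, 5.67, 12.0):
            r1, r2, _ = predict_rates(MotionalParams(model_id=1, S2=0.9, tau_m=tau_m), cfg)
            assert r2 >= r1


class TestDecayFit:
    def test_exact_recovery_at_standard_delays(self):
        series = DecaySeries(T1_DELAYS, tuple(100.0 * math.exp(-10.0 * t) for t in T1_DELAYS), 1e-6)
        fit = fit_decay(series)
        assert fit.rate == pytest.approx(10.0, abs=1e-6)
        assert not fit.flagged

    def test_monte_carlo_mean_recovery(self):
        # rate chosen so the longest delay still carries signal; at much
        # faster decays the tail points are pure noise and the usual O(σ²)
        # nonlinear-fit bias dominates the SE of the mean
        rng = np.random.default_rng(12)
        rate_true = 0.8
        rates = []
        for _ in range(200):
            clean = np.array([100.0 * math.exp(-rate_true * t) for t in T1_DELAYS])
            noisy = clean + rng.normal(0, 1.0, size=clean.size)  # 1 % of I0
            fit = fit_decay(DecaySeries(T1_DELAYS, tuple(noisy), 1.0))
            rates.append(fit.rate)
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(mean - rate_true) < 2 * se

    def test_constant_intensities_flagged(self):
        fit = fit_decay(DecaySeries((0.1, 1.0, 2.0, 4.0), (50.0, 50.0, 50.0, 50.0), 0.5))
        assert fit.flagged

    def test_too_few_distinct_delays_rejected(self):
        with pytest.raises(ValueError):
            DecaySeries((1.0, 1.0, 1.0), (3.0, 2.0, 1.0), 0.1)


class TestNoeRatio:
    @pytest.mark.parametrize("sat,ref,expected", [(5.0, 5.0, 1.0), (0.78, 1.0, 0.78),
                                                  (-0.4, 1.0, -0.4)])
    def test_ratio(self, sat, ref, expected):
        assert noe_ratio(sat, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            noe_ratio(1.0, 0.0)


def record_from(params, cfg, frac=0.02, res_seq=1, rng=None):
    r1, r2, noe = predict_rates(params, cfg)
    s1, s2, sn = frac * r1, frac * r2, frac * max(abs(noe), 1.0)
    if rng is not None:
        r1, r2, noe = (r1 + rng.normal(0, s1), r2 + rng.normal(0, s2),
                       noe + rng.normal(0, sn))
    return RelaxationRecord(res_seq, r1, r2, noe, s1, s2, sn)


class TestFitModel:
    def test_noiseless_model1_recovers_order_parameter(self, cfg):
        rec = record_from(MotionalParams(model_id=1, S2=0.85, tau_m=5.67), cfg)
        res = fit_model(rec, 1, 5.67, cfg)
        assert res.params.S2 == pytest.approx(0.85, abs=1e-3)
        assert res.chi2 < 1e-10
        assert res.dof == 2

    def test_optimizer_at_least_as_good_as_brute_grid(self, cfg):
        """Model-2 χ² from the optimiser must not exceed a vectorised
        brute-force scan over (S², τe)."""
        rng = np.random.default_rng(3)
        rec = record_from(MotionalParams(model_id=2, S2=0.7, tau_m=5.67, tau_e=200.0),
                          cfg, rng=rng)
        res = fit_model(rec, 2, 5.67, cfg)

        s2 = np.linspace(0, 1, 1001)
        te = np.linspace(0, 2000.0, 801)
        S2, TE = np.meshgrid(s2, te, indexing="ij")
        tau_m = 5.67e-9
        tau_e = TE * 1e-12
        tau = np.where(tau_e > 0, tau_m * tau_e / (tau_m + tau_e), 0.0)

        def j(w):
            out = S2 * tau_m / (1 + (w * tau_m) ** 2)
            return 0.4 * (out + (1 - S2) * tau / (1 + (w * tau) ** 2))

        wh, wn = cfg.omega_h, cfg.omega_n
        d2, c2 = cfg.d2, cfg.c2
        jhmn, jn, jhpn, j0, jh = (j(abs(w)) for w in (wh - wn, wn, wh + wn, 0.0, wh))
        r1 = (d2 / 4) * (jhmn + 3 * jn + 6 * jhpn) + c2 * jn
        r2 = (d2 / 8) * (4 * j0 + jhmn + 3 * jn + 6 * jh + 6 * jhpn) + (c2 / 6) * (
            4 * j0 + 3 * jn)
        noe = 1 + (d2 / (4 * np.maximum(r1, 1e-30))) * (
            cfg.gamma_h / cfg.gamma_n) * (6 * jhpn - jhmn)
        chi2_grid = (((rec.R1 - r1) / rec.sigma_R1) ** 2
                     + ((rec.R2 - r2) / rec.sigma_R2) ** 2
                     + ((rec.NOE - noe) / rec.sigma_NOE) ** 2)
        assert res.chi2 <= chi2_grid.min() + 1e-6

    def test_model4_parameter_recovery_over_replicates(self, cfg):
        truth = MotionalParams(model_id=4, S2=0.80, tau_m=5.67, tau_e=50.0, R_ex=2.0)
        rng = np.random.default_rng(7)
        s2s, rexs = [], []
        for i in range(30):
            rec = record_from(truth, cfg, rng=rng, res_seq=i)
            res = fit_model(rec, 4, 5.67, cfg)
            s2s.append(res.params.S2)
            rexs.append(res.params.R_ex)
        assert np.median(s2s) == pytest.approx(0.80, abs=0.02)
        assert np.median(rexs) == pytest.approx(2.0, abs=0.5)


class TestSelectModel:
    def test_rigid_residue_selects_simplest_model(self, cfg):
        rec = record_from(MotionalParams(model_id=1, S2=0.85, tau_m=5.67), cfg)
        res = select_model(rec, 5.67, cfg, seed=0)
        assert res.params.model_id == 1
        assert res.chi2 < 1e-8

    def test_noiseless_generating_model_or_simpler_is_returned(self, cfg):
        for truth in (
            MotionalParams(model_id=2, S2=0.84, tau_m=5.67, tau_e=40.0),
            MotionalParams(model_id=3, S2=0.82, tau_m=5.67, R_ex=4.0),
        ):
            rec = record_from(truth, cfg)
            res = select_model(rec, 5.67, cfg, seed=1)
            assert res.params.model_id <= truth.model_id
            assert res.chi2 < 1e-6

    def test_large_exchange_never_fits_simple_family(self, cfg):
        truth = MotionalParams(model_id=3, S2=0.82, tau_m=5.67, R_ex=8.0)
        rng = np.random.default_rng(21)
        for i in range(6):
            rec = record_from(truth, cfg, rng=rng, res_seq=i)
            res = select_model(rec, 5.67, cfg, n_mc=200, seed=i)
            assert res.params is not None
            assert res.params.model_id in (3, 4)

    def test_infeasible_rates_assign_no_model(self, cfg):
        # R2 far beyond anything reachable even with the R_ex bound
        rec = RelaxationRecord(99, R1=2.0, R2=100.0, NOE=0.8,
                               sigma_R1=0.02, sigma_R2=0.5, sigma_NOE=0.02)
        res = select_model(rec, 5.67, cfg, n_mc=100, seed=2)
        assert res.params is None
        assert "no_model" in res.flags
        assert set(res.selection_trace) == {1, 2, 3, 4, 5}


class TestMcErrors:
    def test_deterministic_for_fixed_seed(self, cfg):
        rng = np.random.default_rng(30)
        rec = record_from(MotionalParams(model_id=2, S2=0.8, tau_m=5.67, tau_e=100.0),
                          cfg, rng=rng)
        res = fit_model(rec, 2, 5.67, cfg)
        e1 = mc_errors(res, rec, 5.67, cfg, n_draws=100, seed=5)
        e2 = mc_errors(res, rec, 5.67, cfg, n_draws=100, seed=5)
        assert e1 == e2
        assert set(e1) == {"S2", "tau_e"}

    def test_error_scales_with_noise(self, cfg):
        truth = MotionalParams(model_id=1, S2=0.85, tau_m=5.67)
        rec1 = record_from(truth, cfg, frac=0.02)
        rec2 = record_from(truth, cfg, frac=0.04)
        res1 = fit_model(rec1, 1, 5.67, cfg)
        res2 = fit_model(rec2, 1, 5.67, cfg)
        se1 = mc_errors(res1, rec1, 5.67, cfg, n_draws=200, seed=6)["S2"]
        se2 = mc_errors(res2, rec2, 5.67, cfg, n_draws=200, seed=6)["S2"]
        assert se2 / se1 == pytest.approx(2.0, rel=0.3)

    def test_small_draw_count_warns(self, cfg):
        rec = record_from(MotionalParams(model_id=1, S2=0.85, tau_m=5.67), cfg)
        res = fit_model(rec, 1, 5.67, cfg)
        with pytest.warns(UserWarning):
            mc_errors(res, rec, 5.67, cfg, n_draws=49, seed=0)


class TestParamInvariants:
    def test_model_constraints_enforced(self):
        with pytest.raises(ValueError):
            MotionalParams(model_id=1, S2=0.8, tau_m=5.0, tau_e=10.0)
        with pytest.raises(ValueError):
            MotionalParams(model_id=5, S2=0.9, S2_f=0.8, tau_m=5.0, tau_e=10.0)
        with pytest.raises(ValueError):
            MotionalParams(model_id=2, S2=1.2, tau_m=5.0)

    def test_record_requires_positive_rates_and_errors(self):
        with pytest.raises(ValueError):
            RelaxationRecord(1, -1.0, 8.0, 0.8, 0.1, 0.1, 0.02)
        with pytest.raises(ValueError):
            RelaxationRecord(1, 2.0, 8.0, 0.8, 0.0, 0.1, 0.02)
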