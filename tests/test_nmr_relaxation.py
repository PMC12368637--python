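"""15N relaxation: forward model, rate fitting, tauC/tauR, SDM, exchange."""

import math

import numpy as np
import pytest

from bindkit import nmr_relaxation as nmr
from bindkit.nmr_relaxation import (
    R1_DELAYS_S,
    R2_DELAYS_S,
    ExchangeTwoState,
    FieldContext,
    ModelFreeParams,
    RelaxationRateSet,
)
from bindkit.synthetic_data import NoiseSpec, gen_relaxation_decays


def oracle_rates(tau_r, s2, tau_e, rex, b0, r_nh=1.02e-10, dsigma_ppm=-172.0):
    """Independent second implementation of the dipolar+CSA rates,
    written from the closed forms with its own constants and structure."""
    gh, gn = 2.6752219e8, -2.7126e7
    hbar, mu0_4pi = 1.054571817e-34, 1e-7
    wh, wn = gh * b0, gn * b0
    tau_p = tau_r if tau_e == 0 else tau_r * tau_e / (tau_r + tau_e)

    def j(w):
        w = abs(w)
        val = s2 * tau_r / (1 + (w * tau_r) ** 2)
        if s2 < 1 and tau_e > 0:
            val += (1 - s2) * tau_p / (1 + (w * tau_p) ** 2)
        return 0.4 * val

    d = mu0_4pi * hbar * gh * gn / r_nh**3
    c = wn * dsigma_ppm * 1e-6 / 3**0.5
    r1 = d * d / 4 * (j(wh - wn) + 3 * j(wn) + 6 * j(wh + wn)) + c * c * j(wn)
    r2 = (
        d * d / 8 * (4 * j(0) + j(wh - wn) + 3 * j(wn) + 6 * j(wh) + 6 * j(wh + wn))
        + c * c / 6 * (4 * j(0) + 3 * j(wn))
        + rex
    )
    noe = 1 + d * d / (4 * r1) * (gh / gn) * (6 * j(wh + wn) - j(wh - wn))
    return r1, r2, noe


class TestForwardRates:
    def test_rigid_limit_j0(self):
        p = ModelFreeParams(tau_r_s=5e-9, s2=1.0)
        assert nmr.spectral_density(0.0, p) == pytest.approx(2.0e-9, rel=1e-12)

    def test_extreme_narrowing_ratio(self):
        # R2/R1 -> 1 exactly in the dipolar-only extreme-narrowing limit;
        # CSA shifts the flat-J ratio to (2.5 d^2 + 7c^2/6)/(2.5 d^2 + c^2)
        p = ModelFreeParams(tau_r_s=1e-12, s2=1.0)
        dipolar_only = FieldContext(b0_t=18.8, delta_sigma_n_ppm=0.0)
        r1, r2, _ = nmr.forward_rates(p, dipolar_only)
        assert r2 / r1 == pytest.approx(1.0, rel=1e-6)
        r1c, r2c, _ = nmr.forward_rates(p, FieldContext(b0_t=18.8))
        assert r2c / r1c == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize("b0", [11.7, 18.8])
    @pytest.mark.parametrize(
        "tau_r,s2,tau_e,rex",
        [(7.45e-9, 0.85, 50e-12, 0.0), (4e-9, 1.0, 0.0, 0.0), (12e-9, 0.7, 30e-12, 3.0)],
    )
    def test_matches_independent_implementation(self, b0, tau_r, s2, tau_e, rex):
        field = FieldContext(b0_t=b0)
        got = nmr.forward_rates(
            ModelFreeParams(tau_r_s=tau_r, s2=s2, tau_e_s=tau_e, rex_s1=rex), field
        )
        expected = oracle_rates(tau_r, s2, tau_e, rex, b0)
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, rel=1e-10)

    def test_rigid_noe_realistic_at_high_field(self, field_188):
        # rigid backbone amides at 18.8 T sit in the 0.8-0.9 NOE range
        _, _, noe = nmr.forward_rates(ModelFreeParams(tau_r_s=7.45e-9, s2=1.0), field_188)
        assert 0.8 < noe < 0.9

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelFreeParams(tau_r_s=-1e-9)
        with pytest.raises(ValueError):
            ModelFreeParams(tau_r_s=1e-9, s2=1.2)
        with pytest.raises(ValueError):
            ModelFreeParams(tau_r_s=1e-9, tau_e_s=2e-9)


class TestExponentialFit:
    def test_noiseless_r1_recovery_at_printed_delays(self):
        t = np.array(R1_DELAYS_S)
        fit = nmr.fit_exponential_rate(t, np.exp(-1.081 * t), n_mc=0)
        assert fit.rate_s1 == pytest.approx(1.081, rel=1e-6)
        assert fit.rate_sigma_s1 == 0.0

    def test_constant_amplitudes_give_zero_rate(self):
        fit = nmr.fit_exponential_rate(np.array(R2_DELAYS_S), np.full(8, 2.5), n_mc=0)
        assert fit.rate_s1 == pytest.approx(0.0, abs=1e-10)

    def test_mc_sigma_tracks_analytic_linearized_error(self):
        # oracle: variance of the slope of a weighted linear fit of
        # log-amplitudes, weights A_i^2/sigma^2
        rate, sigma = 1.081, 0.02
        t = np.array(R1_DELAYS_S)
        amps_clean = np.exp(-rate * t)
        rng = np.random.default_rng(11)
        amps = amps_clean + rng.normal(0, sigma, t.size)
        fit = nmr.fit_exponential_rate(t, amps, n_mc=200, seed=11, noise_sigma=sigma)
        w = amps_clean**2 / sigma**2
        tbar = np.sum(w * t) / np.sum(w)
        var_slope = 1.0 / np.sum(w * (t - tbar) ** 2)
        analytic = math.sqrt(var_slope)
        assert analytic / 2 < fit.rate_sigma_s1 < analytic * 2

    def test_mc_sigma_seed_reproducible_and_scales_with_noise(self):
        t = np.array(R1_DELAYS_S)
        amps = np.exp(-1.081 * t)
        sigmas = []
        for scale in (0.005, 0.01, 0.02):
            a = nmr.fit_exponential_rate(t, amps, n_mc=100, seed=3, noise_sigma=scale)
            b = nmr.fit_exponential_rate(t, amps, n_mc=100, seed=3, noise_sigma=scale)
            assert a.rate_sigma_s1 == b.rate_sigma_s1
            sigmas.append(a.rate_sigma_s1)
        assert sigmas[0] < sigmas[1] < sigmas[2]
        # roughly linear growth
        assert sigmas[2] / sigmas[0] == pytest.approx(4.0, rel=0.5)


class TestNOE:
    def test_equal_amplitudes(self):
        assert nmr.compute_noe(2.0, 2.0) == (1.0, 0.0)

    def test_error_propagation_matches_monte_carlo(self):
        noe, sigma = nmr.compute_noe(0.8, 1.0, 0.01, 0.01)
        assert noe == 0.8
        rng = np.random.default_rng(0)
        mc = rng.normal(0.8, 0.01, 100_000) / rng.normal(1.0, 0.01, 100_000)
        assert sigma == pytest.approx(mc.std(), rel=0.05)
        assert sigma == pytest.approx(0.0128, abs=2e-4)

    def test_zero_reference_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            nmr.compute_noe(0.5, 0.0)


class TestTauC:
    def test_validity_bound(self, field_188):
        assert nmr.tauc_from_ratio(7.0, 6.0, field_188) == 0.0
        assert math.isnan(nmr.tauc_from_ratio(1.0, 1.0, field_188))

    def test_round_trip_high_field(self, field_188):
        r1, r2, _ = nmr.forward_rates(ModelFreeParams(tau_r_s=8e-9, s2=1.0), field_188)
        assert nmr.tauc_from_ratio(r2, r1, field_188) == pytest.approx(8e-9, rel=0.05)

    def test_exact_in_slow_tumbling_limit(self, field_188):
        r1, r2, _ = nmr.forward_rates(ModelFreeParams(tau_r_s=50e-9, s2=1.0), field_188)
        assert nmr.tauc_from_ratio(r2, r1, field_188) == pytest.approx(50e-9, rel=0.01)

    def test_exchange_inflates_apparent_tauc(self, field_188):
        p0 = ModelFreeParams(tau_r_s=8e-9, s2=0.85, tau_e_s=20e-12)
        pex = ModelFreeParams(tau_r_s=8e-9, s2=0.85, tau_e_s=20e-12, rex_s1=5.0)
        r1a, r2a, _ = nmr.forward_rates(p0, field_188)
        r1b, r2b, _ = nmr.forward_rates(pex, field_188)
        assert nmr.tauc_from_ratio(r2b, r1b, field_188) > nmr.tauc_from_ratio(
            r2a, r1a, field_188
        )


def _rate_set(params_by_residue, field):
    rows = [nmr.forward_rates(p, field) for p in params_by_residue]
    r1, r2, noe = map(np.array, zip(*rows))
    return RelaxationRateSet(
        residues=np.arange(1, len(rows) + 1), r1=r1, r2=r2, noe=noe
    )


class TestOverallTauR:
    def test_uniform_residues_recover_single_tauc(self, field_188, rigid_params):
        rates = _rate_set([rigid_params] * 50, field_188)
        mean, sem, n = nmr.overall_tau_r(rates, field_188)
        assert n == 50
        assert sem == pytest.approx(0.0, abs=1e-15)
        expected = nmr.tauc_from_ratio(rates.r2[0], rates.r1[0], field_188)
        assert mean == pytest.approx(expected, rel=1e-12)

    def test_low_noe_residue_excluded(self, field_188, rigid_params):
        rates = _rate_set([rigid_params] * 20, field_188)
        mean_ref, _, _ = nmr.overall_tau_r(rates, field_188)
        noe = rates.noe.copy()
        noe[7] = 0.5
        floppy = RelaxationRateSet(rates.residues, rates.r1, rates.r2, noe)
        mean, _, n = nmr.overall_tau_r(floppy, field_188)
        assert n == 19
        assert mean == pytest.approx(mean_ref, rel=1e-12)

    def test_mask_restricts_selection(self, field_188, rigid_params):
        rates = _rate_set([rigid_params] * 20, field_188)
        _, _, n = nmr.overall_tau_r(rates, field_188, mask=set(range(1, 11)))
        assert n == 10

    def test_trimmed_mean_resists_exchange_outliers(self, field_188):
        rigid = nmr.ModelFreeParams(tau_r_s=7.45e-9, s2=0.85, tau_e_s=20e-12)
        exch = nmr.ModelFreeParams(tau_r_s=7.45e-9, s2=0.85, tau_e_s=20e-12, rex_s1=8.0)
        params = [exch if i % 10 == 0 else rigid for i in range(50)]
        rates = _rate_set(params, field_188)
        clean = _rate_set([rigid] * 50, field_188)
        base, _, _ = nmr.overall_tau_r(clean, field_188)
        plain, _, _ = nmr.overall_tau_r(rates, field_188)
        trimmed, _, _ = nmr.overall_tau_r(rates, field_188, trim_fraction=0.1)
        assert plain > base
        assert abs(trimmed - base) < abs(plain - base)

    def test_structured_mask_fixture_loads(self):
        mask = nmr.load_structured_mask()
        assert len(mask) > 30
        assert all(isinstance(r, int) for r in mask)


class TestReducedSDM:
    @pytest.mark.parametrize("b0", [11.7, 18.8])
    @pytest.mark.parametrize("tau_r", [4e-9, 8e-9, 12e-9])
    @pytest.mark.parametrize("s2", [0.7, 0.85, 1.0])
    def test_forward_inverse_round_trip(self, b0, tau_r, s2):
        field = FieldContext(b0_t=b0)
        p = ModelFreeParams(tau_r_s=tau_r, s2=s2, tau_e_s=20e-12 if s2 < 1 else 0.0)
        r1, r2, noe = nmr.forward_rates(p, field)
        triple = nmr.reduced_sdm(r1, r2, noe, field)
        assert triple.j0 == pytest.approx(nmr.spectral_density(0.0, p), rel=0.05)
        assert triple.j_wn == pytest.approx(
            nmr.spectral_density(field.omega_n, p), rel=0.05
        )
        assert triple.j_wh087 == pytest.approx(
            nmr.spectral_density(0.87 * field.omega_h, p), rel=0.15
        )

    def test_monotone_ordering_on_model_data(self, field_188, rigid_params):
        r1, r2, noe = nmr.forward_rates(rigid_params, field_188)
        t = nmr.reduced_sdm(r1, r2, noe, field_188)
        assert t.j0 >= t.j_wn >= t.j_wh087 >= 0

    def test_exchange_only_inflates_j0(self, field_188, rigid_params):
        r1, r2, noe = nmr.forward_rates(rigid_params, field_188)
        base = nmr.reduced_sdm(r1, r2, noe, field_188)
        exch = nmr.reduced_sdm(r1, r2 + 5.0, noe, field_188)
        assert exch.j0 > base.j0
        assert exch.j_wn == pytest.approx(base.j_wn, rel=1e-12)
        assert exch.j_wh087 == pytest.approx(base.j_wh087, rel=1e-12)

    def test_unit_noe_zeroes_high_frequency_density(self, field_188):
        t = nmr.reduced_sdm(1.0, 10.0, 1.0, field_188)
        assert t.j_wh087 == 0.0

    def test_uncertainty_propagation_positive(self, field_188, rigid_params):
        r1, r2, noe = nmr.forward_rates(rigid_params, field_188)
        t = nmr.reduced_sdm(r1, r2, noe, field_188, 0.05, 0.3, 0.02)
        assert t.j0_err > 0 and t.j_wn_err > 0 and t.j_wh087_err > 0


class TestExchangePopulation:
    def test_linear_mixing_reproduces_four_percent(self):
        p = nmr.exchange_population(ExchangeTwoState(7.45e-9, 41e-9, 8.79e-9))
        assert round(100 * p) == 4
        assert p == pytest.approx(0.040, abs=5e-4)

    def test_inverse_rate_convention_value(self):
        p = nmr.exchange_population(
            ExchangeTwoState(7.45e-9, 41e-9, 8.79e-9, convention="inverse_rate")
        )
        # oracle: algebraic solve of 1/tau_obs = (1-p)/tau_f + p/tau_b
        tf, tb, to = 7.45e-9, 41e-9, 8.79e-9
        expected = (1 / tf - 1 / to) / (1 / tf - 1 / tb)
        assert p == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(0.186, abs=1e-3)

    def test_no_shift_means_no_binding(self):
        for conv in ("linear_tau", "inverse_rate"):
            m = ExchangeTwoState(7.45e-9, 41e-9, 7.45e-9, convention=conv)
            assert nmr.exchange_population(m) == pytest.approx(0.0, abs=1e-15)

    def test_small_p_limit_slope_ratio(self):
        # both conventions are linear in (tau_obs - tau_f) near zero; the
        # slope ratio is tau_b/tau_f, so they agree only when the bound
        # and free correlation times are similar
        tf, tb = 7.45e-9, 41e-9
        to = tf * 1.0001
        lin = nmr.exchange_population(ExchangeTwoState(tf, tb, to))
        inv = nmr.exchange_population(ExchangeTwoState(tf, tb, to, convention="inverse_rate"))
        assert inv / lin == pytest.approx(tb / tf, rel=1e-3)
        tb_close = tf * 1.05
        lin2 = nmr.exchange_population(ExchangeTwoState(tf, tb_close, tf * 1.001))
        inv2 = nmr.exchange_population(
            ExchangeTwoState(tf, tb_close, tf * 1.001, convention="inverse_rate")
        )
        assert abs(inv2 - lin2) / lin2 < 0.10

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolat"):
            nmr.exchange_population(ExchangeTwoState(7.45e-9, 41e-9, 5e-9))


class TestCSP:
    def test_identical_states_zero(self):
        dh = np.array([8.1, 8.3]); dn = np.array([118.0, 121.5])
        assert nmr.csp(dh, dn, dh, dn) == pytest.approx([0.0, 0.0])

    def test_composite_arithmetic(self):
        d = nmr.csp([8.0], [120.0], [8.01], [120.1])
        assert d[0] == pytest.approx(math.sqrt(0.01**2 + (0.14 * 0.1) ** 2), rel=1e-12)
        assert d[0] == pytest.approx(0.0172, abs=1e-4)

    def test_outlier_report(self):
        deltas = np.array([0.01, 0.012, 0.011, 0.013, 0.20])
        assert nmr.csp_outliers(deltas).tolist() == [4]


class TestRateTableFit:
    def test_noiseless_round_trip_to_forward_rates(self, field_188, rigid_params):
        table, noe_pairs = gen_relaxation_decays(
            rigid_params, field_188, residues=[1, 2, 3]
        )
        rates = nmr.fit_rates_from_table(table, n_mc=0)
        r1, r2, noe = nmr.forward_rates(rigid_params, field_188)
        assert rates["R1_s1"].to_numpy() == pytest.approx(r1, rel=1e-6)
        assert rates["R2_s1"].to_numpy() == pytest.approx(r2, rel=1e-6)
        ratios = noe_pairs["I_sat"] / noe_pairs["I_ref"]
        assert ratios.to_numpy() == pytest.approx(noe, rel=1e-12)
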