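"""Transition algebra, emission density, forward algorithm, priors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

import driftswitch as ds
from driftswitch.data import preset_spec
from driftswitch.params import ParameterSet, TransitionModel
from driftswitch.priors import get_profile, log_prior

from conftest import brute_force_loglik


def sim1_transitions():
    return TransitionModel(alpha0=np.array([[0.0, -0.5], [-0.5, 0.0]]),
                           alpha1=np.array([[0.0, 1.0], [-1.0, 0.0]]))


class TestTransitionProbs:
    def test_printed_probabilities_frequent_switching(self):
        tm = sim1_transitions()
        p0 = ds.transition_probs(tm, 0.0)
        assert round(p0[0, 1], 2) == 0.38      # 1 -> 2
        assert round(p0[0, 0], 2) == 0.62      # stay in 1
        assert round(p0[1, 0], 2) == 0.38      # 2 -> 1
        p1 = ds.transition_probs(tm, 1.0)
        assert round(p1[0, 1], 2) == 0.62      # treated, intervention
        assert round(p1[1, 0], 2) == 0.18

    def test_all_zero_coefficients_give_uniform_rows(self):
        tm = TransitionModel(np.zeros((3, 3)), np.zeros((3, 3)))
        np.testing.assert_allclose(ds.transition_probs(tm, 0.7),
                                   np.full((3, 3), 1 / 3))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(2, 4), st.integers(0, 10_000), st.floats(-3, 3))
    def test_rows_sum_to_one(self, S, seed, cov):
        rng = np.random.default_rng(seed)
        a0 = rng.normal(0, 2, (S, S))
        a1 = rng.normal(0, 2, (S, S))
        np.fill_diagonal(a0, 0.0)
        np.fill_diagonal(a1, 0.0)
        p = ds.transition_probs(TransitionModel(a0, a1), cov)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p >= 0).all()

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            TransitionModel(np.array([[0.1, 0.0], [0.0, 0.0]]), np.zeros((2, 2)))


class TestEmission:
    def test_standard_normal_closed_form(self):
        params = ParameterSet(phi0=0.0)
        val = ds.emission_logdensity(params, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0)
        assert val == pytest.approx(-0.9189385, abs=1e-6)

    def test_mean_shift_invariance(self):
        params = ParameterSet()
        rng = np.random.default_rng(0)
        for _ in range(20):
            y_t, y_tm1, mu_t, mu_tm1, phi = rng.normal(size=5)
            iiv = rng.uniform(0.2, 3.0)
            c = rng.normal() * 10
            a = ds.emission_logdensity(params, y_t, y_tm1, mu_t, mu_tm1, iiv, phi)
            b = ds.emission_logdensity(params, y_t + c, y_tm1 + c,
                                       mu_t + c, mu_tm1 + c, iiv, phi)
            assert a == pytest.approx(b, abs=1e-10)

    def test_gradient_in_phi_matches_finite_differences(self):
        params = ParameterSet()
        rng = np.random.default_rng(1)
        for _ in range(10):
            y_t, y_tm1, mu_t, mu_tm1 = rng.normal(size=4)
            iiv = rng.uniform(0.3, 2.0)
            phi = rng.uniform(-0.8, 0.8)
            h = 1e-6
            num = (ds.emission_logdensity(params, y_t, y_tm1, mu_t, mu_tm1, iiv, phi + h)
                   - ds.emission_logdensity(params, y_t, y_tm1, mu_t, mu_tm1, iiv, phi - h)) / (2 * h)
            resid = y_t - (mu_t + phi * (y_tm1 - mu_tm1))
            analytic = resid * (y_tm1 - mu_tm1) / iiv
            assert num == pytest.approx(analytic, rel=1e-4, abs=1e-6)

    def test_nonpositive_iiv_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ds.emission_logdensity(ParameterSet(), 0, 0, 0, 0, 0.0, 0.3)


def _random_case(rng, S, T, kind):
    """Build a random spec/params/latents/data quadruple for oracle checks."""
    baseline = "GCM+RS" if kind in ("baseline", "both") else "GCM"
    iiv = "RS" if kind in ("iiv", "both") else "constant"
    rs_target = tuple(
        t for t, on in (("baseline", baseline == "GCM+RS"), ("iiv", iiv == "RS"))
        if on)
    re = {"sigma_delta_mu": baseline == "GCM+RS", "sigma_delta_iiv": iiv == "RS"}
    spec = ds.ModelSpec(baseline_component=baseline, iiv_component=iiv,
                        n_regimes=S, rs_target=rs_target, random_effects=re)
    a0 = rng.normal(0, 1, (S, S))
    a1 = rng.normal(0, 1, (S, S))
    np.fill_diagonal(a0, 0)
    np.fill_diagonal(a1, 0)
    dmu = np.concatenate([[0.0], np.sort(rng.uniform(0.5, 3.0, S - 1))])
    div = np.concatenate([[0.0], np.sort(rng.uniform(0.2, 1.5, S - 1))])
    pi = rng.dirichlet(np.ones(S))
    params = ParameterSet(
        phi0=rng.uniform(-0.6, 0.6), iiv0=rng.uniform(0.3, 1.2),
        beta00=rng.normal(), beta10=rng.normal(scale=0.3),
        betaIIV00=rng.normal(scale=0.4),
        delta_mu=dmu if baseline == "GCM+RS" else np.zeros(S),
        sigma_delta_mu=np.zeros(S),
        delta_iiv=div if iiv == "RS" else np.zeros(S),
        sigma_delta_iiv=np.zeros(S),
        alpha0=a0, alpha1=a1, pi_init=pi)
    zeta_mu = np.concatenate([[0.0], rng.normal(0, 0.3, S - 1)])
    zeta_iiv = np.concatenate([[0.0], rng.normal(0, 0.2, S - 1)])
    latents = {"b0": rng.normal(), "zeta_mu": zeta_mu, "zeta_iiv": zeta_iiv}
    y = rng.normal(0, 1.5, T)
    if T >= 5:
        y[rng.integers(1, T)] = np.nan  # exercise the missing-data path
    period = np.minimum(np.arange(T) // max(T // 4, 1), 3).astype(float)
    x = (np.arange(T) >= T / 2).astype(float)
    data = {"y": y, "period": period, "covariate": x}
    return spec, params, latents, data


def _oracle_inputs(spec, params, latents, data):
    T = len(data["y"])
    S = spec.n_regimes
    base = latents["b0"] + params.beta10 * data["period"]
    mu = np.repeat(base[:, None], S, axis=1)
    if spec.baseline_component.endswith("+RS"):
        mu = mu + (params.delta_mu + latents["zeta_mu"])[None, :]
    if spec.iiv_component == "RS":
        logvar = np.broadcast_to(
            params.betaIIV00 + (params.delta_iiv + latents["zeta_iiv"])[None, :],
            (T, S)).copy()
    else:
        logvar = np.full((T, S), 2 * math.log(params.iiv0))
    return mu, logvar


class TestForwardAlgorithm:
    @pytest.mark.parametrize("kind", ["baseline", "iiv", "both"])
    @pytest.mark.parametrize("S", [2, 3])
    def test_matches_exhaustive_enumeration(self, kind, S):
        rng = np.random.default_rng(hash((kind, S)) % (2**31))
        for rep in range(6):
            T = int(rng.integers(3, 9))
            spec, params, latents, data = _random_case(rng, S, T, kind)
            got = ds.forward_loglik(spec, params, latents, data)
            mu, logvar = _oracle_inputs(spec, params, latents, data)
            want = brute_force_loglik(data["y"], mu, logvar, params.phi0,
                                      params.alpha0, params.alpha1,
                                      data["covariate"], params.pi_init)
            assert got == pytest.approx(want, abs=1e-8)

    def test_zero_deviations_reduce_to_single_regime(self):
        rng = np.random.default_rng(5)
        spec, params, latents, data = _random_case(rng, 2, 8, "baseline")
        params0 = params.replace(delta_mu=np.zeros(2))
        latents0 = dict(latents, zeta_mu=np.zeros(2))
        ll_rs = ds.forward_loglik(spec, params0, latents0, data)
        spec1 = ds.preset_spec("GCM")
        params1 = params0.replace(delta_mu=np.zeros(1),
                                  sigma_delta_mu=np.zeros(1),
                                  delta_iiv=np.zeros(1),
                                  sigma_delta_iiv=np.zeros(1),
                                  alpha0=np.zeros((1, 1)),
                                  alpha1=np.zeros((1, 1)),
                                  pi_init=np.ones(1))
        ll_1 = ds.forward_loglik(spec1, params1, {"b0": latents["b0"]}, data)
        assert ll_rs == pytest.approx(ll_1, abs=1e-10)

    def test_degenerate_chain_in_regime_one(self):
        """pi = (1, 0) with a near-identity chain equals the single-regime
        likelihood evaluated in regime 1."""
        rng = np.random.default_rng(6)
        spec, params, latents, data = _random_case(rng, 2, 7, "baseline")
        frozen = params.replace(
            pi_init=np.array([1.0, 0.0]),
            alpha0=np.array([[0.0, -40.0], [-40.0, 0.0]]),
            alpha1=np.zeros((2, 2)))
        ll = ds.forward_loglik(spec, frozen, latents, data)
        spec1 = ds.preset_spec("GCM")
        params1 = ParameterSet(phi0=params.phi0, iiv0=params.iiv0,
                               beta00=params.beta00, beta10=params.beta10)
        ll1 = ds.forward_loglik(spec1, params1, {"b0": latents["b0"]}, data)
        assert ll == pytest.approx(ll1, abs=1e-8)

    def test_relabeling_invariance(self):
        """Swapping regime labels together with their parameters leaves the
        marginal likelihood unchanged."""
        rng = np.random.default_rng(7)
        spec, params, latents, data = _random_case(rng, 2, 7, "both")
        perm = [1, 0]
        mu_eff = params.delta_mu + latents["zeta_mu"]
        iiv_eff = params.betaIIV00 + params.delta_iiv + latents["zeta_iiv"]
        ll = ds.forward_loglik(spec, params, latents, data)
        # relabelled system, expressed through the regime-2 reference shift
        swapped = params.replace(
            delta_mu=np.array([0.0, -mu_eff[1]]),
            delta_iiv=np.array([0.0, iiv_eff[0] - iiv_eff[1]]),
            betaIIV00=iiv_eff[1],
            alpha0=params.alpha0[np.ix_(perm, perm)].copy(),
            alpha1=params.alpha1[np.ix_(perm, perm)].copy(),
            pi_init=params.pi_init[perm].copy())
        lat_sw = {"b0": latents["b0"] + mu_eff[1],
                  "zeta_mu": np.zeros(2), "zeta_iiv": np.zeros(2)}
        ll_sw = ds.forward_loglik(spec, swapped, lat_sw, data)
        assert ll == pytest.approx(ll_sw, abs=1e-8)

    def test_monotone_in_outlier_distance(self):
        """Pushing the final observation ever further beyond every regime
        mean strictly lowers the marginal likelihood (unimodal emissions;
        the last time point feeds no AR prediction downstream)."""
        rng = np.random.default_rng(8)
        spec, params, latents, data = _random_case(rng, 2, 6, "baseline")
        data["y"] = np.nan_to_num(data["y"], nan=0.1)
        lls = []
        for bump in (10.0, 20.0, 40.0, 80.0):
            d = dict(data)
            y = d["y"].copy()
            y[-1] = bump
            d["y"] = y
            lls.append(ds.forward_loglik(spec, params, latents, d))
        assert all(a > b for a, b in zip(lls, lls[1:]))


class TestLogPrior:
    def test_truncated_normal_mode_matches_numerical_integration(self):
        prof = get_profile("simulation")
        spec = preset_spec("GCM")
        params = ParameterSet(phi0=0.0, iiv0=0.5, beta00=0.0,
                              sigma_beta0=0.2, beta10=0.5)
        norm = integrate.quad(
            lambda z: stats.norm.pdf(z, 0, 1), -1, 1)[0]
        expected_phi = math.log(stats.norm.pdf(0.0) / norm)
        single = [fp for fp in ds.free_parameters(spec, prof)
                  if fp.name == "phi0"][0]
        assert single.prior.logpdf(0.0) == pytest.approx(expected_phi, abs=1e-8)
        assert np.isfinite(log_prior(prof, params, spec))

    def test_outside_support_is_minus_inf(self):
        prof = get_profile("simulation")
        spec = preset_spec("GCM-RS2")
        params = ds.preset_scenario("sim1_large_N50T100").params.replace(
            delta_mu=np.array([0.0, -0.1]))
        assert log_prior(prof, params, spec) == -math.inf

    def test_empirical_alpha_prior_standard_normal(self):
        prof = get_profile("empirical")
        spec = preset_spec("GCM-RS2").with_profile("empirical")
        fp = {f.name: f for f in ds.free_parameters(spec, prof)}
        assert fp["alpha0[2,1]"].prior.logpdf(0.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_invgamma_variance_prior_change_of_variables(self):
        """The SD-scale density integrates to the same mass the Inverse-Gamma
        variance distribution assigns to the matching variance interval."""
        prof = get_profile("simulation")
        spec = preset_spec("GCM")
        fp = {f.name: f for f in ds.free_parameters(spec, prof)}
        pr = fp["sigma_beta0"].prior
        for s1, s2 in ((0.1, 0.5), (0.5, 5.0)):
            mass_sd = integrate.quad(lambda s: math.exp(pr.logpdf(s)),
                                     s1, s2, limit=200)[0]
            mass_var = (stats.invgamma.cdf(s2 ** 2, 0.001, scale=0.001)
                        - stats.invgamma.cdf(s1 ** 2, 0.001, scale=0.001))
            assert mass_sd == pytest.approx(mass_var, rel=1e-6)

    def test_phi_outside_unit_interval_reports_minus_inf(self):
        prof = get_profile("simulation")
        spec = preset_spec("GCM")
        with pytest.raises(ValueError):
            # the container itself enforces the stationarity support
            ParameterSet(phi0=1.2)
        fp = {f.name: f for f in ds.free_parameters(spec, prof)}
        assert fp["phi0"].prior.logpdf(1.2) == -math.inf
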