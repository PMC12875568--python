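"""Information criteria, entropy, classification scores, decision rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import driftswitch as ds
from driftswitch.model import RegimeProbabilities
from driftswitch.selection import (CandidateMetrics, DecisionRule, decide,
                                   entropy, information_criteria,
                                   rope_sensitivity)

from conftest import auc_pair_count


class TestInformationCriteria:
    def test_null_case(self):
        assert information_criteria(0.0, 0, 1) == (0.0, 0.0, 0.0)

    def test_direct_evaluation(self):
        aic, bic, sbic = information_criteria(-100.0, 5, 100)
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200 + 5 * math.log(100))
        assert sbic == pytest.approx(200 + 5 * math.log(100 * 102 / 24))

    def test_small_n_sbic_interior_not_clamped(self):
        _, _, sbic = information_criteria(0.0, 2, 3)
        assert sbic == pytest.approx(2 * math.log(15 / 24))
        assert sbic < 0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-1e4, 0), st.integers(0, 50), st.integers(1, 10**6))
    def test_bic_aic_identity(self, ll, k, n):
        aic, bic, _ = information_criteria(ll, k, n)
        assert bic - aic == pytest.approx(k * (math.log(n) - 2), rel=1e-12)

    def test_practical_significance_margin(self):
        """A one-parameter simplification with unchanged fit moves the AIC
        by exactly 2 — the conventional practical-significance boundary."""
        a1, _, _ = information_criteria(-500.0, 11, 5000)
        a2, _, _ = information_criteria(-500.0, 10, 5000)
        assert a1 - a2 == pytest.approx(2.0)


def _probs(p, valid=None):
    p = np.asarray(p, float)
    if valid is None:
        valid = np.ones(p.shape[:2], dtype=bool)
    return RegimeProbabilities(p=p, valid=valid)


class TestEntropy:
    def test_degenerate_probabilities_give_one(self):
        p = np.zeros((2, 3, 2))
        p[..., 0] = [[1, 0, 1], [0, 1, 1]]
        p[..., 1] = 1 - p[..., 0]
        assert entropy(_probs(p)).value == pytest.approx(1.0)

    def test_uniform_probabilities_give_zero(self):
        for K in (2, 3, 4):
            p = np.full((3, 5, K), 1.0 / K)
            assert entropy(_probs(p)).value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_single_cell(self):
        p = np.array([[[0.9, 0.1]]])
        want = 1 + (0.9 * math.log(0.9) + 0.1 * math.log(0.1)) / math.log(2)
        got = entropy(_probs(p)).value
        assert got == pytest.approx(want, abs=1e-12)
        assert round(got, 3) == 0.531

    def test_per_person_entropies_partition_global_sum(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=(4, 7))
        e = entropy(_probs(p))
        t_i = np.full(4, 7)
        # (1 - E) * n equals the sum of per-person (1 - E_i) * T_i
        lhs = (1 - e.value) * e.n
        rhs = ((1 - e.per_person) * t_i).sum()
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_single_regime_is_an_error(self):
        p = np.ones((2, 3, 1))
        with pytest.raises(ValueError, match="single regime"):
            entropy(_probs(p))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 4))
    def test_bounds_and_mixing_monotonicity(self, seed, K):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(K), size=(3, 6))
        e0 = entropy(_probs(p)).value
        assert 0.0 <= e0 <= 1.0
        lam = rng.uniform(0.1, 0.9)
        mixed = (1 - lam) * p + lam / K
        e1 = entropy(_probs(mixed)).value
        assert e1 <= e0 + 1e-12


class TestClassificationScores:
    def _truth(self, regimes):
        r = np.asarray(regimes)
        return ds.LatentTruth(regimes=r, baseline_path=np.zeros(r.shape),
                              iiv_path=np.ones(r.shape))

    def test_perfect_separation(self):
        p2 = np.array([[0.9, 0.95, 0.1, 0.05]])
        p = np.stack([1 - p2, p2], axis=2)
        truth = self._truth([[2, 2, 1, 1]])
        auc, rec, prec = ds.classification_scores(_probs(p), truth)
        assert (auc, rec, prec) == (1.0, 1.0, 1.0)

    def test_chance_scores_near_half(self):
        rng = np.random.default_rng(1)
        p2 = rng.uniform(size=(40, 50))
        p = np.stack([1 - p2, p2], axis=2)
        truth = self._truth(rng.integers(1, 3, size=(40, 50)))
        auc, _, _ = ds.classification_scores(_probs(p), truth)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_small_case_matches_pair_counting(self):
        scores = [0.9, 0.3, 0.8, 0.1]
        labels = [1, 1, 0, 0]
        want = auc_pair_count(scores, labels)
        assert want == 0.75
        p2 = np.array([scores])
        p = np.stack([1 - p2, p2], axis=2)
        truth = self._truth([[lab + 1 for lab in labels]])
        auc, _, _ = ds.classification_scores(_probs(p), truth)
        assert auc == pytest.approx(want)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ranking_auc_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 15))
        scores = np.round(rng.uniform(size=n), 2)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        p2 = scores[None, :]
        p = np.stack([1 - p2, p2], axis=2)
        truth = self._truth((labels + 1)[None, :])
        auc, _, _ = ds.classification_scores(_probs(p), truth)
        assert auc == pytest.approx(auc_pair_count(scores, labels), abs=1e-12)

    def test_single_class_truth_flags_undefined_auc(self):
        p2 = np.array([[0.4, 0.6]])
        p = np.stack([1 - p2, p2], axis=2)
        with pytest.warns(UserWarning, match="one class"):
            auc, _, _ = ds.classification_scores(_probs(p), self._truth([[1, 1]]))
        assert math.isnan(auc)


class TestRopeSensitivity:
    def test_hdis_clear_of_rope(self):
        assert rope_sensitivity([(0.2, 0.4)] * 10) == 1.0

    def test_hdis_inside_rope(self):
        assert rope_sensitivity([(0.01, 0.03)] * 10) == 0.0

    def test_type_i_error_at_nominal_rate(self):
        hdis = [(0.1, 0.5)] * 5 + [(-0.2, 0.3)] * 95
        assert rope_sensitivity(hdis, true_value=0.0, mode="zero") == 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            rope_sensitivity([])


def table2_candidates():
    """Metric values shaped like the large-effect simulation results."""
    return [
        CandidateMetrics("RW", False, 14893, 14913, 14929, sensitivity=1.0),
        CandidateMetrics("GCM", False, 13505, 13544, 13576, sensitivity=0.96),
        CandidateMetrics("GCM-RS2", True, 7319, 7391, 7450, 2, 0.91, 1.0),
        CandidateMetrics("RW-RS2", True, 7176, 7242, 7295, 2, 0.89, 1.0),
        CandidateMetrics("GCM-RS3", True, 7263, 7360, 7440, 3, 0.85, 0.89),
        CandidateMetrics("RW-RS3", True, 7111, 7209, 7289, 3, 0.81, 0.91),
    ]


def table4_candidates():
    return [
        CandidateMetrics("RW", False, 8745, 8764, 8780, sensitivity=1.0),
        CandidateMetrics("GCM", False, 8239, 8278, 8310, sensitivity=0.19),
        CandidateMetrics("GCM-RS2", True, 7547, 7618, 7677, 2, 0.21, 0.80),
        CandidateMetrics("RW-RS2", True, 7444, 7509, 7563, 2, 0.19, 0.79),
        CandidateMetrics("GCM-RS3", True, 7432, 7530, 7610, 3, 0.37, 0.78),
        CandidateMetrics("RW-RS3", True, 7333, 7431, 7511, 3, 0.38, 0.72),
    ]


def table5_candidates():
    return [
        CandidateMetrics("RW", False, 7172, 7205, 7232, sensitivity=1.0),
        CandidateMetrics("GCM", False, 6910, 6949, 6981, sensitivity=0.03),
        CandidateMetrics("GCM-RS2", True, 7209, 7281, 7339, 2, 0.37, 0.51),
        CandidateMetrics("RW-RS2", True, 6895, 6967, 7026, 2, 0.22, 0.51),
        CandidateMetrics("GCM-RS3", True, 7015, 7113, 7193, 3, 0.34, 0.51),
        CandidateMetrics("RW-RS3", True, 6395, 6493, 6573, 3, 0.19, 0.51),
    ]


def table3_candidates_moderate():
    return [
        CandidateMetrics("GCM+GCM-IIV", False, 79306, 79385, 79452),
        CandidateMetrics("GCM+RS2-IIV", True, 70463, 70566, 70653, 2,
                         0.58, 0.94),
    ]


class TestDecisionRules:
    @pytest.mark.parametrize("rule,expected", [
        ("IC", "RW-RS3"),
        ("entropy+IC", "GCM-RS2"),
        ("AUC+IC", "GCM-RS2"),            # tied AUC 1.0: reported pair
        ("entropy+sensitivity", "GCM-RS2"),
        ("AUC+sensitivity", "GCM-RS2"),
    ])
    def test_large_effect_verdicts(self, rule, expected):
        assert decide(DecisionRule(rule=rule), table2_candidates()) == expected

    @pytest.mark.parametrize("rule,expected", [
        ("IC", "RW-RS3"),
        ("entropy+IC", "GCM"),
        ("AUC+IC", "GCM-RS2"),
        ("entropy+sensitivity", "GCM"),
        ("AUC+sensitivity", "GCM-RS2"),
    ])
    def test_small_effect_verdicts(self, rule, expected):
        assert decide(DecisionRule(rule=rule), table4_candidates()) == expected

    @pytest.mark.parametrize("rule,expected", [
        ("IC", "RW-RS3"),
        ("entropy+IC", "GCM"),
        ("AUC+IC", "GCM"),
        ("entropy+sensitivity", "GCM"),
        ("AUC+sensitivity", "GCM"),
    ])
    def test_null_effect_verdicts(self, rule, expected):
        assert decide(DecisionRule(rule=rule), table5_candidates()) == expected

    @pytest.mark.parametrize("rule,expected", [
        ("IC", "GCM+RS2-IIV"),
        ("entropy+IC", "GCM+GCM-IIV"),    # moderate sparsity entropy .58 < .6
        ("AUC+IC", "GCM+RS2-IIV"),
    ])
    def test_iiv_switching_verdicts(self, rule, expected):
        assert decide(DecisionRule(rule=rule),
                      table3_candidates_moderate()) == expected

    def test_no_model_selected_when_nothing_qualifies(self):
        cands = [
            CandidateMetrics("GCM", False, 100, 110, 120, sensitivity=0.5),
            CandidateMetrics("GCM-RS2", True, 90, 105, 115, 2, 0.4, 0.5),
        ]
        assert decide(DecisionRule(rule="entropy+sensitivity"), cands) is None

    def test_order_invariance(self):
        cands = table4_candidates()
        for rule in ("IC", "entropy+IC", "AUC+sensitivity"):
            fwd = decide(DecisionRule(rule=rule), cands)
            rev = decide(DecisionRule(rule=rule), list(reversed(cands)))
            assert fwd == rev

    def test_missing_sensitivity_raises(self):
        with pytest.raises(ValueError, match="sensitivity"):
            decide(DecisionRule(rule="entropy+sensitivity"),
                   table3_candidates_moderate())


class TestPluginLoglik:
    def test_gcm_rs2_counts_eleven_parameters(self, tiny_fit):
        _, _, res = tiny_fit
        _, k = ds.plugin_loglik(res)
        assert k == 11

    def test_single_regime_plugin_matches_direct_ar_loglik(self):
        """For a constant S=1 model the plug-in equals the plain AR(1)
        log-likelihood at the same parameter point."""
        scn = ds.preset_scenario("sim1_large_N50T100").with_size(5, 30)
        panel, _ = ds.simulate_dataset(scn, 9)
        res = ds.RegimeSwitchingAR(panel, "GCM").fit(
            settings=ds.MCMCSettings(n_chains=2, n_iter=800, n_burnin=300,
                                     seed=3))
        ll, k = ds.plugin_loglik(res)
        assert k == 5
        pe = res.point_estimates
        b0 = res.latent_means["b0"]
        # direct conditional AR(1) likelihood
        want = 0.0
        for i in range(panel.n_persons):
            y = panel.y[i]
            mu = b0[i] + pe["beta10"] * panel.period[i]
            for t in range(1, y.shape[0]):
                m = mu[t] + pe["phi0"] * (y[t - 1] - mu[t - 1])
                want += -0.5 * (math.log(2 * math.pi * pe["iiv0"] ** 2)
                                + (y[t] - m) ** 2 / pe["iiv0"] ** 2)
        assert ll == pytest.approx(want, rel=1e-10)

    def test_fit_metrics_assembles_report(self, tiny_fit):
        panel, truth, res = tiny_fit
        m = ds.fit_metrics(res, truth, name="GCM-RS2")
        assert m.n == panel.n_total
        assert m.aic == pytest.approx(-2 * m.loglik_hat + 2 * m.k)
        assert m.is_rs and m.entropy is not None and m.auc is not None
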