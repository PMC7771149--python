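import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from neckteeth.data import JuvenileRecord
from neckteeth.design import DesignSpec
from neckteeth.likelihoods import (
    DefenseParams,
    MorphoParams,
    PriorSpec,
    binomial_count_loglik,
    defense_joint_loglik,
    log_prior,
    morpho_loglik,
    ordinal_category_probs,
    positive_orthant_logprob,
    truncated_mvn_loglik,
)

SPEC_K = DesignSpec(factors={"kairomone": (False, True)}, max_interaction_order=1)


def _record(k, ped, kair=False):
    return JuvenileRecord(
        clone="UNI", kairomone=kair, uvr=False, instar=2, mother_uid="m0",
        neckteeth=k, pedestal=ped,
    )


def _params(beta_n=(0.0, 0.0), beta_p=(0.0,), tau=(-1.0, 1.0), u=0.0, sigma=1.0):
    return DefenseParams(
        beta_n=np.array(beta_n),
        beta_p=np.array(beta_p),
        tau=np.array(tau),
        mothers=("m0",),
        u_n=np.array([u]),
        u_p=np.array([u]),
        sigma_n=sigma,
        sigma_p=sigma,
    )


class TestOrdinal:
    def test_symmetric_closed_form(self):
        probs = ordinal_category_probs(0.0, (-1.0, 1.0))
        assert probs == pytest.approx([0.26894, 0.46212, 0.26894], abs=1e-5)

    def test_extreme_eta_concentrates_on_C(self):
        probs = ordinal_category_probs(60.0, (-1.0, 1.0))
        assert probs[2] == pytest.approx(1.0, abs=1e-12)
        assert probs[:2] == pytest.approx([0.0, 0.0], abs=1e-12)

    @pytest.mark.parametrize("eta,tau", [(0.7, (-0.3, 1.2)), (-2.0, (0.5, 0.6)), (3.0, (-4.0, 8.0))])
    def test_normalization_and_monotonicity(self, eta, tau):
        probs = ordinal_category_probs(eta, tau)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(probs >= 0)
        shifted = ordinal_category_probs(eta + 1.0, tau)
        assert shifted[2] > probs[2]

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            ordinal_category_probs(0.0, (1.0, -1.0))


class TestBinomial:
    @pytest.mark.parametrize(
        "k,eta,expected",
        [
            (5, 0.0, math.log(1 / 32)),
            (2, 0.0, math.log(10 / 32)),
            (5, math.log(3.0), 5 * math.log(0.75)),
        ],
    )
    def test_closed_forms(self, k, eta, expected):
        assert binomial_count_loglik(k, eta) == pytest.approx(expected, abs=1e-4)

    def test_out_of_range_count(self):
        with pytest.raises(ValueError):
            binomial_count_loglik(6, 0.0)


class TestDefenseJoint:
    def test_single_record_closed_form(self):
        # binomial(5 | eta=0) + ordinal C at eta=0, tau=(-1,1)
        ll = defense_joint_loglik(
            [_record(5, "C")], _params(), SPEC_K, include_random_effect_prior=False
        )
        assert ll == pytest.approx(-3.4657 + math.log(0.26894), abs=1e-4)

    def test_enumeration_sums_to_one(self):
        params = _params(beta_n=(0.3, -0.2), beta_p=(0.7,), tau=(-0.4, 0.9), u=0.15)
        lls = [
            defense_joint_loglik(
                [_record(k, ped, kair=True)], params, SPEC_K,
                include_random_effect_prior=False,
            )
            for k in range(6)
            for ped in "ABC"
        ]
        assert logsumexp(lls) == pytest.approx(0.0, abs=1e-12)

    def test_dataset_additivity(self):
        recs = [_record(2, "B"), _record(0, "A", kair=True), _record(4, "C")]
        single = defense_joint_loglik(recs, _params(), SPEC_K, include_random_effect_prior=False)
        double = defense_joint_loglik(recs * 2, _params(), SPEC_K, include_random_effect_prior=False)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_unknown_mother_errors(self):
        rec = JuvenileRecord(
            clone="UNI", kairomone=False, uvr=False, instar=2, mother_uid="ghost",
            neckteeth=1, pedestal="A",
        )
        with pytest.raises(KeyError, match="ghost"):
            defense_joint_loglik([rec], _params(), SPEC_K)

    def test_random_effect_prior_term(self):
        recs = [_record(2, "B")]
        without = defense_joint_loglik(recs, _params(), SPEC_K, include_random_effect_prior=False)
        with_prior = defense_joint_loglik(recs, _params(), SPEC_K)
        assert with_prior == pytest.approx(without + 2 * stats.norm.logpdf(0.0), abs=1e-10)


class TestTruncatedMVN:
    def test_univariate_reduction(self):
        assert truncated_mvn_loglik(1.0, 0.0, 1.0) == pytest.approx(
            math.log(2 * stats.norm.pdf(1.0)), abs=1e-6
        )

    def test_bivariate_independent(self):
        ll = truncated_mvn_loglik([1.0, 1.0], [0.0, 0.0], np.eye(2))
        assert ll == pytest.approx(2 * stats.norm.logpdf(1.0) + math.log(4), abs=1e-6)

    def test_outside_orthant(self):
        assert truncated_mvn_loglik([1.0, -0.5], [0.0, 0.0], np.eye(2)) == -math.inf

    def test_correlated_orthant_against_monte_carlo(self):
        rng = np.random.default_rng(11)
        mu = np.array([0.3, -0.2, 0.5])
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + 0.5 * np.eye(3)
        n = 1_000_000
        draws = rng.multivariate_normal(mu, cov, size=n)
        p_hat = np.all(draws > 0, axis=1).mean()
        se = math.sqrt(p_hat * (1 - p_hat) / n)
        p = math.exp(positive_orthant_logprob(mu, cov))
        assert abs(p - p_hat) < 3 * se

    def test_truncation_constant_vanishes_deep_in_orthant(self):
        cov = np.array([[1.0, 0.3, 0.1], [0.3, 1.0, 0.2], [0.1, 0.2, 1.0]])
        logp = positive_orthant_logprob(np.array([5.0, 5.0, 5.0]), cov)
        assert math.exp(logp) == pytest.approx(1.0, abs=1e-4)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            truncated_mvn_loglik([1.0, 1.0], [0.0, 0.0], np.array([[1.0, 2.0], [2.0, 1.0]]))


def _morpho_record(bl, bw, sl, kair=False):
    return JuvenileRecord(
        clone="UNI", kairomone=kair, uvr=False, instar=2, mother_uid="m0",
        neckteeth=0, pedestal="A", body_length=bl, body_width=bw, spina_length=sl,
    )


def _morpho_params(coef=None, sigma=None):
    return MorphoParams(
        coef=np.zeros((2, 3)) if coef is None else coef,
        mothers=("m0",),
        U=np.zeros((1, 3)),
        sigma_u=np.array([1.0, 1.0, 1.0]),
        Sigma=np.eye(3) if sigma is None else sigma,
    )


class TestMorphoLoglik:
    def test_independent_closed_form(self):
        ll = morpho_loglik(
            [_morpho_record(1.0, 1.0, 1.0)], _morpho_params(), SPEC_K,
            include_random_effect_prior=False,
        )
        assert ll == pytest.approx(3 * (stats.norm.logpdf(1.0) + math.log(2)), abs=1e-6)

    def test_partial_record_marginalizes(self):
        ll = morpho_loglik(
            [_morpho_record(1.0, None, None)], _morpho_params(), SPEC_K,
            include_random_effect_prior=False,
        )
        assert ll == pytest.approx(truncated_mvn_loglik(1.0, 0.0, 1.0), abs=1e-10)

    def test_all_missing_skipped(self):
        recs = [_morpho_record(1.0, 1.0, 1.0), _morpho_record(None, None, None)]
        ll_both = morpho_loglik(recs, _morpho_params(), SPEC_K, include_random_effect_prior=False)
        ll_one = morpho_loglik(recs[:1], _morpho_params(), SPEC_K, include_random_effect_prior=False)
        assert ll_both == pytest.approx(ll_one, abs=1e-12)

    def test_permutation_invariance(self):
        recs = [
            _morpho_record(0.9, 0.5, 0.4),
            _morpho_record(1.1, 0.6, None, kair=True),
            _morpho_record(0.8, None, 0.3),
        ]
        params = _morpho_params(sigma=np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 1.0]]))
        fwd = morpho_loglik(recs, params, SPEC_K, include_random_effect_prior=False)
        rev = morpho_loglik(recs[::-1], params, SPEC_K, include_random_effect_prior=False)
        assert fwd == pytest.approx(rev, rel=1e-12)


class TestPriors:
    def test_single_coefficient_closed_form(self):
        assert log_prior(np.array([0.0])) == pytest.approx(-3.2215, abs=1e-4)
        assert log_prior(np.array([10.0])) == pytest.approx(-3.7215, abs=1e-4)

    def test_threshold_ordering_gives_minus_inf(self):
        params = _params()
        params.tau = np.array([1.0, 1.0 - 1e-9])  # violate ordering post-hoc
        assert log_prior(params) == -math.inf

    def test_defense_params_prior_decomposes(self):
        params = _params(beta_n=(1.0, -2.0), beta_p=(0.5,), tau=(-1.0, 1.0), sigma=0.7)
        expected = (
            sum(stats.norm.logpdf(v, scale=10) for v in (1.0, -2.0, 0.5, -1.0, 1.0))
            + 2 * (stats.halfnorm.logpdf(0.7, scale=10))
        )
        assert log_prior(params) == pytest.approx(expected, abs=1e-10)
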