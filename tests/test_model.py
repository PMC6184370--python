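"""Generative-model construction: likelihoods, transitions, preferences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import repgame as rg
from repgame.config import DONATE, KEEP, ParameterError

alphas = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)
betas = st.floats(min_value=0.01, max_value=1.0, allow_nan=False,
                  exclude_min=False)


def assert_column_stochastic(m, atol=1e-12):
    assert np.allclose(m.sum(axis=0), 1.0, atol=atol, rtol=0)
    assert (m >= -atol).all()


class TestApprovalLikelihood:
    @pytest.mark.parametrize("alpha, p_expected", [
        (0.0, 0.5),                       # uninformative 50-50 limit
        (np.log(3), 0.75),                # e^ln3/(e^ln3+1) = 3/4
        (50.0, 1.0),                      # near-deterministic limit
    ])
    def test_diagonal_probability(self, alpha, p_expected):
        a = rg.build_approval_likelihood(alpha)
        assert a[0, 0] == a[1, 1] == pytest.approx(p_expected, abs=1e-9)
        assert a[1, 0] == a[0, 1] == pytest.approx(1 - p_expected, abs=1e-9)

    def test_alpha_zero_exactly_half(self):
        assert (rg.build_approval_likelihood(0.0) == 0.5).all()

    def test_negative_alpha_rejected(self):
        with pytest.raises(ParameterError):
            rg.build_approval_likelihood(-0.1)

    @settings(max_examples=100, derandomize=True)
    @given(alphas)
    def test_stochastic_and_in_range(self, alpha):
        a = rg.build_approval_likelihood(alpha)
        assert_column_stochastic(a)
        assert 0.5 <= a[0, 0] < 1.0 or alpha > 30  # saturates at fp 1.0

    @settings(max_examples=50, derandomize=True)
    @given(alphas, alphas)
    def test_strictly_increasing_in_alpha(self, a1, a2):
        lo, hi = min(a1, a2), max(a1, a2)
        if hi - lo > 1e-9 and hi < 30:
            assert (rg.build_approval_likelihood(hi)[0, 0]
                    > rg.build_approval_likelihood(lo)[0, 0])


class TestSelfworthTransition:
    def test_beta_one_is_identity_for_both_actions(self):
        for action in (DONATE, KEEP):
            assert np.array_equal(rg.build_selfworth_transition(action, 1.0),
                                  np.eye(2))

    def test_half_beta_is_maximally_imprecise(self):
        b = rg.build_selfworth_transition(DONATE, 0.5)
        assert b[:, 1] == pytest.approx([0.5, 0.5])
        b = rg.build_selfworth_transition(KEEP, 0.5)
        assert b[:, 0] == pytest.approx([0.5, 0.5])

    def test_donate_sustains_charitable(self):
        b = rg.build_selfworth_transition(DONATE, 0.9)
        assert b[0, 0] == 1.0           # charitable -> charitable
        assert b[0, 1] == pytest.approx(0.1)  # mean -> charitable
        assert b[1, 1] == pytest.approx(0.9)

    def test_keep_mirrors_donate(self):
        donate = rg.build_selfworth_transition(DONATE, 0.7)
        keep = rg.build_selfworth_transition(KEEP, 0.7)
        assert np.allclose(keep, donate[::-1, ::-1])

    @pytest.mark.parametrize("beta", [0.0, -0.1, 1.1])
    def test_invalid_beta_rejected(self, beta):
        with pytest.raises(ParameterError):
            rg.build_selfworth_transition(DONATE, beta)

    @settings(max_examples=100, derandomize=True)
    @given(betas, st.sampled_from([DONATE, KEEP]))
    def test_columns_stochastic(self, beta, action):
        assert_column_stochastic(rg.build_selfworth_transition(action, beta))


class TestWealthTransition:
    def test_donate_floor_absorbing(self):
        b = rg.build_wealth_transition(DONATE, 0.1, 8)
        assert b[0, 0] == 1.0

    def test_keep_at_top_drops_only_by_decay(self):
        b = rg.build_wealth_transition(KEEP, 0.1, 8)
        assert b[7, 7] == pytest.approx(0.9)
        assert b[6, 7] == pytest.approx(0.1)

    def test_keep_mid_level_single_step_enumeration(self):
        # keep from level 3: shift to 4, then decay to 3 with prob 0.1
        b = rg.build_wealth_transition(KEEP, 0.1, 8)
        assert b[4, 3] == pytest.approx(0.9)
        assert b[3, 3] == pytest.approx(0.1)
        assert b[:, 3].sum() == pytest.approx(1.0)

    def test_donate_reaches_floor_within_n_minus_one_steps(self):
        n = 8
        b = rg.build_wealth_transition(DONATE, 0.1, n)
        power = np.linalg.matrix_power(b, n - 1)
        assert np.allclose(power[0], 1.0, atol=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            rg.build_wealth_transition(DONATE, 1.5, 8)
        with pytest.raises(ParameterError):
            rg.build_wealth_transition(DONATE, 0.1, 1)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=0, max_value=1), st.integers(2, 12),
           st.sampled_from([DONATE, KEEP]), st.booleans())
    def test_columns_stochastic(self, attrition, n, action, decay_first):
        b = rg.build_wealth_transition(action, attrition, n, decay_first)
        assert_column_stochastic(b)


class TestPreferences:
    def test_default_span_four_log_linear(self, default_config):
        prefs = rg.build_preferences(default_config)
        assert np.allclose(prefs.c_wealth, np.arange(8) * 4 / 7)
        assert prefs.c_wealth.max() - prefs.c_wealth.min() == pytest.approx(4.0)
        assert prefs.c_approval[0] - prefs.c_approval[1] == pytest.approx(4.0)

    def test_zero_span_indifferent(self):
        prefs = rg.build_preferences(rg.GameConfig(preference_span=0.0))
        assert (prefs.c_wealth == 0).all()
        assert prefs.c_approval[0] == prefs.c_approval[1]

    @settings(max_examples=30, derandomize=True)
    @given(st.floats(min_value=0, max_value=10))
    def test_approval_margin_equals_span(self, span):
        prefs = rg.build_preferences(rg.GameConfig(preference_span=span))
        assert prefs.c_approval[0] - prefs.c_approval[1] == pytest.approx(span)


class TestAssembleAndValidate:
    def test_default_dimensions(self, default_model):
        assert default_model.n_joint == 16
        assert len(default_model.action_set) == 2
        assert default_model.likelihood.a_wealth.shape == (8, 16)
        assert default_model.likelihood.a_approval.shape == (2, 16)

    def test_minimal_two_level_instance(self):
        model = rg.assemble_model(rg.GameConfig(n_wealth_levels=2))
        assert model.n_joint == 4
        assert rg.validate_model(model) == []

    @settings(max_examples=100, derandomize=True)
    @given(alphas, betas)
    def test_joint_transitions_stochastic_for_random_params(self, alpha, beta):
        model = rg.assemble_model(rg.GameConfig(alpha=alpha, beta=beta))
        for action in (DONATE, KEEP):
            assert_column_stochastic(model.transitions.b_joint[action])
        assert rg.validate_model(model) == []

    def test_tensor_factorization_on_product_beliefs(self, default_model,
                                                     rng):
        # acting on a product-form belief joint-wise equals acting
        # factor-wise and re-composing
        for action in (DONATE, KEEP):
            qw = rng.dirichlet(np.ones(8))
            qs = rng.dirichlet(np.ones(2))
            joint = np.kron(qw, qs)
            via_joint = default_model.transitions.b_joint[action] @ joint
            via_factors = np.kron(
                default_model.transitions.b_wealth[action] @ qw,
                default_model.transitions.b_selfworth[action] @ qs)
            assert np.allclose(via_joint, via_factors, atol=1e-12)

    def test_validate_reports_perturbed_likelihood_column(self, default_model):
        bad = default_model.likelihood.a_approval.copy()
        bad[0, 3] += 0.01
        broken = rg.GenerativeModel(
            config=default_model.config,
            likelihood=rg.LikelihoodModel(
                a_wealth=default_model.likelihood.a_wealth,
                a_approval=bad,
                a_approval_factor=default_model.likelihood.a_approval_factor),
            transitions=default_model.transitions,
            preferences=default_model.preferences,
            initial_prior=default_model.initial_prior)
        report = rg.validate_model(broken)
        assert any("a_approval" in line and "3" in line for line in report)

    def test_validate_reports_factorization_violation(self, default_model):
        bad_joint = dict(default_model.transitions.b_joint)
        perturbed = bad_joint[DONATE].copy()
        perturbed[:, 0] = np.roll(perturbed[:, 0], 1)
        bad_joint[DONATE] = perturbed
        broken = rg.GenerativeModel(
            config=default_model.config,
            likelihood=default_model.likelihood,
            transitions=rg.TransitionModel(
                b_wealth=default_model.transitions.b_wealth,
                b_selfworth=default_model.transitions.b_selfworth,
                b_joint=bad_joint),
            preferences=default_model.preferences,
            initial_prior=default_model.initial_prior)
        assert any("factorize" in line for line in rg.validate_model(broken))

    def test_initial_prior_point_mass_on_broke_charitable(self, default_model):
        d = default_model.initial_prior.d_joint
        assert d[0] == 1.0 and d.sum() == 1.0
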