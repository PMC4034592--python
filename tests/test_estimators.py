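import numpy as np
import pytest

from dtlest import (
    LikelihoodData,
    Scenario,
    TrialDesign,
    bcmle_estimate,
    conditional_loglik,
    estimate_all,
    final_stage_estimate,
    mle_estimate,
    rb1_conditioning,
    rb1_estimate,
    rb2_estimate,
    selection_probability,
    simulate_trial,
    upper_truncated_normal_mean,
)
from dtlest.estimators import _stat_variances, batch_estimates, selection_event_moments
from dtlest.trial import simulate_batch

from conftest import make_outcome


class TestMleAndFinalStage:
    def test_mle_weighted_mean(self, design_unequal):
        stage_means = [
            [1.0, 2.0, 3.0],
            [0.5, 0.1, np.nan],
            [0.2, np.nan, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design_unequal)
        assert outcome.selected_arm == 0
        assert mle_estimate(outcome, design_unequal) == pytest.approx(275 / 175)

    def test_final_stage_passthrough(self, design_unequal):
        stage_means = [
            [1.0, 2.0, 3.0],
            [0.5, 0.1, np.nan],
            [0.2, np.nan, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design_unequal)
        assert final_stage_estimate(outcome) == 3.0

    def test_two_stage_mle(self):
        design = TrialDesign((3, 1), (50, 50), 50.0)
        stage_means = [
            [1.0, 0.4],
            [0.5, np.nan],
            [0.2, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design)
        assert mle_estimate(outcome, design) == pytest.approx(0.7)


class TestRb1Conditioning:
    def test_fixed_example_moments_and_bound(self, design321, outcome_321):
        # z = 85, y12 = 0.5, dropped stage-1 mean 0.3, runner-up cumulative 0.25
        ctx = rb1_conditioning(outcome_321, design321)
        assert ctx.mu_tilde == pytest.approx((85 - 50 * 0.5) / 100)
        assert ctx.sigma_tilde == pytest.approx(np.sqrt(50 * 50 / (50 * 100)))
        t_expected = min((85 - 25 - 50 * 0.3) / 50, (85 - 100 * 0.25) / 50)
        assert ctx.t == pytest.approx(t_expected)
        assert ctx.lower == -np.inf

    def test_simulated_trials_final_mean_below_bound(self, design321):
        sc = Scenario(design=design321, means=(0.5, 0.0, -0.5), seed=31, reps=400)
        for i in range(400):
            _, outcome = simulate_trial(sc, i)
            ctx = rb1_conditioning(outcome, design321)
            assert outcome.relabeled_means[0, -1] <= ctx.t + 1e-12

    def test_inconsistent_outcome_rejected(self, design321, outcome_321):
        bad = np.array(outcome_321.relabeled_means, copy=True)
        # a stage-1 mean below the dropped arm's contradicts the recorded
        # selection event, which the bound check must catch
        bad[0, 0] = float(outcome_321.drop_thresholds[0]) - 0.5
        broken = type(outcome_321)(
            selected_arm=outcome_321.selected_arm,
            ranking=outcome_321.ranking,
            relabeled_means=bad,
            cumulative_mles=outcome_321.cumulative_mles,
            survivors_per_stage=outcome_321.survivors_per_stage,
            drop_thresholds=outcome_321.drop_thresholds,
        )
        with pytest.raises(ValueError):
            rb1_conditioning(broken, design321)

    def test_two_stage_reduces_to_total_over_n(self):
        design = TrialDesign((3, 1), (50, 50), 50.0)
        stage_means = [
            [1.0, 0.4],
            [0.5, np.nan],
            [0.2, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design)
        ctx = rb1_conditioning(outcome, design)
        z = 50 * 1.0 + 50 * 0.4
        assert ctx.mu_tilde == pytest.approx(z / 100)  # the two-stage MLE
        assert ctx.t == pytest.approx((z - 50 * 0.5) / 50)

    def test_moments_free_of_true_means(self, design321, outcome_321):
        # the context is a function of observed statistics only: relabelling
        # the same numbers under different simulation truths changes nothing
        ctx_a = rb1_conditioning(outcome_321, design321)
        outcome_321.mu_selected = 123.0
        ctx_b = rb1_conditioning(outcome_321, design321)
        outcome_321.mu_selected = 0.0
        assert (ctx_a.mu_tilde, ctx_a.sigma_tilde, ctx_a.t) == (
            ctx_b.mu_tilde, ctx_b.sigma_tilde, ctx_b.t,
        )


def rejection_oracle_rb1(design, z0, y12, c1, c2, n_draws=6_000_000, window=0.25, seed=0):
    """Conditional Monte-Carlo estimate of E[Y_13 | Z_1 ~= z0, Y_12 = y12, Q].

    Draws unconstrained stage means for the selected arm (stage 2 fixed at
    its conditioning value), keeps draws whose sufficient total falls in a
    narrow window around z0 and that satisfy the selection inequalities
    against the frozen competitor statistics, and averages the final-stage
    mean of the survivors.
    """
    n1, n2, n3 = design.n_per_stage
    sd = design.stage_sd
    rng = np.random.default_rng(seed)
    y11 = rng.normal(0.0, sd[0], n_draws)
    y13 = rng.normal(0.0, sd[2], n_draws)
    z = n1 * y11 + n2 * y12 + n3 * y13
    keep = (np.abs(z - z0) < window) & (y11 >= c1) & ((n1 * y11 + n2 * y12) / (n1 + n2) >= c2)
    assert keep.sum() > 3000, "oracle needs more draws"
    return y13[keep].mean(), y13[keep].std() / np.sqrt(keep.sum())


def rejection_oracle_rb2(design, z0, c2, n_draws=6_000_000, window=0.25, seed=0):
    """Conditional MC estimate of E[Y_13 | Z_1 ~= z0, stage-two rule]."""
    n1, n2, n3 = design.n_per_stage
    sd = design.stage_sd
    rng = np.random.default_rng(seed)
    y11 = rng.normal(0.0, sd[0], n_draws)
    y12 = rng.normal(0.0, sd[1], n_draws)
    y13 = rng.normal(0.0, sd[2], n_draws)
    z = n1 * y11 + n2 * y12 + n3 * y13
    keep = (np.abs(z - z0) < window) & ((n1 * y11 + n2 * y12) / (n1 + n2) >= c2)
    assert keep.sum() > 3000, "oracle needs more draws"
    return y13[keep].mean(), y13[keep].std() / np.sqrt(keep.sum())


class TestRaoBlackwellOracles:
    # five fixed conditioning points (z, y12, c1, c2) on the unit-sd design
    POINTS = [
        (85.0, 0.5, 0.3, 0.25),
        (20.0, 0.1, -0.5, 0.1),
        (-30.0, -0.4, -0.9, -0.6),
        (60.0, 1.2, 0.0, 0.45),
        (10.0, -0.8, -1.2, 0.0),
    ]

    @pytest.mark.parametrize("z0, y12, c1, c2", POINTS)
    def test_rb1_matches_rejection_sampler(self, design321, z0, y12, c1, c2):
        n1, n2, n3 = design321.n_per_stage
        y13 = (z0 - n1 * 0.0 - n2 * y12) / n3  # placeholder; fix y11 below
        # build an outcome with the exact conditioning values; the final
        # stage mean must satisfy the bound, so put it well inside
        ctx_t = min((z0 - n2 * y12 - n1 * c1) / n3, (z0 - (n1 + n2) * c2) / n3)
        y13 = ctx_t - 0.5
        y11 = (z0 - n2 * y12 - n3 * y13) / n1
        r1 = c1 + 0.1  # runner-up stage-1 mean: kept at stage 1 ...
        stage_means = [
            [y11, y12, y13],
            [r1, 2 * c2 - r1, np.nan],  # ... with cumulative exactly c2
            [c1, np.nan, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design321)
        assert outcome.selected_arm == 0
        assert outcome.drop_thresholds[0] == pytest.approx(c1)
        assert outcome.drop_thresholds[1] == pytest.approx(c2)
        est = rb1_estimate(outcome, design321)
        oracle, se = rejection_oracle_rb1(design321, z0, y12, c1, c2)
        # window bias on the sufficient total adds ~window/(n1+n3)
        assert est == pytest.approx(oracle, abs=max(3 * se, 0.03))

    @pytest.mark.parametrize("z0, y12, c1, c2", POINTS[:3])
    def test_rb2_matches_rejection_sampler(self, design321, z0, y12, c1, c2):
        ctx_t = min((z0 - 50 * y12 - 50 * c1) / 50, (z0 - 100 * c2) / 50)
        y13 = ctx_t - 0.5
        y11 = (z0 - 50 * y12 - 50 * y13) / 50
        r1 = c1 + 0.1
        stage_means = [
            [y11, y12, y13],
            [r1, 2 * c2 - r1, np.nan],
            [c1, np.nan, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design321)
        est = rb2_estimate(outcome, design321)
        oracle, se = rejection_oracle_rb2(design321, z0, c2)
        assert est == pytest.approx(oracle, abs=max(3 * se, 0.03))

    def test_rb1_far_bound_returns_conditional_mean(self, design321):
        stage_means = [
            [1.0, 0.5, 0.2],
            [-50.0, 0.0, np.nan],
            [-60.0, np.nan, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design321)
        ctx = rb1_conditioning(outcome, design321)
        assert rb1_estimate(outcome, design321) == pytest.approx(ctx.mu_tilde, abs=1e-9)

    def test_rb2_far_bound_returns_mle(self, design321):
        stage_means = [
            [1.0, 0.5, 0.2],
            [-50.0, 0.0, np.nan],
            [-60.0, np.nan, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design321)
        assert rb2_estimate(outcome, design321) == pytest.approx(
            mle_estimate(outcome, design321), abs=1e-9
        )

    def test_two_stage_umvcue_direct_formula(self):
        # independent closed form for the two-stage drop-the-losers UMVCUE
        design = TrialDesign((4, 1), (40, 30), 20.0)
        y11, y12 = 1.1, 0.3
        c1 = 0.6  # best competitor stage-1 mean
        stage_means = [
            [y11, y12],
            [c1, np.nan],
            [0.1, np.nan],
            [-0.2, np.nan],
        ]
        _, outcome = make_outcome(stage_means, design)
        n1, n2 = design.n_per_stage
        z = n1 * y11 + n2 * y12
        direct = upper_truncated_normal_mean(
            z / (n1 + n2),
            np.sqrt(design.v2 * n1 / (n2 * (n1 + n2))),
            (z - n1 * c1) / n2,
        )
        assert rb1_estimate(outcome, design) == pytest.approx(direct, abs=1e-12)


class TestSelectionProbability:
    def test_equal_means_is_one_sixth(self, design321):
        # membership reading: 3 choices of dropped arm x 2 winners, all
        # exchangeable
        assert selection_probability((0.0, 0.0, 0.0), design321) == pytest.approx(
            1 / 6, abs=2e-6
        )

    def test_matches_monte_carlo_at_separated_means(self, design321):
        mu = (5.0, 0.0, 0.0)
        p = selection_probability(mu, design321)
        rng = np.random.default_rng(11)
        n = 1_000_000
        S = selection_event_moments(design321)
        m = np.array([mu[0] - mu[2], mu[1] - mu[2], mu[0] - mu[1]])
        draws = rng.multivariate_normal(m, S, size=n)
        mc = (draws > 0).all(axis=1).mean()
        se = np.sqrt(mc * (1 - mc) / n)
        assert p == pytest.approx(mc, abs=3 * se)

    def test_simulation_frequency_of_full_event(self, design321):
        # frequency of (specific arm dropped first, specific winner) in full
        # trial simulation equals the orthant probability
        mu = (0.8, 0.2, -0.3)
        reps = 200_000
        sc = Scenario(design=design321, means=mu, seed=13, reps=reps)
        batch = simulate_batch(sc)
        freq = float(np.mean(batch.selected == 0))
        # P(arm 1 selected) = P(Q; psi relabellings) summed over which arm
        # was dropped first
        p = selection_probability((mu[0], mu[1], mu[2]), design321) + selection_probability(
            (mu[0], mu[2], mu[1]), design321
        )
        se = np.sqrt(freq * (1 - freq) / reps)
        assert freq == pytest.approx(p, abs=3 * se)

    def test_requires_321(self):
        design = TrialDesign((4, 2, 1), (50, 50, 50), 50.0)
        with pytest.raises(ValueError):
            selection_probability((0, 0, 0, 0), design)


class TestConditionalLoglik:
    def test_additive_structure(self, design321):
        data = LikelihoodData(0.4, 0.2, -0.3)
        mu = np.array([0.1, 0.0, -0.2])
        var = _stat_variances(design321)
        gauss = -0.5 * np.sum((data.as_array() - mu) ** 2 / var) - 0.5 * np.sum(
            np.log(2 * np.pi * var)
        )
        expected = gauss - np.log(selection_probability(mu, design321))
        assert conditional_loglik(mu, data, design321) == pytest.approx(expected, abs=1e-10)

    def test_diverges_for_extreme_mu1(self, design321):
        data = LikelihoodData(0.4, 0.2, -0.3)
        l0 = conditional_loglik([0.4, 0.2, -0.3], data, design321)
        l_far = conditional_loglik([40.0, 0.2, -0.3], data, design321)
        assert l_far < l0 - 100


class TestBcmle:
    def test_gradient_vanishes_at_optimum(self, design321):
        data = LikelihoodData(0.4, 0.2, -0.3)
        muhat = bcmle_estimate(data, design321)

        def ll(mu):
            return conditional_loglik(mu, data, design321)

        eps = 3e-4
        for i in range(3):
            e = np.zeros(3)
            e[i] = eps
            g = (ll(muhat + e) - ll(muhat - e)) / (2 * eps)
            assert abs(g) < 1e-4

    def test_distinct_starts_agree(self, design321):
        data = LikelihoodData(0.9, 0.5, -0.8)
        a = bcmle_estimate(data, design321)
        b = bcmle_estimate(data, design321, start=np.array([0.0, 0.0, 0.0]))
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_wide_separation_recovers_naive_stats(self, design321):
        # when the observed ordering is unambiguous, P(Q) ~ 1 and the
        # penalty barely moves the estimates
        data = LikelihoodData(6.0, 0.0, -6.0)
        muhat = bcmle_estimate(data, design321)
        np.testing.assert_allclose(muhat, data.as_array(), atol=0.02)

    def test_corrects_downward_under_equal_stats(self, design321):
        data = LikelihoodData(0.3, 0.25, 0.2)
        muhat = bcmle_estimate(data, design321)
        assert muhat[0] < data.selected_stat  # selection bias pulled back


class TestEstimateAll:
    def test_full_set_on_321(self, design321, outcome_321):
        est = estimate_all(outcome_321, design321)
        assert est.mle == pytest.approx(85 / 150)
        assert est.final_stage == pytest.approx(0.5)
        assert est.rb1 is not None and est.rb2 is not None and est.bcmle is not None
        # RB estimates correct downward relative to the MLE here
        assert est.rb1 < est.mle

    def test_batch_matches_scalar_path(self, design321):
        sc = Scenario(design=design321, means=(0.0, 0.4, -0.2), seed=21, reps=40)
        batch = simulate_batch(sc)
        ests = batch_estimates(batch)
        n = np.asarray(design321.n_per_stage, float)
        for i in range(40):
            y = batch.y_selected[i]
            c1, c2 = batch.thresholds[i]
            r1 = c1 + 0.1
            stage_means = [
                [y[0], y[1], y[2]],
                [r1, 2 * c2 - r1, np.nan],
                [c1, np.nan, np.nan],
            ]
            _, outcome = make_outcome(stage_means, design321)
            if outcome.selected_arm != 0 or outcome.survivors_per_stage[0] != [0, 1]:
                continue  # crafted competitors reproduce a different event
            assert ests["mle"][i] == pytest.approx(mle_estimate(outcome, design321))
            assert ests["rb1"][i] == pytest.approx(rb1_estimate(outcome, design321))
            assert ests["rb2"][i] == pytest.approx(rb2_estimate(outcome, design321))
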