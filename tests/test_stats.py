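"""Choice-probability estimation, posteriors, resampling, GLM, decoding."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from escapenav.errors import PosteriorDomainError, ValidationError
from escapenav.stats import (ChoiceCounts, arm_choice_probability,
                             beta_posterior, classical_tests,
                             decode_escape_arm, fit_choice_glm,
                             naive_vs_experienced, time_binned_posterior)
from escapenav.synth import (SyntheticTrialSpec, generate_choice_glm_dataset,
                             generate_heading_dataset, generate_trials)


class TestArmChoiceProbability:
    def test_point_estimates(self):
        trials = pd.DataFrame({"chosen_arm": ["right"] * 6 + ["left"] * 4})
        counts, p = arm_choice_probability(trials)
        assert (counts.n, counts.k) == (10, 6)
        assert p == 0.6
        all_left = pd.DataFrame({"chosen_arm": ["left"] * 5})
        assert arm_choice_probability(all_left)[1] == 0.0

    def test_empty_is_error(self):
        with pytest.raises(ValidationError):
            arm_choice_probability(pd.DataFrame({"chosen_arm": []}))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        arms = ["right"] * 13 + ["left"] * 7
        p0 = arm_choice_probability(pd.DataFrame({"chosen_arm": arms}))[1]
        for _ in range(5):
            rng.shuffle(arms)
            assert arm_choice_probability(
                pd.DataFrame({"chosen_arm": arms}))[1] == p0

    def test_binomial_sampling_bound(self):
        spec = SyntheticTrialSpec(n_trials=600, true_p_right=0.8, seed=5)
        trials = generate_trials(spec)
        _, p = arm_choice_probability(trials)
        assert abs(p - 0.8) <= 3 * math.sqrt(0.8 * 0.2 / 600)

    def test_counts_invariant(self):
        with pytest.raises(ValidationError):
            ChoiceCounts(n=5, k=7)


class TestBetaPosterior:
    def test_printed_update(self):
        post = beta_posterior(ChoiceCounts(10, 7))
        assert (post.a_post, post.b_post) == (7, 3)

    def test_minimal_counts_recover_the_prior(self):
        post = beta_posterior(ChoiceCounts(2, 1))
        assert (post.a_post, post.b_post) == (1, 1)

    def test_degenerate_counts_raise_domain_error(self):
        for n, k in ((10, 0), (10, 10)):
            with pytest.raises(PosteriorDomainError):
                beta_posterior(ChoiceCounts(n, k))

    def test_standard_convention_is_conjugate_update(self):
        post = beta_posterior(ChoiceCounts(10, 10), convention="standard")
        assert (post.a_post, post.b_post) == (11, 1)

    @pytest.mark.parametrize("n,k", [(10, 7), (5, 2), (50, 40), (600, 474),
                                     (3, 1), (20, 19)])
    def test_matches_grid_normalized_density(self, n, k):
        """Posterior mean and 95% interval agree with brute-force
        grid-normalized integration of the implemented density to 1e-6."""
        post = beta_posterior(ChoiceCounts(n, k))
        x = np.linspace(0.0, 1.0, 2_000_001)[1:-1]
        dens = x ** (post.a_post - 1) * (1 - x) ** (post.b_post - 1)
        w = dens / dens.sum()
        mean = float((w * x).sum())
        cdf = np.cumsum(w)
        lo = float(x[np.searchsorted(cdf, 0.025)])
        hi = float(x[np.searchsorted(cdf, 0.975)])
        assert post.mean == pytest.approx(mean, abs=1e-6)
        got_lo, got_hi = post.interval()
        assert got_lo == pytest.approx(lo, abs=1e-6)
        assert got_hi == pytest.approx(hi, abs=1e-6)

    def test_density_integrates_to_one(self):
        post = beta_posterior(ChoiceCounts(40, 31))
        x = np.linspace(0, 1, 100_001)
        integral = np.trapezoid(post.pdf(x), x)
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestNaiveVsExperienced:
    def _trials(self, n=80, p=0.7, seed=0):
        spec = SyntheticTrialSpec(n_trials=n, true_p_right=p,
                                  naive_fraction=0.15, seed=seed)
        return generate_trials(spec)

    def test_identical_experienced_trials_zero_width(self):
        trials = pd.DataFrame({
            "arena_id": 4, "naive": [True] * 3 + [False] * 20,
            "chosen_arm": ["right"] * 3 + ["right"] * 20,
        })
        res = naive_vs_experienced(trials, n_resamples=50, seed=0)[4]
        assert res.interval == (1.0, 1.0)

    def test_reproducible_with_fixed_seed(self):
        trials = self._trials()
        r1 = naive_vs_experienced(trials, n_resamples=1, seed=3)[4]
        r2 = naive_vs_experienced(trials, n_resamples=1, seed=3)[4]
        assert np.array_equal(r1.resampled_p_right, r2.resampled_p_right)

    def test_matched_groups_cover_naive_estimate(self):
        """With equal true P(right) in both groups, the naive estimate falls
        inside the resampled 95% interval in >= 90% of replicates."""
        hits = 0
        n_rep = 30
        for seed in range(n_rep):
            trials = self._trials(n=120, p=0.7, seed=seed)
            res = naive_vs_experienced(trials, n_resamples=200,
                                       seed=seed)[4]
            lo, hi = res.interval
            hits += lo - 1e-9 <= res.naive_p_right <= hi + 1e-9
        assert hits / n_rep >= 0.9

    def test_fewer_experienced_than_naive_is_error(self):
        trials = pd.DataFrame({
            "arena_id": 1, "naive": [True] * 5 + [False] * 2,
            "chosen_arm": ["right"] * 7,
        })
        with pytest.raises(ValidationError):
            naive_vs_experienced(trials)


class TestTimeBinnedPosterior:
    def test_bin_boundaries(self):
        trials = generate_trials(SyntheticTrialSpec(n_trials=200, seed=1))
        bins = time_binned_posterior(trials)
        assert (bins[0].t_start, bins[0].t_end) == (0.0, 300.0)
        assert (bins[1].t_start, bins[1].t_end) == (120.0, 420.0)
        assert bins[-1].t_end <= 3600.0 + 1e-9

    def test_all_trials_at_time_zero(self):
        trials = pd.DataFrame({
            "chosen_arm": ["right", "left"] * 5, "t_session": 0.0,
        })
        bins = time_binned_posterior(trials)
        populated = [b for b in bins if b.posterior is not None]
        assert all(b.t_start == 0.0 or b.posterior is None for b in bins)
        assert populated and populated[0].n_trials == 10
        empties = [b for b in bins if b.t_start >= 300.0]
        assert all(b.posterior is None and b.gap_reason == "empty"
                   for b in empties)

    def test_stationary_preference_bins_agree_with_pooled(self):
        """Under a constant choice probability, every populated bin's
        posterior mean lies inside the pooled posterior's 95% interval."""
        trials = generate_trials(SyntheticTrialSpec(
            n_trials=400, true_p_right=0.8, seed=9))
        counts, _ = arm_choice_probability(trials)
        pooled = beta_posterior(counts)
        lo, hi = pooled.interval()
        # widen by binomial noise of the per-bin sample size
        bins = time_binned_posterior(trials)
        for b in bins:
            if b.posterior is None or b.n_trials < 10:
                continue
            margin = 2.0 * math.sqrt(0.8 * 0.2 / b.n_trials)
            assert lo - margin <= b.posterior.mean <= hi + margin


GLM_WEIGHTS = {"geodesic_ratio": -3.0, "angle_ratio": -3.0,
               "t_session": 0.0, "origin_arm": 0.0}


@pytest.fixture(scope="module")
def dataset():
    return generate_choice_glm_dataset(GLM_WEIGHTS, n=600, seed=21)


class TestChoiceGLM:

    def test_parameter_recovery_and_accuracy(self, dataset):
        trials, truth = dataset
        res = fit_choice_glm(trials, seed=0)
        assert len(res.accuracies) == 20
        assert res.accuracies.mean() > 0.5
        named = dict(zip(res.coef_names, zip(res.coef_mean, res.coef_se)))
        for var in ("geodesic_ratio", "angle_ratio"):
            mean, se = named[var]
            assert abs(mean - truth[var]) <= 2 * se

    def test_shuffled_outcomes_destroy_accuracy(self, dataset):
        trials, _ = dataset
        res = fit_choice_glm(trials, shuffle_control=True, seed=0)
        assert abs(res.accuracies.mean()) < 0.15

    def test_trial_only_subset_is_worse(self, dataset):
        """Dropping the arena predictors (keeping trial time and origin)
        loses most of the predictive accuracy."""
        trials, _ = dataset
        full = fit_choice_glm(trials, seed=0)
        partial = fit_choice_glm(trials, seed=0,
                                 variable_subset=("t_session", "origin_arm"))
        assert partial.accuracies.mean() < full.accuracies.mean() - 0.3

    def test_median_coefficient_error_across_datasets(self):
        """Over 20 independent synthetic datasets (600 trials each) the
        median absolute coefficient error stays below 0.5 on the
        normalized scale."""
        errors = []
        for seed in range(20):
            trials, truth = generate_choice_glm_dataset(GLM_WEIGHTS, n=600,
                                                        seed=100 + seed)
            res = fit_choice_glm(trials, n_repeats=1, seed=seed)
            named = dict(zip(res.coef_names, res.coef_mean))
            pairs = [("geodesic_ratio", "geodesic_ratio"),
                     ("angle_ratio", "angle_ratio"),
                     ("t_session", "t_session"),
                     ("origin_right", "origin_arm")]
            errors.extend(abs(named[fit_name] - truth[truth_name])
                          for fit_name, truth_name in pairs)
        assert np.median(errors) < 0.5

    def test_single_arena_rejected(self):
        trials = generate_trials(SyntheticTrialSpec(n_trials=50, seed=0))
        with pytest.raises(ValidationError):
            fit_choice_glm(trials)


class TestDecoding:
    def test_uninformative_headings_decode_at_chance(self):
        H, arms = generate_heading_dataset(n_trials=150, max_separation_deg=0,
                                           seed=3)
        acc = decode_escape_arm(H, arms, n_splits=30, seed=0)
        assert np.nanmax(np.abs(acc - 0.5)) < 0.12

    def test_fully_separated_headings_decode_perfectly(self):
        H, arms = generate_heading_dataset(n_trials=150,
                                           max_separation_deg=400,
                                           noise_deg=1.0, seed=4)
        acc = decode_escape_arm(H, arms, n_splits=30, seed=0)
        assert (acc[1:] > 0.95).all()

    def test_growing_separation_gives_increasing_accuracy(self):
        H, arms = generate_heading_dataset(n_trials=240, n_timepoints=8,
                                           max_separation_deg=80,
                                           noise_deg=25.0, seed=5)
        acc = decode_escape_arm(H, arms, n_splits=60, seed=0)
        # strongly increasing overall: late accuracy beats early clearly
        assert acc[-1] - acc[0] > 0.25
        assert sps.spearmanr(np.arange(8), acc).statistic > 0.8

    def test_single_class_flagged(self):
        H = np.random.default_rng(0).normal(size=(40, 3))
        acc = decode_escape_arm(H, np.zeros(40, dtype=int), seed=0)
        assert np.isnan(acc).all()


class TestClassicalTests:
    def test_identical_proportions_z_is_zero(self):
        a = ChoiceCounts(40, 10)
        stat, p = classical_tests(a, a, kind="two_proportion_z")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_z_rejected(self):
        with pytest.raises(ValidationError):
            classical_tests(ChoiceCounts(5, 0), ChoiceCounts(4, 0),
                            kind="two_proportion_z")

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p for [[10, 0], [0, 10]] against an exhaustive
        hypergeometric enumeration."""
        a, b = ChoiceCounts(10, 10), ChoiceCounts(10, 0)
        _, p = classical_tests(a, b, kind="fisher_exact")
        # enumerate all tables with fixed margins (row sums 10, col sums 10)
        probs = [sps.hypergeom.pmf(x, 20, 10, 10) for x in range(11)]
        obs = sps.hypergeom.pmf(10, 20, 10, 10)
        expected = sum(q for q in probs if q <= obs * (1 + 1e-12))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_chi2_uniform_counts_zero(self):
        stat, p = classical_tests(np.array([25, 25, 25, 25]), kind="chi2")
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_chi2_two_sample_table(self):
        stat, p = classical_tests(ChoiceCounts(50, 40), ChoiceCounts(50, 10),
                                  kind="chi2")
        expected_stat, expected_p, *_ = sps.chi2_contingency(
            [[40, 10], [10, 40]], correction=False)
        assert stat == pytest.approx(expected_stat)
        assert p == pytest.approx(expected_p)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            classical_tests(ChoiceCounts(5, 2), kind="anova")
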