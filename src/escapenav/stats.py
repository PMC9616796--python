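"""Choice-probability estimation and inference for escape-arm behavior.

Implements the pooled arm-choice estimate, the Beta-Binomial posterior with
the study's printed (non-conjugate-standard) update, naive-vs-experienced
resampling, time-binned posteriors, the GLM predicting escape arm from trial
and arena covariates, heading-based decoding of the escape arm, and the
classical two-sample tests used throughout.

A trial table is a pandas DataFrame with columns ``mouse_id``, ``arena_id``,
``naive`` (bool), ``chosen_arm`` ('left'/'right'), ``origin_arm``,
``t_session`` (seconds), ``geodesic_ratio``, ``angle_ratio``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import STATS_DEFAULTS
from .errors import PosteriorDomainError, ValidationError

TRIAL_COLUMNS = ["mouse_id", "arena_id", "naive", "chosen_arm", "origin_arm",
                 "t_session", "geodesic_ratio", "angle_ratio"]


# ---------------------------------------------------------------------------
# Counts and point estimate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChoiceCounts:
    """n = total trials, k = right-path escapes."""

    n: int
    k: int

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise ValidationError("need 0 <= k <= n")

    @property
    def p_right(self) -> float:
        return self.k / self.n


def arm_choice_probability(trials: pd.DataFrame) -> tuple[ChoiceCounts, float]:
    """Pooled right-arm escape probability with exact counts."""
    if len(trials) == 0:
        raise ValidationError("no trials")
    k = int((trials["chosen_arm"] == "right").sum())
    counts = ChoiceCounts(n=len(trials), k=k)
    return counts, counts.p_right


# ---------------------------------------------------------------------------
# Bayesian posterior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PosteriorEstimate:
    """Beta posterior over P(right)."""

    a_post: float
    b_post: float

    def __post_init__(self):
        if self.a_post <= 0 or self.b_post <= 0:
            raise PosteriorDomainError(
                "non-positive Beta shape: with the unit prior the update "
                "a' = a + k - 1, b' = b + n - k - 1 is undefined for k == 0 "
                "or k == n")

    @property
    def mean(self) -> float:
        return self.a_post / (self.a_post + self.b_post)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        d = sps.beta(self.a_post, self.b_post)
        return float(d.ppf(lo)), float(d.ppf(1.0 - lo))

    def pdf(self, x) -> np.ndarray:
        return sps.beta(self.a_post, self.b_post).pdf(x)


def beta_posterior(counts: ChoiceCounts, a_prior: float = 1.0,
                   b_prior: float = 1.0,
                   convention: str = STATS_DEFAULTS["posterior_convention"]
                   ) -> PosteriorEstimate:
    """Beta posterior for the right-arm probability.

    ``convention='paper'`` applies the study's printed update
    ``a' = a + k - 1, b' = b + n - k - 1`` verbatim (undefined for k = 0 or
    k = n with the unit prior — an explicit domain error);
    ``convention='standard'`` applies the usual conjugate update
    ``a' = a + k, b' = b + n - k``.
    """
    if convention == "paper":
        return PosteriorEstimate(a_prior + counts.k - 1,
                                 b_prior + counts.n - counts.k - 1)
    if convention == "standard":
        return PosteriorEstimate(a_prior + counts.k,
                                 b_prior + counts.n - counts.k)
    raise ValidationError(f"unknown posterior convention {convention!r}")


# ---------------------------------------------------------------------------
# Naive vs experienced resampling
# ---------------------------------------------------------------------------

@dataclass
class ResampleComparison:
    arena_id: object
    naive_p_right: float
    n_naive: int
    resampled_p_right: np.ndarray
    mean: float
    interval: tuple[float, float]


def naive_vs_experienced(trials: pd.DataFrame,
                         n_resamples: int = STATS_DEFAULTS["n_resamples"],
                         seed: int = 0) -> dict[object, ResampleComparison]:
    """Per arena: naive-trial P(right) vs subsampled experienced trials.

    Experienced trials are repeatedly sampled without replacement to match
    the arena's naive-trial count; the resampled distribution is summarized
    by its mean and 95th-percentile interval.
    """
    rng = np.random.default_rng(seed)
    out: dict[object, ResampleComparison] = {}
    for arena_id, sub in trials.groupby("arena_id", sort=True):
        naive = sub[sub["naive"].astype(bool)]
        exp = sub[~sub["naive"].astype(bool)]
        if len(naive) == 0 or len(exp) == 0:
            raise ValidationError(
                f"arena {arena_id}: need >= 1 naive and >= 1 experienced trial")
        if len(exp) < len(naive):
            raise ValidationError(
                f"arena {arena_id}: fewer experienced ({len(exp)}) than "
                f"naive ({len(naive)}) trials")
        right = (exp["chosen_arm"] == "right").to_numpy()
        ps = np.empty(n_resamples)
        for i in range(n_resamples):
            pick = rng.choice(len(right), size=len(naive), replace=False)
            ps[i] = right[pick].mean()
        lo, hi = np.percentile(ps, [2.5, 97.5])
        out[arena_id] = ResampleComparison(
            arena_id=arena_id,
            naive_p_right=float((naive["chosen_arm"] == "right").mean()),
            n_naive=len(naive), resampled_p_right=ps,
            mean=float(ps.mean()), interval=(float(lo), float(hi)))
    return out


# ---------------------------------------------------------------------------
# Time-binned posterior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeBin:
    t_start: float
    t_end: float
    n_trials: int
    posterior: PosteriorEstimate | None       # None marks a gap
    gap_reason: str = ""


def time_binned_posterior(trials: pd.DataFrame,
                          bin_width: float = STATS_DEFAULTS["bin_width_s"],
                          bin_step: float = STATS_DEFAULTS["bin_step_s"],
                          horizon: float = STATS_DEFAULTS["horizon_s"],
                          convention: str = STATS_DEFAULTS["posterior_convention"],
                          ) -> list[TimeBin]:
    """Posterior of P(right) in overlapping session-time bins.

    Bins are [t, t + bin_width) for t = 0, bin_step, 2*bin_step, ... within
    the first ``horizon`` seconds. Empty bins (and, under the paper
    convention, bins with all-left or all-right trials) yield flagged gaps
    rather than estimates.
    """
    sub = trials[trials["t_session"] < horizon]
    out: list[TimeBin] = []
    t = 0.0
    while t + bin_width <= horizon + 1e-9:
        in_bin = sub[(sub["t_session"] >= t) & (sub["t_session"] < t + bin_width)]
        if len(in_bin) == 0:
            out.append(TimeBin(t, t + bin_width, 0, None, "empty"))
        else:
            counts, _ = arm_choice_probability(in_bin)
            try:
                post = beta_posterior(counts, convention=convention)
                out.append(TimeBin(t, t + bin_width, counts.n, post))
            except PosteriorDomainError:
                out.append(TimeBin(t, t + bin_width, counts.n, None,
                                   "degenerate counts"))
        t += bin_step
    return out


# ---------------------------------------------------------------------------
# GLM choice prediction
# ---------------------------------------------------------------------------

GLM_VARIABLES = ("geodesic_ratio", "angle_ratio", "t_session", "origin_arm")


@dataclass
class GLMResult:
    accuracies: np.ndarray            # Pearson r per fit (k_folds * n_repeats)
    coef_names: list[str]
    coefs: np.ndarray                 # (n_fits, n_coefs) incl. intercept
    coef_ses: np.ndarray              # asymptotic SEs per fit, same shape
    shuffled: bool

    @property
    def coef_mean(self) -> np.ndarray:
        return self.coefs.mean(axis=0)

    @property
    def coef_sd(self) -> np.ndarray:
        """Spread of the coefficient across fits. Folds overlap, so this
        understates sampling error; see ``coef_se`` for calibrated
        uncertainty."""
        return self.coefs.std(axis=0, ddof=1)

    @property
    def coef_se(self) -> np.ndarray:
        """Mean asymptotic standard error of each coefficient."""
        return self.coef_ses.mean(axis=0)


def _design_matrix(trials: pd.DataFrame, variables) -> pd.DataFrame:
    """Predictors normalized to [0, 1]; categorical origin arm one-hot."""
    cols = {}
    for var in variables:
        if var == "origin_arm":
            cols["origin_right"] = (trials["origin_arm"] == "right").astype(float)
        else:
            v = trials[var].to_numpy(dtype=float)
            span = v.max() - v.min()
            cols[var] = (v - v.min()) / span if span > 0 else np.zeros(len(v))
    return pd.DataFrame(cols, index=trials.index)


def fit_choice_glm(trials: pd.DataFrame,
                   k_folds: int = STATS_DEFAULTS["glm_k_folds"],
                   n_repeats: int = STATS_DEFAULTS["glm_n_repeats"],
                   shuffle_control: bool = False,
                   variable_subset=None,
                   seed: int = 0) -> GLMResult:
    """Binomial GLM (logit link) predicting right-arm escapes.

    Stratified k-fold cross-validation, stratified on arena so each test set
    is roughly balanced across arenas, repeated ``n_repeats`` times with
    fresh splits (20 fits with the defaults). Accuracy per fit is the
    Pearson correlation between the predicted P(right) and the observed
    choices (right = 1) on held-out trials. ``shuffle_control`` permutes the
    outcomes before fitting; ``variable_subset`` restricts the predictors.
    """
    import statsmodels.api as sm
    from sklearn.model_selection import StratifiedKFold

    if trials["arena_id"].nunique() < 2:
        raise ValidationError("need trials from >= 2 arenas for the GLM")
    variables = tuple(variable_subset) if variable_subset else GLM_VARIABLES
    X = _design_matrix(trials, variables)
    y = (trials["chosen_arm"] == "right").to_numpy(dtype=float)
    arena = trials["arena_id"].to_numpy()
    rng = np.random.default_rng(seed)
    if shuffle_control:
        y = rng.permutation(y)
    acc, coefs, ses = [], [], []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for train, test in skf.split(X, arena):
            y_tr = y[train]
            if y_tr.min() == y_tr.max():
                raise ValidationError(
                    "degenerate training fold: a single outcome class")
            design = sm.add_constant(X.iloc[train], has_constant="add")
            model = sm.GLM(y_tr, design, family=sm.families.Binomial())
            fit = model.fit()
            pred = fit.predict(sm.add_constant(X.iloc[test],
                                               has_constant="add"))
            if np.std(pred) < 1e-12 or np.std(y[test]) < 1e-12:
                r = 0.0
            else:
                r = float(sps.pearsonr(pred, y[test])[0])
            acc.append(r)
            coefs.append(fit.params.to_numpy())
            ses.append(fit.bse.to_numpy())
    names = ["const", *X.columns]
    return GLMResult(np.array(acc), names, np.array(coefs), np.array(ses),
                     shuffled=shuffle_control)


# ---------------------------------------------------------------------------
# Heading-based decoding
# ---------------------------------------------------------------------------

def decode_escape_arm(headings_by_timepoint: np.ndarray, arms: np.ndarray,
                      n_splits: int = STATS_DEFAULTS["decode_n_splits"],
                      test_fraction: float = STATS_DEFAULTS["decode_test_fraction"],
                      seed: int = 0) -> np.ndarray:
    """Decode the escape arm from heading at each normalized timepoint.

    ``headings_by_timepoint`` is (n_trials, n_timepoints); ``arms`` holds
    the binary trial labels. Per timepoint a logistic regression on the
    single heading predictor is fitted on ``n_splits`` random train/test
    splits (test fraction 1/3) and the mean held-out accuracy returned.
    Timepoints whose labels are single-class are flagged with NaN.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    H = np.asarray(headings_by_timepoint, dtype=float)
    y = np.asarray(arms)
    if H.ndim != 2 or len(y) != H.shape[0]:
        raise ValidationError("headings must be (n_trials, n_timepoints)")
    rng = np.random.default_rng(seed)
    out = np.empty(H.shape[1])
    for t in range(H.shape[1]):
        if len(np.unique(y)) < 2:
            out[t] = np.nan
            continue
        scores = []
        for _ in range(n_splits):
            X_tr, X_te, y_tr, y_te = train_test_split(
                H[:, [t]], y, test_size=test_fraction,
                random_state=int(rng.integers(2**31)), stratify=y)
            if len(np.unique(y_tr)) < 2:
                continue
            clf = LogisticRegression().fit(X_tr, y_tr)
            scores.append(clf.score(X_te, y_te))
        out[t] = float(np.mean(scores)) if scores else np.nan
    return out


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def classical_tests(counts_a, counts_b=None, kind: str = "two_proportion_z"
                    ) -> tuple[float, float]:
    """Named classical tests on choice counts; all two-sided.

    ``two_proportion_z`` and ``fisher_exact`` compare two
    :class:`ChoiceCounts`; ``chi2`` tests one count vector against
    uniformity (pass an array) or a 2x2 table built from two counts.
    """
    if kind == "two_proportion_z":
        from statsmodels.stats.proportion import proportions_ztest
        if counts_b is None:
            raise ValidationError("two-proportion z-test needs two counts")
        pooled = (counts_a.k + counts_b.k) / (counts_a.n + counts_b.n)
        if pooled in (0.0, 1.0):
            raise ValidationError(
                "zero-margin table: the z-test statistic is undefined")
        stat, p = proportions_ztest([counts_a.k, counts_b.k],
                                    [counts_a.n, counts_b.n])
        return float(stat), float(p)
    if kind == "fisher_exact":
        if counts_b is None:
            raise ValidationError("Fisher's exact test needs two counts")
        table = [[counts_a.k, counts_a.n - counts_a.k],
                 [counts_b.k, counts_b.n - counts_b.k]]
        stat, p = sps.fisher_exact(table, alternative="two-sided")
        return float(stat), float(p)
    if kind == "chi2":
        if counts_b is None:
            observed = np.asarray(counts_a, dtype=float)
            stat, p = sps.chisquare(observed)
            return float(stat), float(p)
        table = np.array([[counts_a.k, counts_a.n - counts_a.k],
                          [counts_b.k, counts_b.n - counts_b.k]], dtype=float)
        stat, p, *_ = sps.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    raise ValidationError(f"unknown test kind {kind!r}")
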