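"""Interval estimation for the selected treatment mean.

Three routes, matched to the estimators they wrap:

* a conditional nonparametric bootstrap for the Rao-Blackwellized
  estimators — every arm's stage data are resampled with replacement and a
  replicate is accepted only if it reproduces the trial's original
  selection event, so the bootstrap distribution mimics the estimator's
  conditional sampling distribution; percentile endpoints are read off;
* a profile-likelihood interval for the bias-corrected conditional MLE,
  inverting the chi-square(1) likelihood-ratio statistic of the
  selection-penalized likelihood;
* plain Wald intervals (estimate +- z * sd) for the naive MLE and the
  final-stage mean, which ignore selection by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.stats import chi2, norm

from .design import TrialDesign
from .estimators import (
    LikelihoodData,
    bcmle_estimate,
    conditional_loglik,
    negloglik_factory,
    upper_truncated_normal_mean,
)
from .trial import SelectionOutcome, TrialData

__all__ = [
    "BootstrapSettings",
    "IntervalResult",
    "percentile_interval",
    "bootstrap_ci",
    "profile_likelihood_ci",
    "wald_ci",
]


@dataclass(frozen=True)
class BootstrapSettings:
    """Replication control for the conditional bootstrap."""

    B: int = 1000
    level: float = 0.95
    max_attempts: int = 4_000_000
    seed: int = 0
    batch_size: int = 4000

    def __post_init__(self) -> None:
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.max_attempts < self.B:
            raise ValueError("max_attempts must be >= B")


@dataclass
class IntervalResult:
    lower: float
    upper: float
    method: str
    level: float
    n_accepted: int | None = None
    replicates: np.ndarray | None = None
    diagnostics: dict | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower endpoint exceeds upper endpoint")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def percentile_interval(values, level: float) -> tuple[float, float]:
    """Equal-tail empirical percentile interval of a replicate collection."""
    alpha = 1.0 - level
    lo, hi = np.percentile(np.asarray(values, dtype=float), [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _resample_means(rng, data: np.ndarray, B: int) -> np.ndarray:
    n = data.shape[0]
    return data[rng.integers(0, n, size=(B, n))].mean(axis=1)


def bootstrap_ci(
    trial: TrialData,
    outcome: SelectionOutcome,
    design: TrialDesign,
    estimator_tag: str,
    settings: BootstrapSettings,
    rng: np.random.Generator | None = None,
    return_replicates: bool = False,
) -> IntervalResult:
    """Conditional nonparametric bootstrap percentile interval (rb1/rb2).

    Stage by stage, every arm still active in the original trial is
    resampled with replacement from its own patients; a replicate survives
    only if the resampled cumulative MLEs reproduce the original selection
    event (same arms dropped at each stage, same winner).  Accepted
    replicates are pushed through the estimator's closed form with the
    truncation bound recomputed from the resampled competitor statistics,
    and the equal-tail percentiles give the interval.

    Raises when ``settings.max_attempts`` resampling attempts cannot
    produce ``settings.B`` acceptances (pathological acceptance rate).
    """
    if estimator_tag not in ("rb1", "rb2"):
        raise ValueError("bootstrap intervals are provided for 'rb1' and 'rb2'")
    if estimator_tag == "rb2" and design.J != 3:
        raise ValueError("rb2 requires a three-stage design")
    if trial.patient_responses is None:
        raise ValueError("the conditional bootstrap needs patient-level responses")
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    n = np.asarray(design.n_per_stage, dtype=float)
    J, K = design.J, design.K
    Ncum = design.n_cum
    sel = outcome.selected_arm
    # original active sets per stage and drop cohorts
    active_sets: list[list[int]] = [list(range(K))] + [list(s) for s in outcome.survivors_per_stage]
    accepted: list[np.ndarray] = []
    acc_ysel: list[np.ndarray] = []
    acc_thr: list[np.ndarray] = []
    n_acc = 0
    attempts = 0
    while n_acc < settings.B:
        if attempts >= settings.max_attempts:
            rate = n_acc / max(attempts, 1)
            raise RuntimeError(
                f"bootstrap acceptance rate {rate:.2e}: {n_acc} acceptances "
                f"in {attempts} attempts (need B={settings.B})"
            )
        B = min(settings.batch_size, settings.max_attempts - attempts)
        attempts += B
        ok = np.ones(B, dtype=bool)
        cum = {k: np.zeros(B) for k in active_sets[0]}
        means = {k: np.empty((B, J)) * np.nan for k in active_sets[0]}
        thresholds = np.empty((B, J - 1))
        for j in range(J - 1):
            active = active_sets[j]
            kept = set(active_sets[j + 1])
            for k in active:
                m = _resample_means(rng, trial.patient_responses[k][j], B)
                means[k][:, j] = m
                cum[k] = cum[k] + n[j] * m
            xbar = np.stack([cum[k] / Ncum[j] for k in active], axis=1)
            keep_n = len(kept)
            # replicate kept set must equal the original kept set
            order = np.argsort(-xbar, axis=1, kind="stable")
            kept_idx = [i for i, k in enumerate(active) if k in kept]
            top = np.sort(order[:, :keep_n], axis=1)
            ok &= np.all(top == np.sort(np.array(kept_idx)), axis=1)
            dropped_idx = [i for i, k in enumerate(active) if k not in kept]
            thresholds[:, j] = xbar[:, dropped_idx].max(axis=1)
        m3 = _resample_means(rng, trial.patient_responses[sel][J - 1], B)
        ysel = means[sel]
        ysel[:, J - 1] = m3
        z = ysel @ n
        if estimator_tag == "rb1":
            inter = ysel[:, 1 : J - 1] @ n[1 : J - 1] if J > 2 else 0.0
            mu_t = (z - inter) / (n[0] + n[J - 1])
            sd_t = np.sqrt(design.v2 * n[0] / (n[J - 1] * (n[0] + n[J - 1])))
            t = np.full(B, np.inf)
            for j in range(1, J):
                trailing = ysel[:, j : J - 1] @ n[j : J - 1] if j < J - 1 else 0.0
                t = np.minimum(t, (z - trailing - Ncum[j - 1] * thresholds[:, j - 1]) / n[J - 1])
            est = upper_truncated_normal_mean(mu_t, sd_t, t)
        else:
            sd2 = np.sqrt(design.v2 * (1.0 / n[2] - 1.0 / Ncum[2]))
            t_prime = (z - Ncum[1] * thresholds[:, 1]) / n[2]
            est = upper_truncated_normal_mean(z / Ncum[2], sd2, t_prime)
        est = np.atleast_1d(est)[ok]
        accepted.append(est)
        if return_replicates:
            acc_ysel.append(ysel[ok])
            acc_thr.append(thresholds[ok])
        n_acc += est.size
    reps = np.concatenate(accepted)[: settings.B]
    lo, hi = percentile_interval(reps, settings.level)
    diagnostics = None
    if return_replicates:
        diagnostics = {
            "y_selected": np.concatenate(acc_ysel)[: settings.B],
            "thresholds": np.concatenate(acc_thr)[: settings.B],
            "acceptance_rate": n_acc / attempts,
        }
    return IntervalResult(
        lower=lo,
        upper=hi,
        method="bootstrap-percentile",
        level=settings.level,
        n_accepted=int(reps.size),
        replicates=reps if return_replicates else None,
        diagnostics=diagnostics,
    )


def profile_likelihood_ci(
    data: LikelihoodData,
    design: TrialDesign,
    level: float = 0.95,
    xtol: float = 1e-4,
) -> IntervalResult:
    """Profile-likelihood interval for mu_1 under the conditional likelihood.

    Lambda(mu_1) = 2 * [l(joint BC-MLE) - max_{mu_2, mu_3} l(mu_1, ., .)];
    the interval is the set where Lambda stays below the chi-square(1)
    quantile, with endpoints located by bisection to ``xtol``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    q = float(chi2.ppf(level, df=1))
    muhat = bcmle_estimate(data, design)
    neg = negloglik_factory(data, design)
    lhat = -neg(muhat)
    start23 = muhat[1:].copy()

    def lam(mu1: float) -> float:
        # warm-started profile maximization over the nuisance means; the
        # inner tolerance contributes O(1e-8) to Lambda, far below xtol
        nonlocal start23
        res = minimize(
            lambda u: neg(np.array([mu1, u[0], u[1]])),
            start23,
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
        )
        start23 = res.x
        return 2.0 * (lhat + res.fun)

    sd1 = float(np.sqrt(design.v2 / design.n_cum[-1]))
    endpoints = []
    for sign in (-1.0, 1.0):
        start23 = muhat[1:].copy()
        a = float(muhat[0])
        fa = -q  # Lambda(muhat) = 0
        b = a + sign * sd1
        fb = lam(b) - q
        while fb < 0:
            a, fa = b, fb
            b = b + sign * sd1
            fb = lam(b) - q
        root = brentq(lambda m: lam(m) - q, *sorted((a, b)), xtol=xtol)
        endpoints.append(float(root))
    lo, hi = min(endpoints), max(endpoints)
    return IntervalResult(lower=lo, upper=hi, method="profile-likelihood", level=level)


def wald_ci(estimate: float, sd: float, level: float = 0.95) -> IntervalResult:
    """Symmetric normal-theory interval estimate +- z_{1-alpha/2} * sd."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    zq = float(norm.ppf(0.5 + level / 2.0))
    return IntervalResult(
        lower=float(estimate - zq * sd),
        upper=float(estimate + zq * sd),
        method="wald",
        level=level,
    )
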