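"""Operating characteristics of designs and estimators by Monte Carlo.

Bias is computed in the selection-averaged (extended) sense: the estimand
mu_1 is the true mean of whichever arm was selected in each replicate, so
the reported bias is sum_k P(select k) * E[estimate - mu_k | select k].
MSE, coverage, interval width and the tail proportions (interval entirely
above/below mu_1) are averaged the same way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Scenario, TrialDesign
from .estimators import LikelihoodData, batch_estimates, bcmle_estimate
from .intervals import BootstrapSettings, bootstrap_ci, profile_likelihood_ci, wald_ci
from .trial import simulate_batch, simulate_trial

__all__ = [
    "OCResult",
    "CoverageResult",
    "PowerResult",
    "oc_study",
    "overestimation_rate",
    "coverage_study",
    "tail_proportions",
    "selection_power",
]


@dataclass
class OCResult:
    """Bias/MSE summaries per estimator for one scenario."""

    scenario: Scenario
    n_reps: dict[str, int]
    bias: dict[str, float]
    mse: dict[str, float]
    mc_se: dict[str, float]
    conditional_bias: dict[str, dict[int, float]] = field(default_factory=dict)
    overestimation: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for est in self.bias:
            rows.append(
                {
                    "estimator": est,
                    "bias": self.bias[est],
                    "mse": self.mse[est],
                    "mc_se": self.mc_se[est],
                    "overestimation": self.overestimation.get(est, np.nan),
                    "n_reps": self.n_reps[est],
                    "seed": self.scenario.seed,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class CoverageResult:
    """Interval operating characteristics per method for one scenario."""

    scenario: Scenario
    level: float
    n_reps: int
    coverage: dict[str, float]
    mean_width: dict[str, float]
    pct_above: dict[str, float]
    pct_below: dict[str, float]
    n_failures: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.coverage:
            rows.append(
                {
                    "method": m,
                    "coverage": self.coverage[m],
                    "mean_width": self.mean_width[m],
                    "pct_above": self.pct_above[m],
                    "pct_below": self.pct_below[m],
                    "n_reps": self.n_reps,
                    "seed": self.scenario.seed,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class PowerResult:
    """Probability of selecting the designated best arm along a grid."""

    frame: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.frame


def oc_study(
    scenario: Scenario,
    estimators: tuple[str, ...] = ("mle", "rb1", "rb2", "final_stage"),
    bcmle_reps: int | None = 2000,
) -> OCResult:
    """Monte-Carlo bias and MSE of the requested estimators.

    Closed-form estimators use every replicate; the BC-MLE, which requires
    a numerical maximization per replicate, uses the first ``bcmle_reps``
    replicates (its bias is reported with a correspondingly larger MC
    standard error).
    """
    batch = simulate_batch(scenario)
    closed = tuple(e for e in estimators if e != "bcmle")
    ests = batch_estimates(batch, which=closed)
    bias, mse, mc_se, n_reps, cond, over = {}, {}, {}, {}, {}, {}
    mu_sel = batch.mu_selected

    def accumulate(name, values, mu):
        err = values - mu
        bias[name] = float(err.mean())
        mse[name] = float((err**2).mean())
        mc_se[name] = float(err.std(ddof=1) / np.sqrt(err.size))
        n_reps[name] = int(err.size)
        over[name] = float((err > 0).mean())

    for name, values in ests.items():
        accumulate(name, values, mu_sel)
        cond[name] = {
            int(k): float((values - mu_sel)[batch.selected == k].mean())
            for k in np.unique(batch.selected)
        }
    if "bcmle" in estimators:
        design = scenario.design
        m = min(bcmle_reps or batch.reps, batch.reps)
        n = np.asarray(design.n_per_stage, dtype=float)
        vals = np.empty(m)
        for i in range(m):
            y = batch.y_selected[i]
            lik = LikelihoodData(
                selected_stat=float(np.dot(n, y) / n.sum()),
                runnerup_stat=float(batch.thresholds[i, 1]),
                dropped_stat=float(batch.thresholds[i, 0]),
            )
            vals[i] = bcmle_estimate(lik, design)[0]
        accumulate("bcmle", vals, mu_sel[:m])
        cond["bcmle"] = {
            int(k): float((vals - mu_sel[:m])[batch.selected[:m] == k].mean())
            for k in np.unique(batch.selected[:m])
        }
    return OCResult(
        scenario=scenario, n_reps=n_reps, bias=bias, mse=mse, mc_se=mc_se,
        conditional_bias=cond, overestimation=over,
    )


def overestimation_rate(
    scenario: Scenario, estimators: tuple[str, ...] = ("mle", "rb1", "rb2")
) -> dict[str, float]:
    """Fraction of replicates in which each estimator exceeds mu_1."""
    batch = simulate_batch(scenario)
    ests = batch_estimates(batch, which=estimators)
    return {name: float((v > batch.mu_selected).mean()) for name, v in ests.items()}


def coverage_study(
    scenario: Scenario,
    methods: tuple[str, ...] = ("rb1", "rb2"),
    settings: BootstrapSettings | None = None,
    n_trials: int | None = None,
    level: float = 0.95,
    progress: bool = False,
) -> CoverageResult:
    """Coverage, width and tail proportions of the interval methods.

    Simulates ``n_trials`` patient-level trials; per trial, builds the
    requested intervals (conditional bootstrap for rb1/rb2,
    profile-likelihood for bcmle, Wald for mle/final_stage) and scores
    whether each contains, sits entirely above, or entirely below the true
    mean of the selected arm.  Bootstrap failures (acceptance exhaustion)
    are counted and excluded.
    """
    if settings is None:
        settings = BootstrapSettings(B=500, level=level)
    design = scenario.design
    S = int(n_trials if n_trials is not None else scenario.reps)
    needs_patients = any(m in ("rb1", "rb2") for m in methods)
    scenario = Scenario(
        design=design, means=scenario.means, seed=scenario.seed, reps=S,
        patient_level=scenario.patient_level or needs_patients,
        control_mean=scenario.control_mean,
    )
    boot_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(scenario.seed), spawn_key=(987654321,))
    )
    hits = {m: 0 for m in methods}
    above = {m: 0 for m in methods}
    below = {m: 0 for m in methods}
    widths = {m: [] for m in methods}
    fails = {m: 0 for m in methods}
    NJ = design.n_cum[-1]
    for i in range(S):
        trial, outcome = simulate_trial(scenario, i)
        mu1 = outcome.mu_selected
        lik = None
        for m in methods:
            try:
                if m in ("rb1", "rb2"):
                    iv = bootstrap_ci(trial, outcome, design, m, settings, rng=boot_rng)
                elif m == "bcmle":
                    lik = lik or LikelihoodData.from_outcome(outcome, design)
                    iv = profile_likelihood_ci(lik, design, level)
                elif m == "mle":
                    from .estimators import mle_estimate

                    iv = wald_ci(mle_estimate(outcome, design),
                                 float(np.sqrt(design.v2 / NJ)), level)
                elif m == "final_stage":
                    iv = wald_ci(float(outcome.relabeled_means[0, -1]),
                                 float(design.stage_sd[-1]), level)
                else:
                    raise ValueError(f"unknown interval method {m!r}")
            except RuntimeError:
                fails[m] += 1
                continue
            hits[m] += iv.contains(mu1)
            above[m] += iv.lower > mu1
            below[m] += iv.upper < mu1
            widths[m].append(iv.width)
    denom = {m: S - fails[m] for m in methods}
    return CoverageResult(
        scenario=scenario,
        level=level,
        n_reps=S,
        coverage={m: hits[m] / denom[m] for m in methods},
        mean_width={m: float(np.mean(widths[m])) for m in methods},
        pct_above={m: 100.0 * above[m] / denom[m] for m in methods},
        pct_below={m: 100.0 * below[m] / denom[m] for m in methods},
        n_failures=fails,
    )


def tail_proportions(
    K_grid,
    n_per_stage=(50, 50, 50),
    v2: float = 50.0,
    seed: int = 0,
    wald_reps: int = 50_000,
    boot_trials: int = 1000,
    boot_settings: BootstrapSettings | None = None,
    methods: tuple[str, ...] = ("rb1", "rb2", "mle"),
) -> pd.DataFrame:
    """Percent of intervals entirely above / below mu_1 for K:2:1 designs.

    All arm means are zero.  The MLE's Wald interval is cheap and evaluated
    on ``wald_reps`` summary-level replicates; bootstrap methods run at the
    reduced ``boot_trials`` scale.
    """
    rows = []
    for K in K_grid:
        arms = (int(K), 2, 1)
        design = TrialDesign(arms, tuple(n_per_stage), v2)
        row: dict = {"K": int(K)}
        if "mle" in methods:
            sc = Scenario(design=design, means=(0.0,) * K, seed=seed, reps=wald_reps)
            batch = simulate_batch(sc)
            mle = batch_estimates(batch, which=("mle",))["mle"]
            zq = 1.959963984540054
            sd = float(np.sqrt(v2 / design.n_cum[-1]))
            row["mle_above"] = 100.0 * float((mle - zq * sd > batch.mu_selected).mean())
            row["mle_below"] = 100.0 * float((mle + zq * sd < batch.mu_selected).mean())
        boot_methods = tuple(m for m in methods if m in ("rb1", "rb2"))
        if boot_methods:
            sc = Scenario(
                design=design, means=(0.0,) * K, seed=seed + 1,
                reps=boot_trials, patient_level=True,
            )
            cov = coverage_study(sc, methods=boot_methods, settings=boot_settings)
            for m in boot_methods:
                row[f"{m}_above"] = cov.pct_above[m]
                row[f"{m}_below"] = cov.pct_below[m]
        rows.append(row)
    return pd.DataFrame(rows)


def selection_power(
    designs,
    means,
    delta_arm: int,
    delta_grid,
    best_arm: int,
    reps: int = 50_000,
    seed: int = 0,
) -> PowerResult:
    """Probability of selecting the designated best arm as one mean varies.

    ``means`` is the base vector; entry ``delta_arm`` sweeps over
    ``delta_grid``.  When the swept value makes the best arm non-unique the
    point is flagged but still reported for ``best_arm``.
    """
    rows = []
    for label, design in designs:
        base = list(means)
        if len(base) != design.K:
            raise ValueError(f"means length {len(base)} != K={design.K} for design {label}")
        for d, delta in enumerate(delta_grid):
            mu = list(base)
            mu[delta_arm] = float(delta)
            unique_best = mu[best_arm] > max(v for i, v in enumerate(mu) if i != best_arm)
            sc = Scenario(design=design, means=tuple(mu), seed=seed, reps=reps)
            batch = simulate_batch(sc)
            rows.append(
                {
                    "design": label,
                    "delta": float(delta),
                    "power": float((batch.selected == best_arm).mean()),
                    "best_unique": bool(unique_best),
                    "n_reps": reps,
                    "seed": seed,
                }
            )
    return PowerResult(frame=pd.DataFrame(rows))
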