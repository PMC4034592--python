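"""Model/Results interface for estimating the selected treatment mean.

``DropTheLosersModel`` wraps one completed trial (stage-wise arm means,
optionally patient-level responses) together with its design;  ``fit``
applies the selection rule, computes the requested point estimates and
confidence intervals, and returns a ``DropTheLosersResults`` object with a
``summary()`` table in the spirit of statsmodels results classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TrialDesign
from .estimators import (
    EstimateSet,
    LikelihoodData,
    bcmle_estimate,
    final_stage_estimate,
    mle_estimate,
    rb1_conditioning,
    rb1_estimate,
    rb2_estimate,
)
from .intervals import BootstrapSettings, IntervalResult, bootstrap_ci, profile_likelihood_ci, wald_ci
from .trial import SelectionOutcome, TrialData, rank_and_select

__all__ = ["DropTheLosersModel", "DropTheLosersResults"]

_ESTIMATOR_NAMES = ("mle", "final_stage", "rb1", "rb2", "bcmle")


class DropTheLosersModel:
    """One completed drop-the-losers trial, ready for estimation.

    Parameters
    ----------
    stage_means
        Array of shape ``(K, J)``: mean response of each original arm at
        each stage, NaN where the arm had been dropped.
    design
        The :class:`~dtlest.design.TrialDesign` the trial followed.
    patient_responses
        Optional ragged list ``[arm][stage] -> 1-d array`` of raw
        responses; required for bootstrap intervals.
    """

    def __init__(self, stage_means, design: TrialDesign, patient_responses=None):
        self.design = design
        self.data = TrialData(
            stage_means=np.asarray(stage_means, dtype=float),
            patient_responses=patient_responses,
        )
        self.outcome: SelectionOutcome = rank_and_select(self.data, design)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, design: TrialDesign) -> "DropTheLosersModel":
        """Build a model from tidy data.

        Accepts either summary rows (columns ``arm``, ``stage``, ``mean``;
        one row per active arm-stage, 1-based indices) or patient rows
        (columns ``arm``, ``stage``, ``response``).
        """
        K, J = design.K, design.J
        means = np.full((K, J), np.nan)
        patients = None
        if "response" in df.columns:
            patients = [[None] * J for _ in range(K)]
            for (arm, stage), grp in df.groupby(["arm", "stage"]):
                x = grp["response"].to_numpy(dtype=float)
                if x.size != design.n_per_stage[int(stage) - 1]:
                    raise ValueError(
                        f"arm {arm} stage {stage}: {x.size} responses, "
                        f"expected {design.n_per_stage[int(stage) - 1]}"
                    )
                patients[int(arm) - 1][int(stage) - 1] = x
                means[int(arm) - 1, int(stage) - 1] = x.mean()
        elif "mean" in df.columns:
            for _, row in df.iterrows():
                means[int(row["arm"]) - 1, int(row["stage"]) - 1] = float(row["mean"])
        else:
            raise ValueError("dataframe needs a 'mean' or 'response' column")
        return cls(means, design, patient_responses=patients)

    def fit(
        self,
        estimators: tuple[str, ...] = ("mle", "final_stage", "rb1", "rb2", "bcmle"),
        level: float = 0.95,
        bootstrap: BootstrapSettings | None = None,
        compute_ci: bool = True,
    ) -> "DropTheLosersResults":
        """Compute the requested estimators and intervals.

        RB2 and the BC-MLE are silently skipped on designs they are not
        defined for (non-three-stage, non-3:2:1 respectively).  Bootstrap
        intervals need patient-level data and a ``BootstrapSettings``.
        """
        design, outcome = self.design, self.outcome
        is_321 = design.arms_per_stage == (3, 2, 1)
        wanted = [e for e in _ESTIMATOR_NAMES if e in estimators]
        estimates: dict[str, float] = {}
        for name in wanted:
            if name == "mle":
                estimates[name] = mle_estimate(outcome, design)
            elif name == "final_stage":
                estimates[name] = final_stage_estimate(outcome)
            elif name == "rb1":
                estimates[name] = rb1_estimate(outcome, design)
            elif name == "rb2" and design.J == 3:
                estimates[name] = rb2_estimate(outcome, design)
            elif name == "bcmle" and is_321:
                lik = LikelihoodData.from_outcome(outcome, design)
                estimates[name] = float(bcmle_estimate(lik, design)[0])
        intervals: dict[str, IntervalResult] = {}
        if compute_ci:
            NJ = design.n_cum[-1]
            if "mle" in estimates:
                intervals["mle"] = wald_ci(estimates["mle"], float(np.sqrt(design.v2 / NJ)), level)
            if "final_stage" in estimates:
                intervals["final_stage"] = wald_ci(
                    estimates["final_stage"], float(design.stage_sd[-1]), level
                )
            if bootstrap is not None and self.data.patient_responses is not None:
                for tag in ("rb1", "rb2"):
                    if tag in estimates:
                        intervals[tag] = bootstrap_ci(
                            self.data, outcome, design, tag,
                            BootstrapSettings(
                                B=bootstrap.B, level=level,
                                max_attempts=bootstrap.max_attempts,
                                seed=bootstrap.seed, batch_size=bootstrap.batch_size,
                            ),
                        )
            if "bcmle" in estimates:
                lik = LikelihoodData.from_outcome(outcome, design)
                intervals["bcmle"] = profile_likelihood_ci(lik, design, level)
        return DropTheLosersResults(
            model=self, estimates=estimates, intervals=intervals, level=level
        )


@dataclass
class DropTheLosersResults:
    """Estimation results for one trial; returned by ``fit``."""

    model: DropTheLosersModel
    estimates: dict[str, float]
    intervals: dict[str, IntervalResult]
    level: float

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.estimates, name="estimate")

    @property
    def estimate_set(self) -> EstimateSet:
        e = self.estimates
        return EstimateSet(
            mle=e.get("mle", np.nan),
            final_stage=e.get("final_stage", np.nan),
            rb1=e.get("rb1", np.nan),
            rb2=e.get("rb2"),
            bcmle=e.get("bcmle"),
        )

    def conf_int(self) -> pd.DataFrame:
        rows = {
            name: (iv.lower, iv.upper, iv.method)
            for name, iv in self.intervals.items()
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["lower", "upper", "method"]
        )

    def truncation_context(self):
        """Conditional moments and bound behind the RB1 estimate."""
        return rb1_conditioning(self.model.outcome, self.model.design)

    def summary(self) -> str:
        design = self.model.design
        outcome = self.model.outcome
        lines = [
            "Drop-the-losers selected-mean estimation",
            "=" * 56,
            f"Design: {design.label}   n/stage: {design.n_per_stage}   v2: {design.v2:g}",
            f"Selected arm (original label): {outcome.selected_arm + 1}",
            f"Final ranking (arm order): {[int(r) for r in outcome.ranking]}",
            "-" * 56,
            f"{'estimator':<12}{'estimate':>10}   {self.level:.0%} interval",
        ]
        for name, value in self.estimates.items():
            iv = self.intervals.get(name)
            ivs = f"[{iv.lower:8.4f}, {iv.upper:8.4f}] ({iv.method})" if iv else ""
            lines.append(f"{name:<12}{value:>10.4f}   {ivs}")
        lines.append("=" * 56)
        return "\n".join(lines)
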