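"""Trial designs and simulation scenarios for drop-the-losers selection.

A *J*-stage drop-the-losers trial starts with ``K_1`` experimental arms and
drops a predetermined number of them at each interim analysis until a single
arm remains for the confirmatory stage.  A three-stage design that keeps
``L`` of ``K`` arms after stage one is written ``K:L:1``.  Patient responses
are normal with common within-arm variance ``v2``, so the stage-*j* sample
mean of any active arm has standard deviation ``sqrt(v2 / n_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["TrialDesign", "Scenario", "parse_design_string", "validate_design"]


def parse_design_string(s: str) -> tuple[int, ...]:
    """Parse a design label like ``"3:2:1"`` into an arms-per-stage tuple.

    The token count gives the number of stages; tokens must be strictly
    decreasing positive integers ending in 1.
    """
    try:
        arms = tuple(int(tok) for tok in s.strip().split(":"))
    except ValueError as exc:
        raise ValueError(f"design string {s!r} is not colon-separated integers") from exc
    if len(arms) < 2:
        raise ValueError(f"design string {s!r} must have at least two stages")
    if any(a <= 0 for a in arms):
        raise ValueError(f"design string {s!r} contains non-positive arm counts")
    if any(later >= earlier for earlier, later in zip(arms, arms[1:])):
        raise ValueError(f"design string {s!r}: arms per stage must strictly decrease")
    if arms[-1] != 1:
        raise ValueError(f"design string {s!r}: final stage must have exactly one arm")
    return arms


@dataclass(frozen=True)
class TrialDesign:
    """A J-stage drop-the-losers design.

    Parameters
    ----------
    arms_per_stage
        Number of experimental arms active at the start of each stage,
        strictly decreasing to 1 (e.g. ``(3, 2, 1)`` for a 3:2:1 trial).
    n_per_stage
        Patients recruited per active arm at each stage.
    v2
        Within-arm response variance, common to all arms and stages.
    q_ordering
        Reading of the selection event Q used for conditional estimation.
        ``"membership"`` (default) conditions only on which arms were kept
        versus dropped at each stage plus the final interim ranking;
        ``"full"`` additionally conditions on the observed ordering among
        simultaneously kept arms.
    """

    arms_per_stage: tuple[int, ...]
    n_per_stage: tuple[int, ...]
    v2: float
    q_ordering: str = "membership"

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms_per_stage", tuple(int(a) for a in self.arms_per_stage))
        object.__setattr__(self, "n_per_stage", tuple(int(n) for n in self.n_per_stage))
        object.__setattr__(self, "v2", float(self.v2))
        arms, ns = self.arms_per_stage, self.n_per_stage
        if len(arms) < 2:
            raise ValueError("a drop-the-losers design needs at least two stages")
        if len(ns) != len(arms):
            raise ValueError("n_per_stage and arms_per_stage must have equal length")
        if any(later >= earlier for earlier, later in zip(arms, arms[1:])):
            raise ValueError("arms_per_stage must strictly decrease")
        if arms[-1] != 1:
            raise ValueError("final stage must have exactly one experimental arm")
        if any(n < 1 for n in ns):
            raise ValueError("all per-stage sample sizes must be >= 1")
        if self.v2 <= 0:
            raise ValueError("within-arm variance v2 must be positive")
        if self.q_ordering not in ("membership", "full"):
            raise ValueError("q_ordering must be 'membership' or 'full'")

    # ---- derived design constants -------------------------------------
    @property
    def J(self) -> int:
        """Number of stages."""
        return len(self.arms_per_stage)

    @property
    def K(self) -> int:
        """Number of experimental arms at the start of the trial."""
        return self.arms_per_stage[0]

    @property
    def stage_sd(self) -> np.ndarray:
        """Standard deviation sigma_j of a stage-j arm mean, sqrt(v2/n_j)."""
        return np.sqrt(self.v2 / np.asarray(self.n_per_stage, dtype=float))

    @property
    def n_cum(self) -> np.ndarray:
        """Cumulative per-arm sample size N_j = n_1 + ... + n_j."""
        return np.cumsum(self.n_per_stage)

    @property
    def label(self) -> str:
        return ":".join(str(a) for a in self.arms_per_stage)

    @classmethod
    def from_string(
        cls,
        s: str,
        n_per_stage: Sequence[int] | int,
        v2: float,
        q_ordering: str = "membership",
    ) -> "TrialDesign":
        arms = parse_design_string(s)
        if np.isscalar(n_per_stage):
            n_per_stage = (int(n_per_stage),) * len(arms)
        return cls(arms, tuple(n_per_stage), v2, q_ordering)


def validate_design(design: TrialDesign) -> TrialDesign:
    """Re-validate a design and return it (raises on invalid schedules)."""
    return replace(design)


@dataclass(frozen=True)
class Scenario:
    """A simulation scenario: a design plus true arm means and replication.

    ``means`` holds the true mean response of each experimental arm in the
    original arm labelling; ``control_mean``, when given, is simulated but
    never used in selection (the control proceeds to the final stage
    regardless, so it cannot influence which arm is picked).
    """

    design: TrialDesign
    means: tuple[float, ...]
    seed: int = 0
    reps: int = 1
    patient_level: bool = False
    control_mean: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", tuple(float(m) for m in self.means))
        if len(self.means) != self.design.K:
            raise ValueError(
                f"means has length {len(self.means)}, design starts with {self.design.K} arms"
            )
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
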