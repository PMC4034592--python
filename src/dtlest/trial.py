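"""Simulation and the selection/relabelling rule of drop-the-losers trials.

``simulate_trial`` draws a single replicate (stage-wise arm means, or full
patient-level responses) and applies ``rank_and_select``, which encodes the
design's selection rule: at the end of each interim stage the active arms
are ranked by their cumulative MLEs and the worst performers are dropped,
until a single arm reaches the confirmatory stage.  The realized pattern of
these inequalities is the selection event Q on which all conditional
estimation is based.

``simulate_batch`` is the vectorized engine behind the operating-
characteristics harness; it draws all replicates from a single generator
stream and returns only the summary statistics the estimators need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import Scenario, TrialDesign

__all__ = [
    "TrialData",
    "SelectionOutcome",
    "BatchTrials",
    "cumulative_mle",
    "rank_and_select",
    "simulate_trial",
    "simulate_batch",
    "satisfies_q",
]


@dataclass
class TrialData:
    """Observed data of one trial: stage-wise arm means, optionally patients.

    ``stage_means[k, j]`` is the mean response of arm ``k`` (original
    labelling) among the ``n_j`` patients it recruited at stage ``j``; NaN
    where the arm was no longer active.  ``patient_responses[k][j]`` holds
    the raw responses behind that mean when patient-level data were
    simulated (needed by the conditional bootstrap), else None.
    """

    stage_means: np.ndarray
    patient_responses: list[list[np.ndarray | None]] | None = None
    control_responses: list[np.ndarray] | None = None


@dataclass
class SelectionOutcome:
    """The realized selection event Q of one trial.

    ``ranking[k]`` is the final rank (1 = selected) of original arm ``k``.
    ``relabeled_means[r-1, j]`` re-indexes stage means so that row 0 is the
    selected arm; rows follow the final ranking.  ``drop_thresholds[j-1]``
    is the largest cumulative MLE among the arms dropped at stage ``j`` —
    the value the surviving arms had to beat, which defines the truncation
    bound used by the Rao-Blackwellized estimators.
    """

    selected_arm: int
    ranking: np.ndarray
    relabeled_means: np.ndarray
    cumulative_mles: np.ndarray
    survivors_per_stage: list[list[int]]
    drop_thresholds: np.ndarray
    mu_selected: float | None = None

    @property
    def runner_up(self) -> int:
        """Original index of the arm ranked second."""
        return int(np.nonzero(self.ranking == 2)[0][0])


@dataclass
class BatchTrials:
    """Vectorized summary of many simulated trials of one scenario."""

    design: TrialDesign
    y_selected: np.ndarray  # (reps, J) selected arm's stage means
    thresholds: np.ndarray  # (reps, J-1) max dropped cumulative MLE per stage
    selected: np.ndarray  # (reps,) original arm index selected
    mu_selected: np.ndarray  # (reps,) true mean of the selected arm

    @property
    def reps(self) -> int:
        return self.y_selected.shape[0]


def cumulative_mle(stage_means_for_arm, n_per_stage, through_stage: int) -> float:
    """Weighted mean of an arm's stage means through the given stage.

    Returns sum_{i<=j} n_i Y_i / N_j, the arm's MLE from all patients it
    recruited up to and including ``through_stage`` (1-based).
    """
    y = np.asarray(stage_means_for_arm, dtype=float)
    n = np.asarray(n_per_stage, dtype=float)
    j = int(through_stage)
    if j < 1 or j > y.shape[-1] or j > n.shape[-1]:
        raise IndexError(f"through_stage {j} outside the arm's activity")
    if np.any(np.isnan(y[..., :j])):
        raise IndexError("arm was not active through the requested stage")
    return float(np.dot(n[:j], y[..., :j]) / n[:j].sum())


def rank_and_select(trial: TrialData, design: TrialDesign) -> SelectionOutcome:
    """Apply the drop-the-losers selection rule and relabel by final rank.

    At each interim stage the active arms are ranked by cumulative MLE and
    the top ``arms_per_stage[j+1]`` are kept.  Exact ties are broken in
    favour of the lower original arm index (a probability-zero event for
    continuous responses, fixed for determinism).  The final ranking gives
    rank 1 to the winner; arms dropped at a later stage rank above arms
    dropped earlier, and arms dropped at the same stage are ordered by
    their cumulative MLE at the stage they were dropped.
    """
    Y = np.asarray(trial.stage_means, dtype=float)
    K, J = design.K, design.J
    if Y.shape != (K, J):
        raise ValueError(f"stage_means must have shape {(K, J)}")
    n = np.asarray(design.n_per_stage, dtype=float)
    active = list(range(K))
    cum_mles = np.full((K, J), np.nan)
    survivors: list[list[int]] = []
    thresholds = np.full(J - 1, np.nan)
    # rank cohorts, worst first: [dropped@1, dropped@2, ..., runner-up, winner]
    cohorts: list[list[int]] = []
    for j in range(1, J):
        for k in active:
            cum_mles[k, j - 1] = cumulative_mle(Y[k], n, j)
        # sort active arms best-first, ties to the lower original index
        order = sorted(active, key=lambda k: (-cum_mles[k, j - 1], k))
        keep_n = design.arms_per_stage[j]
        kept, dropped = order[:keep_n], order[keep_n:]
        thresholds[j - 1] = max(cum_mles[k, j - 1] for k in dropped)
        # within a cohort: better cumulative MLE at drop time = better rank
        cohorts.append(sorted(dropped, key=lambda k: (cum_mles[k, j - 1], -k)))
        survivors.append(sorted(kept))
        active = kept
    (selected,) = active
    cum_mles[selected, J - 1] = cumulative_mle(Y[selected], n, J)
    cohorts.append([selected])
    flat = [k for cohort in cohorts for k in cohort]  # worst ... best
    ranking = np.empty(K, dtype=int)
    for rank_from_worst, k in enumerate(flat):
        ranking[k] = K - rank_from_worst
    relabeled = np.full((K, J), np.nan)
    for k in range(K):
        relabeled[ranking[k] - 1] = Y[k]
    return SelectionOutcome(
        selected_arm=int(selected),
        ranking=ranking,
        relabeled_means=relabeled,
        cumulative_mles=cum_mles,
        survivors_per_stage=survivors,
        drop_thresholds=thresholds,
    )


def satisfies_q(outcome: SelectionOutcome, design: TrialDesign, atol: float = 1e-12) -> bool:
    """Check the relabeled outcome against its own selection inequalities.

    Every arm kept at stage j must have cumulative MLE >= every arm dropped
    at stage j (membership reading of Q).
    """
    n = np.asarray(design.n_per_stage, dtype=float)
    K, J = design.K, design.J
    ranking = outcome.ranking
    active = list(range(K))
    for j in range(1, J):
        keep_n = design.arms_per_stage[j]
        kept = [k for k in active if k in set(outcome.survivors_per_stage[j - 1])]
        dropped = [k for k in active if k not in set(kept)]
        if len(kept) != keep_n:
            return False
        x = {k: cumulative_mle(outcome.relabeled_means[ranking[k] - 1], n, j) for k in active}
        if any(x[a] < x[d] - atol for a in kept for d in dropped):
            return False
        active = kept
    return True


def _replicate_rng(seed: int, replicate_index: int, stream: int = 0) -> np.random.Generator:
    """Independent substream for one replicate of one scenario."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(replicate_index), int(stream)))
    )


def simulate_trial(scenario: Scenario, replicate_index: int) -> tuple[TrialData, SelectionOutcome]:
    """Simulate one trial replicate and apply selection.

    Stage-wise means are drawn as Y_kj ~ N(mu_k, v2/n_j) for every arm still
    active at stage j (as means of n_j patient draws when
    ``scenario.patient_level``).  Identical ``(seed, replicate_index)``
    reproduce identical output bit for bit.  Control-arm responses, when a
    control mean is given, come from a separate substream and play no part
    in selection.
    """
    design = scenario.design
    rng = _replicate_rng(scenario.seed, replicate_index)
    K, J = design.K, design.J
    mu = np.asarray(scenario.means, dtype=float)
    sd_patient = np.sqrt(design.v2)
    stage_sd = design.stage_sd
    Y = np.full((K, J), np.nan)
    patients: list[list[np.ndarray | None]] | None = None
    if scenario.patient_level:
        patients = [[None] * J for _ in range(K)]
    active = list(range(K))
    for j in range(J):
        nj = design.n_per_stage[j]
        for k in active:
            if scenario.patient_level:
                x = rng.normal(mu[k], sd_patient, size=nj)
                patients[k][j] = x
                Y[k, j] = x.mean()
            else:
                Y[k, j] = rng.normal(mu[k], stage_sd[j])
        if j < J - 1:
            # interim drop: keep the top arms by cumulative MLE
            n = np.asarray(design.n_per_stage, dtype=float)
            order = sorted(active, key=lambda k: (-cumulative_mle(Y[k], n, j + 1), k))
            active = sorted(order[: design.arms_per_stage[j + 1]])
    control = None
    if scenario.control_mean is not None and scenario.patient_level:
        crng = _replicate_rng(scenario.seed, replicate_index, stream=1)
        control = [
            crng.normal(scenario.control_mean, sd_patient, size=nj) for nj in design.n_per_stage
        ]
    trial = TrialData(stage_means=Y, patient_responses=patients, control_responses=control)
    outcome = rank_and_select(trial, design)
    outcome.mu_selected = float(mu[outcome.selected_arm])
    return trial, outcome


def simulate_batch(
    scenario: Scenario,
    reps: int | None = None,
    rng: np.random.Generator | None = None,
) -> BatchTrials:
    """Vectorized simulation of many replicates (summary level).

    Uses a single generator stream (seeded from the scenario seed unless an
    explicit generator is passed), trading the per-replicate substream
    reproducibility of :func:`simulate_trial` for throughput; a fixed seed
    still reproduces the whole batch exactly.
    """
    design = scenario.design
    R = int(reps if reps is not None else scenario.reps)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=int(scenario.seed)))
    K, J = design.K, design.J
    mu = np.asarray(scenario.means, dtype=float)
    n = np.asarray(design.n_per_stage, dtype=float)
    Ncum = design.n_cum
    stage_sd = design.stage_sd
    idx = np.arange(R)
    alive = np.ones((R, K), dtype=bool)
    cum = np.zeros((R, K))
    means_by_stage = []
    thresholds = np.empty((R, J - 1))
    for j in range(J - 1):
        Yj = rng.normal(mu, stage_sd[j], size=(R, K))
        means_by_stage.append(Yj)
        cum = cum + n[j] * Yj
        xbar = cum / Ncum[j]
        # rank actives best-first; ties go to the lower original index
        masked = np.where(alive, xbar, -np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(K), (R, K)), -masked), axis=1)
        keep_n = design.arms_per_stage[j + 1]
        kept = order[:, :keep_n]
        dropped = order[:, keep_n : design.arms_per_stage[j]]
        thresholds[:, j] = masked[idx[:, None], dropped].max(axis=1)
        alive = np.zeros((R, K), dtype=bool)
        alive[idx[:, None], kept] = True
    selected = np.argmax(alive, axis=1)
    yJ = rng.normal(mu[selected], stage_sd[J - 1])
    y_sel = np.empty((R, J))
    for j in range(J - 1):
        y_sel[:, j] = means_by_stage[j][idx, selected]
    y_sel[:, J - 1] = yJ
    return BatchTrials(
        design=design,
        y_selected=y_sel,
        thresholds=thresholds,
        selected=selected,
        mu_selected=mu[selected],
    )
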