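"""Run configuration and result serialization.

Configurations round-trip through YAML/JSON (load -> dump -> load is the
identity); tabular results are written as RFC-4180 CSV with a small
``#``-prefixed metadata header (seed, package version, config hash) so a
run can be traced back to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .design import Scenario, TrialDesign, parse_design_string

__all__ = ["RunConfig", "write_results", "config_hash"]


@dataclass
class RunConfig:
    """Declarative description of a simulation/estimation run."""

    design: str = "3:2:1"
    n_per_stage: list[int] = field(default_factory=lambda: [50, 50, 50])
    v2: float = 50.0
    means: list[float] = field(default_factory=lambda: [0.0, 0.0, 0.0])
    reps: int = 1000
    seed: int = 0
    patient_level: bool = False
    q_ordering: str = "membership"
    estimators: list[str] = field(default_factory=lambda: ["mle", "rb1", "rb2", "final_stage"])
    bootstrap_B: int = 1000
    level: float = 0.95

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # ---- object construction -----------------------------------------
    def trial_design(self) -> TrialDesign:
        arms = parse_design_string(self.design)
        n = self.n_per_stage
        if len(n) != len(arms):
            raise ValueError("n_per_stage length must match the design's stage count")
        return TrialDesign(arms, tuple(n), self.v2, self.q_ordering)

    def scenario(self) -> Scenario:
        return Scenario(
            design=self.trial_design(),
            means=tuple(self.means),
            seed=self.seed,
            reps=self.reps,
            patient_level=self.patient_level,
        )


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the configuration content."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_results(result, path, fmt: str = "csv", config: RunConfig | None = None, seed=None):
    """Serialize a result object (anything with ``to_frame``/``to_dict``).

    CSV output carries ``#`` metadata lines before the header; JSON output
    nests the payload under ``"result"`` next to the metadata.
    """
    path = Path(path)
    meta = {"version": __version__}
    if seed is not None:
        meta["seed"] = int(seed)
    if config is not None:
        meta["config_hash"] = config_hash(config)
    if fmt == "csv":
        if hasattr(result, "to_frame"):
            frame = result.to_frame()
        elif isinstance(result, pd.DataFrame):
            frame = result
        else:
            frame = pd.DataFrame([result.to_dict()])
        frame = frame.round(10)
        with open(path, "w", newline="") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            frame.to_csv(fh, index=False, lineterminator="\n")
    elif fmt == "json":
        if isinstance(result, pd.DataFrame):
            payload = result.to_dict(orient="records")
        elif hasattr(result, "to_frame"):
            payload = result.to_frame().to_dict(orient="records")
        elif hasattr(result, "to_dict"):
            payload = result.to_dict()
        else:
            payload = result
        path.write_text(json.dumps({**meta, "result": payload}, indent=2, sort_keys=True))
    else:
        raise ValueError("fmt must be 'csv' or 'json'")
    return path
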