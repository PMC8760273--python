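"""Run configuration: a validated, hashable record of every knob.

YAML in, dataclass out; unknown keys are listed and rejected.  The config
hash is embedded in run outputs so that every artifact is reproducible
from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # dimensions
    window: int = 11
    maze_height: int = 21
    maze_width: int = 41
    # priors (decision prior by first-action group; state prior is flat)
    E_right: float = 1.0 / 256
    E_left: float = 1.0 / 256
    E_up: float = 1.0 / 256
    E_down: float = 1.0 / 256
    # risk
    gamma_success: float = 0.0
    gamma_partial: float = 0.45
    gamma_fail: float = 0.55
    d_star: int = 2
    # learning
    lr_V: float = 0.1
    lr_WK: float = 1e-3
    # protocol
    T: int = 20_000
    n_sessions: int = 100
    n_training_mazes: int = 1
    seed: int = 0
    # mode flags (recorded in every snapshot; the maze pipeline always runs
    # the fixed-point network whose expectations are the log-ratio means —
    # digamma expectations and the Euler integrator are library modes used
    # by the verification tools)
    expectation_mode: str = "logratio"   # or "digamma"
    delayed_modulation: bool = True
    ode_mode: bool = False

    def __post_init__(self) -> None:
        if self.expectation_mode not in ("logratio", "digamma"):
            raise ValueError("expectation_mode must be 'logratio' or 'digamma'")
        if self.window % 2 == 0:
            raise ValueError("window must be odd")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - valid)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def snapshot(self, path: str | Path) -> None:
        payload = self.to_dict()
        payload["config_hash"] = self.hash
        Path(path).write_text(json.dumps(payload, indent=2))

    # convenience constructors for the domain objects
    def agent_config(self):
        from .experiment import AgentConfig
        from .maze import RiskParams

        return AgentConfig(
            window=self.window, lr_V=self.lr_V, lr_WK=self.lr_WK,
            risk=RiskParams(self.gamma_success, self.gamma_partial,
                            self.gamma_fail, self.d_star),
            delayed_modulation=self.delayed_modulation,
        )

    def decision_prior(self):
        from .experiment import decision_prior_vector

        return decision_prior_vector(self.E_right, self.E_left,
                                     self.E_up, self.E_down)
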