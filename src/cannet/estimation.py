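"""Estimating implicit priors from activity, and predicting learning.

When threshold adaptation is slow relative to the recording window, the
threshold perturbations are identified by maximum likelihood from time
averages of the rates: the log of the mean middle-layer rate estimates
``phi`` (the log state prior) and the log of the mean output rate
estimates ``psi`` (the log decision prior).  With the estimated priors
and the known network architecture and risk function, a naive agent can
be reconstructed and trained on fresh mazes; its learning curve predicts
that of the original agent without ever reading the original activity or
behaviour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .experiment import AgentConfig, SessionLog, build_agent, train
from .maze import RiskParams
from .pomdp import PROB_FLOOR

__all__ = ["PriorEstimate", "estimate_thresholds", "reconstruct_and_predict"]


@dataclass
class PriorEstimate:
    """Estimated threshold perturbations with implied priors.

    By construction ``exp(phi1) + exp(phi0) = 1`` elementwise (likewise
    ``psi``); ``E1_normalized`` rescales the one-hot decision block so its
    1-components sum to 1."""

    phi1: np.ndarray
    phi0: np.ndarray
    psi1: np.ndarray
    psi0: np.ndarray
    n_samples: int
    se_phi: np.ndarray
    se_psi: np.ndarray
    floored: bool = False

    @property
    def D1_hat(self) -> np.ndarray:
        return np.exp(self.phi1)

    @property
    def E1_hat(self) -> np.ndarray:
        return np.exp(self.psi1)

    @property
    def E1_normalized(self) -> np.ndarray:
        e = self.E1_hat
        return e / e.sum()

    @classmethod
    def from_true_psi(cls, psi1: np.ndarray, psi0: np.ndarray,
                      phi1: np.ndarray | None = None,
                      phi0: np.ndarray | None = None) -> "PriorEstimate":
        """Carrier for an exactly known perturbation (reconstruction tests)."""
        n = len(psi1)
        if phi1 is None:
            phi1 = np.full(1, np.log(0.5))
            phi0 = np.full(1, np.log(0.5))
        return cls(np.asarray(phi1), np.asarray(phi0), np.asarray(psi1),
                   np.asarray(psi0), n_samples=0,
                   se_phi=np.zeros_like(phi1), se_psi=np.zeros(n))

    def to_json(self, path) -> None:
        payload = {
            "phi1": self.phi1.tolist(), "phi0": self.phi0.tolist(),
            "psi1": self.psi1.tolist(), "psi0": self.psi0.tolist(),
            "n_samples": self.n_samples,
            "se_phi": self.se_phi.tolist(), "se_psi": self.se_psi.tolist(),
            "E1_normalized": self.E1_normalized.tolist(),
            "floored": self.floored,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PriorEstimate":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["phi1"]), np.array(d["phi0"]),
                   np.array(d["psi1"]), np.array(d["psi0"]),
                   int(d["n_samples"]), np.array(d["se_phi"]),
                   np.array(d["se_psi"]), bool(d["floored"]))


def estimate_thresholds(activity_logs: list[SessionLog],
                        use_decisions: bool = False) -> PriorEstimate:
    """Maximum-likelihood threshold perturbations from pooled activity.

    Pools (concatenates) all supplied session logs — typically one session
    on each of several distinct mazes — and takes the log of the mean
    rates.  Means at exactly 0 or 1 are floored and flagged.  Standard
    errors use the binomial approximation on the per-period means.  With
    ``use_decisions`` the realized decision indicators replace the graded
    output rates (a spike-count estimator).
    """
    if not activity_logs:
        raise ValueError("at least one activity log is required")
    n = sum(log.n_periods for log in activity_logs)
    if n == 0:
        raise ValueError("activity logs contain no periods")
    sum_x = np.sum([log.sum_x for log in activity_logs], axis=0)
    if use_decisions:
        n_y = len(activity_logs[0].sum_y)
        sum_y = np.zeros(n_y)
        for log in activity_logs:
            sum_y += np.bincount(log.decisions, minlength=n_y)
    else:
        sum_y = np.sum([log.sum_y for log in activity_logs], axis=0)
    mx, my = sum_x / n, sum_y / n
    floored = bool(np.any((mx <= 0) | (mx >= 1)) or np.any((my <= 0) | (my >= 1)))
    lo, hi = PROB_FLOOR, 1.0 - PROB_FLOOR
    mx, my = np.clip(mx, lo, hi), np.clip(my, lo, hi)
    return PriorEstimate(
        phi1=np.log(mx), phi0=np.log1p(-mx),
        psi1=np.log(my), psi0=np.log1p(-my),
        n_samples=n,
        se_phi=np.sqrt(mx * (1 - mx) / n),
        se_psi=np.sqrt(my * (1 - my) / n),
        floored=floored,
    )


def reconstruct_and_predict(estimate: PriorEstimate, fresh_mazes,
                            n_sessions: int = 100, seed: int = 0,
                            T: int = 20_000,
                            config: AgentConfig | None = None,
                            risk_params: RiskParams | None = None,
                            use_phi: bool = False,
                            return_agent: bool = False):
    """Train a reconstructed naive agent and return its learning curve.

    The agent is rebuilt from the estimated decision perturbation alone
    (weights at their standard initializations; the state perturbation is
    used only when ``use_phi`` is set, mirroring the default analysis) and
    trained with the standard protocol on mazes the source agent never
    saw.  This function takes no activity or behaviour logs: the
    prediction uses only the estimated priors and the known architecture
    and risk function.
    """
    config = config or AgentConfig()
    if risk_params is not None:
        config = AgentConfig(window=config.window,
                             identity_mix=config.identity_mix,
                             lr_V=config.lr_V, lr_WK=config.lr_WK,
                             risk=risk_params,
                             delayed_modulation=config.delayed_modulation)
    D1 = estimate.D1_hat if use_phi else None
    agent = build_agent(E1=estimate.E1_hat, D1=D1, config=config)
    curve = train(agent, fresh_mazes, n_sessions=n_sessions, seed=seed, T=T)
    return (curve, agent) if return_agent else curve
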