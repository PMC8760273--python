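"""Canonical two-layer rate-coding network.

A middle layer ``x`` with recurrent connections receives binary sensory
input ``o``; an output layer ``y`` read from the delayed middle layer
drives decisions.  Neural activity and synaptic plasticity both descend a
single cost function ``L``: the activity fixed point is a sigmoid of the
summed synaptic drive, plasticity is Hebbian with an activity-dependent
homeostatic term, and output-layer plasticity is additionally scaled by
``(1 - 2*Gamma(t))`` where the modulator ``Gamma`` reports delayed risk —
Hebbian when risk is low, anti-Hebbian when high.

Each synapse class comes in an excitatory/inhibitory pair (``W1``/``W0``
for sensory input, ``K1``/``K0`` recurrent, ``V1``/``V0`` output).  Firing
thresholds adapt with the weights, carrying perturbation terms ``phi`` and
``psi`` that encode the log state and decision priors of the equivalent
Bayesian scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

from .pomdp import PROB_FLOOR, RATIO_CLIP

__all__ = [
    "sig",
    "sig_inv",
    "NetworkState",
    "SynapticWeights",
    "ThresholdSpec",
    "ModulatorTrace",
    "ActivityHistory",
    "activity_fixed_point",
    "activity_ode_step",
    "cost_L",
    "plasticity_step_middle",
    "plasticity_step_output",
    "synaptic_fixed_point",
]

logger = logging.getLogger("cannet")


def sig(w: np.ndarray) -> np.ndarray:
    """Logistic activation (the neurometric function)."""
    return expit(w)


def sig_inv(p: np.ndarray, clip: float = RATIO_CLIP) -> np.ndarray:
    """Inverse sigmoid with arguments clipped to ``(clip, 1 - clip)``;
    the synaptic fixed points diverge at ratios of exactly 0 or 1."""
    return logit(np.clip(p, clip, 1.0 - clip))


def _log1m_sig(w: np.ndarray) -> np.ndarray:
    """ln(1 - sig(w)), computed stably as -log(1 + exp(w))."""
    return -np.logaddexp(0.0, w)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class NetworkState:
    x: np.ndarray
    y: np.ndarray
    x_delayed: np.ndarray
    dt_steps: int = 1

    def clipped(self) -> "NetworkState":
        lo, hi = PROB_FLOOR, 1.0 - PROB_FLOOR
        return NetworkState(np.clip(self.x, lo, hi), np.clip(self.y, lo, hi),
                            np.clip(self.x_delayed, lo, hi), self.dt_steps)


@dataclass
class SynapticWeights:
    """The six synaptic matrices with inverse-learning-rate factors and
    initial copies (the initial weights scaled by ``lam`` play the role of
    Dirichlet prior concentrations in the Bayesian reading)."""

    W1: np.ndarray
    W0: np.ndarray
    K1: np.ndarray
    K0: np.ndarray
    V1: np.ndarray
    V0: np.ndarray
    lam_W: float = 1.0
    lam_K: float = 1.0
    lam_V: float = 1.0
    init: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_x, n_o = self.W1.shape
        if self.K1.shape != (n_x, n_x) or self.V1.shape[1] != n_x:
            raise ValueError("weight shapes inconsistent with layer sizes")
        for l0, l1 in ((self.W0, self.W1), (self.K0, self.K1), (self.V0, self.V1)):
            if l0.shape != l1.shape:
                raise ValueError("paired weight matrices must share a shape")
        if not self.init:
            self.init = {k: getattr(self, k).copy()
                         for k in ("W1", "W0", "K1", "K0", "V1", "V0")}

    @property
    def n_x(self) -> int:
        return self.W1.shape[0]

    @property
    def n_o(self) -> int:
        return self.W1.shape[1]

    @property
    def n_y(self) -> int:
        return self.V1.shape[0]

    def copy(self) -> "SynapticWeights":
        return SynapticWeights(
            self.W1.copy(), self.W0.copy(), self.K1.copy(), self.K0.copy(),
            self.V1.copy(), self.V0.copy(), self.lam_W, self.lam_K, self.lam_V,
            {k: v.copy() for k, v in self.init.items()})


@dataclass
class ThresholdSpec:
    """Threshold perturbations: ``phi`` pairs encode the log state prior,
    ``psi`` pairs the log decision prior; ``exp(phi1) + exp(phi0) = 1``
    elementwise (likewise ``psi``)."""

    phi1: np.ndarray
    phi0: np.ndarray
    psi1: np.ndarray
    psi0: np.ndarray

    @classmethod
    def from_priors(cls, D1: np.ndarray, E1: np.ndarray) -> "ThresholdSpec":
        D1 = np.clip(np.asarray(D1, float), PROB_FLOOR, 1 - PROB_FLOOR)
        E1 = np.clip(np.asarray(E1, float), PROB_FLOOR, 1 - PROB_FLOOR)
        return cls(np.log(D1), np.log(1 - D1), np.log(E1), np.log(1 - E1))

    def validate(self, atol: float = 1e-9) -> None:
        for a, b in ((self.phi1, self.phi0), (self.psi1, self.psi0)):
            if np.max(np.abs(np.exp(a) + np.exp(b) - 1.0)) > atol:
                raise ValueError("exp(perturbations) must sum to 1 elementwise")

    def h(self, weights: SynapticWeights) -> tuple[np.ndarray, np.ndarray]:
        """Adaptive middle-layer thresholds ``(h1, h0)``."""
        h1 = (_log1m_sig(weights.W1).sum(axis=1)
              + _log1m_sig(weights.K1).sum(axis=1) + self.phi1)
        h0 = (_log1m_sig(weights.W0).sum(axis=1)
              + _log1m_sig(weights.K0).sum(axis=1) + self.phi0)
        return h1, h0

    def m(self, weights: SynapticWeights) -> tuple[np.ndarray, np.ndarray]:
        """Adaptive output-layer thresholds ``(m1, m0)``."""
        m1 = _log1m_sig(weights.V1).sum(axis=1) + self.psi1
        m0 = _log1m_sig(weights.V0).sum(axis=1) + self.psi0
        return m1, m0


@dataclass
class ModulatorTrace:
    """Per-evaluation-window risk levels with the delay rule: plasticity
    attributable to the most recent ``dt`` window is unmodulated
    (``Gamma(t, tau) = 0`` for ``t - dt < tau <= t``), earlier windows see
    the current risk."""

    values: np.ndarray  # Gamma per evaluation window, each in [0, 1]
    dt_windows: int = 1

    def __post_init__(self) -> None:
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("risk levels must lie in [0, 1]")

    def gamma_at(self, t: int, tau: int) -> float:
        """Gamma(t, tau) for window index ``tau`` evaluated at time ``t``."""
        if t - self.dt_windows < tau <= t:
            return 0.0
        return float(self.values[min(t, len(self.values) - 1)])


@dataclass
class ActivityHistory:
    """Aligned activity record over one averaging window (a session)."""

    o: np.ndarray          # (T, N_o)
    x: np.ndarray          # (T, N_x)
    y: np.ndarray          # (T, N_y)
    x_delayed: np.ndarray  # (T, N_x): x at tau - dt

    @property
    def T(self) -> int:
        return self.o.shape[0]


# ---------------------------------------------------------------------------
# activity dynamics
# ---------------------------------------------------------------------------


def _drives(o_t: np.ndarray, x_delayed: np.ndarray, w: SynapticWeights,
            thr: ThresholdSpec) -> tuple[np.ndarray, np.ndarray]:
    h1, h0 = thr.h(w)
    m1, m0 = thr.m(w)
    drive_x = (w.W1 - w.W0) @ o_t + (w.K1 - w.K0) @ x_delayed + h1 - h0
    drive_y = (w.V1 - w.V0) @ x_delayed + m1 - m0
    return drive_x, drive_y


def activity_fixed_point(o_t: np.ndarray, x_delayed: np.ndarray,
                         weights: SynapticWeights,
                         thresholds: ThresholdSpec) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state activity: sigmoid of the summed synaptic drive."""
    drive_x, drive_y = _drives(o_t, x_delayed, weights, thresholds)
    return sig(drive_x), sig(drive_y)


def activity_ode_step(state: NetworkState, o_t: np.ndarray,
                      weights: SynapticWeights, thresholds: ThresholdSpec,
                      step_size: float) -> NetworkState:
    """One explicit Euler step of the leaky rate dynamics.

    The leak is the inverse sigmoid of the rate, so the stationary point is
    the sigmoid fixed point.  Rates that a step would push out of (0, 1)
    are clipped to the floor (warning logged).
    """
    if step_size <= 0:
        raise ValueError("step_size must be positive")
    drive_x, drive_y = _drives(o_t, state.x_delayed, weights, thresholds)
    dx = -logit(state.x) + drive_x
    dy = -logit(state.y) + drive_y
    x = state.x + step_size * dx
    y = state.y + step_size * dy
    lo, hi = PROB_FLOOR, 1.0 - PROB_FLOOR
    if (np.any((x <= 0) | (x >= 1)) or np.any((y <= 0) | (y >= 1))):
        logger.warning("Euler step left (0, 1); rates clipped to the floor")
    return NetworkState(np.clip(x, lo, hi), np.clip(y, lo, hi),
                        state.x_delayed, state.dt_steps)


def cost_integrand(o_t: np.ndarray, x: np.ndarray, y: np.ndarray,
                   x_delayed: np.ndarray, weights: SynapticWeights,
                   thresholds: ThresholdSpec, gamma: float) -> float:
    """Instantaneous contribution to the cost ``L`` at one time step."""
    h1, h0 = thresholds.h(weights)
    m1, m0 = thresholds.m(weights)
    xb, yb = 1.0 - x, 1.0 - y
    lo = PROB_FLOOR
    term_x = (x @ (np.log(np.maximum(x, lo)) - weights.W1 @ o_t
                   - weights.K1 @ x_delayed - h1)
              + xb @ (np.log(np.maximum(xb, lo)) - weights.W0 @ o_t
                      - weights.K0 @ x_delayed - h0))
    mod = 1.0 - 2.0 * gamma
    term_y = (y @ (np.log(np.maximum(y, lo)) - mod * (weights.V1 @ x_delayed)
                   - m1)
              + yb @ (np.log(np.maximum(yb, lo)) - mod * (weights.V0 @ x_delayed)
                      - m0))
    return float(term_x + term_y)


def cost_L(history: ActivityHistory, weights: SynapticWeights,
           thresholds: ThresholdSpec,
           gamma_trace: ModulatorTrace | np.ndarray | float = 0.0) -> float:
    """Cost function over a history, as a sum over time steps.

    Output terms at step ``tau`` are modulated by ``(1 - 2*Gamma(t, tau))``
    under the delay rule (the most recent window is unmodulated).  The
    order-one weight-dependent residual of the underlying integral (a
    constant in the optimized activity, negligible against the order-t
    terms) is excluded.
    """
    T = history.T
    if T == 0:
        return 0.0
    if isinstance(gamma_trace, ModulatorTrace):
        gammas = np.array([gamma_trace.gamma_at(T - 1, tau) for tau in range(T)])
    else:
        gammas = np.broadcast_to(np.asarray(gamma_trace, dtype=float), (T,)).copy()
        gammas[-1] = 0.0  # current window is never modulated
    total = 0.0
    for tau in range(T):
        total += cost_integrand(history.o[tau], history.x[tau], history.y[tau],
                                history.x_delayed[tau], weights, thresholds,
                                float(gammas[tau]))
    return total


# ---------------------------------------------------------------------------
# plasticity
# ---------------------------------------------------------------------------


def _hebb(post: np.ndarray, pre: np.ndarray) -> np.ndarray:
    """Time-averaged outer product <post pre^T> over a (T, n) history."""
    return post.T @ pre / post.shape[0]


def plasticity_step_middle(weights: SynapticWeights, history: ActivityHistory,
                           learning_rate: float | None = None) -> SynapticWeights:
    """One batch plasticity update of the middle-layer synapses.

    Hebbian term ``<post pre^T>`` plus homeostatic term
    ``-<post 1^T> * sig(w)`` (the threshold's derivative with respect to
    the weight), applied with rate ``1 / lam_W`` (or ``learning_rate``).
    """
    if history.T == 0:
        raise ValueError("history must be nonempty")
    new = weights.copy()
    eta = learning_rate if learning_rate is not None else 1.0 / weights.lam_W
    x, xb = history.x, 1.0 - history.x
    for name, post, pre in (
        ("W1", x, history.o), ("W0", xb, history.o),
        ("K1", x, history.x_delayed), ("K0", xb, history.x_delayed),
    ):
        w = getattr(new, name)
        rate = eta if name.startswith("W") else (
            learning_rate if learning_rate is not None else 1.0 / weights.lam_K)
        incr = _hebb(post, pre) - post.mean(axis=0)[:, None] * sig(w)
        setattr(new, name, w + rate * incr)
    return new


def plasticity_step_output(weights: SynapticWeights, history: ActivityHistory,
                           Gamma: float | np.ndarray,
                           learning_rate: float | None = None) -> SynapticWeights:
    """One batch plasticity update of the output synapses, with the Hebbian
    term scaled by ``(1 - 2*Gamma)`` (per step if ``Gamma`` is an array);
    the homeostatic term is not modulated."""
    if history.T == 0:
        raise ValueError("history must be nonempty")
    new = weights.copy()
    eta = learning_rate if learning_rate is not None else 1.0 / weights.lam_V
    mod = np.broadcast_to(1.0 - 2.0 * np.asarray(Gamma, dtype=float),
                          (history.T,))
    y, yb = history.y, 1.0 - history.y
    for name, post in (("V1", y), ("V0", yb)):
        w = getattr(new, name)
        hebb = (post * mod[:, None]).T @ history.x_delayed / history.T
        incr = hebb - post.mean(axis=0)[:, None] * sig(w)
        setattr(new, name, w + eta * incr)
    return new


def synaptic_fixed_point(post: np.ndarray, pre: np.ndarray,
                         gammas: np.ndarray | float | None = None) -> np.ndarray:
    """Closed-form synaptic fixed point for a given activity history.

    ``sig(w) = <(1 - 2*Gamma) post pre^T> / <post 1^T>`` with the
    modulation inside the numerator average only (pass ``gammas=None`` for
    unmodulated middle-layer synapses).  Ratios are clipped before the
    inverse sigmoid; entries with zero postsynaptic mass are undefined and
    returned as NaN (reported in the log).
    """
    T = post.shape[0]
    if gammas is None:
        num = _hebb(post, pre)
    else:
        mod = np.broadcast_to(1.0 - 2.0 * np.asarray(gammas, dtype=float), (T,))
        num = (post * mod[:, None]).T @ pre / T
    den = post.mean(axis=0)
    ratio = np.full_like(num, np.nan)
    ok = den > 0
    ratio[ok] = num[ok] / den[ok, None]
    if not np.all(ok):
        logger.warning("zero postsynaptic activity for units %s; fixed point "
                       "undefined there", np.where(~ok)[0].tolist())
    out = np.full_like(ratio, np.nan)
    out[ok] = sig_inv(ratio[ok])
    return out
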