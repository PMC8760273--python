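"""Variational inference for the binary-factor POMDP.

Free energy is evaluated over the whole past-to-present history of
observations, with posterior beliefs over states and decisions that are
updated *filter-style*: only the current-time belief is optimized at each
step, past beliefs are frozen.  Coordinate-wise minimization gives the
closed-form state and decision posteriors (per-factor softmax of summed
log-evidence), and the stationarity condition for the Dirichlet parameter
posteriors gives pseudo-count accumulation, with past decision counts
modulated by ``(1 - 2*Gamma)`` — the delayed risk signal that makes past
decisions count for (risk low) or against (risk high) the policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .pomdp import BeliefBlock, PROB_FLOOR, floor_log

__all__ = [
    "DirichletBank",
    "History",
    "FreeEnergyReport",
    "dirichlet_expectations",
    "infer_state",
    "infer_decision",
    "update_parameters",
    "free_energy",
]

logger = logging.getLogger("cannet")

#: smallest admissible Dirichlet concentration after anti-Hebbian decrements
CONC_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Dirichlet posteriors over the mappings
# ---------------------------------------------------------------------------


def dirichlet_expectations(conc: np.ndarray, mode: str = "digamma",
                           axis: str = "out") -> tuple[np.ndarray, np.ndarray]:
    """Mean and log-mean of per-column Dirichlet posteriors.

    ``conc`` has the factorized mapping shape ``(n_out, n_in, 2, 2)``.
    ``axis='out'`` treats each input column as a 2-outcome Dirichlet
    (the generative direction); ``axis='in'`` normalizes along the input
    values instead (the inverse/recognition direction encoded by the
    network's synapses).  ``mode='digamma'`` is the exact log-mean;
    ``mode='logratio'`` is the large-concentration approximation
    ``ln(theta / sum)``, whose error is O(1/sum) — this is the regime in
    which the network correspondence is exact.
    """
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0.0):
        raise ValueError("Dirichlet concentrations must be positive")
    ax = -2 if axis == "out" else -1
    total = conc.sum(axis=ax, keepdims=True)
    mean = conc / total
    if mode == "digamma":
        logmean = digamma(conc) - digamma(total)
    elif mode == "logratio":
        logmean = np.log(conc) - np.log(total)
    else:
        raise ValueError(f"unknown expectation mode {mode!r}")
    return mean, logmean


@dataclass
class DirichletBank:
    """Concentration parameters for the three mappings, plus their priors.

    Shapes follow the factorized mapping convention: ``a`` is
    ``(N_o, N_s, 2, 2)``, ``b`` is ``(N_s, N_s, 2, 2)`` and ``c`` is
    ``(N_d, N_s, 2, 2)``.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    a0: np.ndarray = None
    b0: np.ndarray = None
    c0: np.ndarray = None

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr <= 0.0):
                raise ValueError(f"concentration {name} must be positive")
            if getattr(self, name + "0") is None:
                setattr(self, name + "0", arr.copy())

    @classmethod
    def flat(cls, n_o: int, n_s: int, n_d: int, value: float = 1.0) -> "DirichletBank":
        return cls(
            a=np.full((n_o, n_s, 2, 2), value),
            b=np.full((n_s, n_s, 2, 2), value),
            c=np.full((n_d, n_s, 2, 2), value),
        )

    def mean(self, which: str, axis: str = "out") -> np.ndarray:
        return dirichlet_expectations(getattr(self, which), axis=axis)[0]

    def logmean(self, which: str, mode: str = "digamma",
                axis: str = "out") -> np.ndarray:
        return dirichlet_expectations(getattr(self, which), mode=mode, axis=axis)[1]

    def copy(self) -> "DirichletBank":
        return DirichletBank(self.a.copy(), self.b.copy(), self.c.copy(),
                             self.a0.copy(), self.b0.copy(), self.c0.copy())


# ---------------------------------------------------------------------------
# histories
# ---------------------------------------------------------------------------


@dataclass
class History:
    """Aligned block-vector history for one action phase.

    ``states[0]`` is the initial state belief; ``observations[t]`` and
    ``decisions[t]`` belong to time ``t + 1`` and pair with ``states[t + 1]``
    and previous state ``states[t]`` respectively.
    """

    observations: np.ndarray          # (T, 2, N_o)
    states: np.ndarray                # (T + 1, 2, N_s)
    decisions: np.ndarray | None = None  # (T, 2, N_d)

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.observations.shape[0] + 1:
            raise ValueError("states must have one more entry than observations")
        if self.decisions is not None:
            self.decisions = np.asarray(self.decisions, dtype=float)
            if self.decisions.shape[0] != self.observations.shape[0]:
                raise ValueError("decisions and observations must align")

    @property
    def T(self) -> int:
        return self.observations.shape[0]


# ---------------------------------------------------------------------------
# coordinate-wise posterior updates
# ---------------------------------------------------------------------------


def _softmax_block(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=0, keepdims=True)
    w = np.exp(logits - m)
    return w / w.sum(axis=0, keepdims=True)


def state_logits(o_t: np.ndarray, s_prev: np.ndarray, lnA: np.ndarray,
                 lnBinv: np.ndarray, lnD: np.ndarray) -> np.ndarray:
    """Per-factor 2-row logits for the state posterior."""
    term_A = np.einsum("ijmk,mi->kj", lnA, o_t)
    term_B = np.einsum("pjlk,lp->kj", lnBinv, s_prev)
    return term_A + term_B + lnD


def infer_state(o_t: BeliefBlock | np.ndarray, s_prev: BeliefBlock | np.ndarray,
                lnA: np.ndarray, lnBinv: np.ndarray,
                lnD: np.ndarray) -> BeliefBlock:
    """State posterior at the current time (the Bayesian-filter update).

    Per-factor softmax of summed log-evidence: observation evidence through
    the likelihood log-mean ``lnA`` (shape ``(N_o, N_s, 2, 2)``), the
    inverse-transition message from the frozen previous belief (``lnBinv``,
    shape ``(N_s, N_s, 2, 2)``, indexed ``[prev_factor, factor, l, k]``)
    and the log state prior ``lnD`` (shape ``(2, N_s)``).
    """
    o = o_t.block if isinstance(o_t, BeliefBlock) else np.asarray(o_t, float)
    s = s_prev.block if isinstance(s_prev, BeliefBlock) else np.asarray(s_prev, float)
    return BeliefBlock(_softmax_block(state_logits(o, s, lnA, lnBinv, lnD)))


def decision_logits(s_prev: np.ndarray, lnCinv: np.ndarray,
                    lnE: np.ndarray) -> np.ndarray:
    term_C = np.einsum("jklm,lj->mk", lnCinv, s_prev)
    return term_C + lnE


def infer_decision(s_prev: BeliefBlock | np.ndarray, lnCinv: np.ndarray,
                   lnE: np.ndarray) -> BeliefBlock:
    """Decision posterior given the previous state belief.

    ``lnCinv`` has shape ``(N_s, N_d, 2, 2)`` indexed
    ``[state_factor, decision_factor, l_state, m_decision]``; ``lnE`` is the
    log decision prior ``(2, N_d)``.
    """
    s = s_prev.block if isinstance(s_prev, BeliefBlock) else np.asarray(s_prev, float)
    return BeliefBlock(_softmax_block(decision_logits(s, lnCinv, lnE)))


# ---------------------------------------------------------------------------
# parameter learning
# ---------------------------------------------------------------------------


def update_parameters(bank: DirichletBank, history: History,
                      Gamma_t: float) -> DirichletBank:
    """Accumulate co-occurrence pseudo-counts from a history.

    Likelihood and transition counts are plain outer products of aligned
    beliefs.  Policy counts for *past* decisions are scaled by
    ``(1 - 2*Gamma_t)`` — the post hoc risk evaluation — while the
    current decision enters unmodulated.  Concentrations that an
    anti-Hebbian decrement would drive nonpositive are clamped at a small
    floor (the Dirichlet requires positivity; a warning is logged).
    """
    if history.T == 0:
        return bank.copy()
    if not 0.0 <= Gamma_t <= 1.0:
        raise ValueError("Gamma_t must lie in [0, 1]")
    new = bank.copy()
    o, s = history.observations, history.states
    new.a = new.a + np.einsum("tmi,tkj->ijmk", o, s[1:])
    new.b = new.b + np.einsum("tkj,tlp->jpkl", s[1:], s[:-1])
    if history.decisions is not None:
        d = history.decisions
        mod = 1.0 - 2.0 * Gamma_t
        if history.T > 1:
            past = np.einsum("tmk,tlj->kjml", d[:-1], s[:-2])
            new.c = new.c + mod * past
        new.c = new.c + np.einsum("mk,lj->kjml", d[-1], s[-2])
        if np.any(new.c <= 0.0):
            n_bad = int(np.sum(new.c <= 0.0))
            logger.warning(
                "anti-Hebbian update drove %d policy concentrations nonpositive; "
                "clamped at %g", n_bad, CONC_FLOOR)
            new.c = np.maximum(new.c, CONC_FLOOR)
    return new


# ---------------------------------------------------------------------------
# variational free energy
# ---------------------------------------------------------------------------


@dataclass
class FreeEnergyReport:
    total: float
    accuracy_state_term: float
    decision_term: float
    parameter_complexity: float
    per_time: np.ndarray
    #: entropy of the binarized risk; reported for completeness but not
    #: part of ``total`` (it does not enter the belief optimization)
    risk_entropy: float = 0.0

    def to_rows(self) -> list[tuple[int, str, float]]:
        """(time, term, value) rows for TSV export."""
        rows = [(t + 1, "per_time_total", float(v))
                for t, v in enumerate(self.per_time)]
        rows += [(0, "accuracy_state_term", self.accuracy_state_term),
                 (0, "decision_term", self.decision_term),
                 (0, "parameter_complexity", self.parameter_complexity),
                 (0, "total", self.total)]
        return rows


def _dirichlet_kl(conc: np.ndarray, conc0: np.ndarray) -> float:
    """KL divergence between posterior and prior per-column Dirichlets,
    summed over all factor pairs and input columns (normalizing over the
    output-value axis)."""
    s, s0 = conc.sum(axis=-2), conc0.sum(axis=-2)
    term = (gammaln(s) - gammaln(s0)
            - (gammaln(conc).sum(axis=-2) - gammaln(conc0).sum(axis=-2)))
    term = term + ((conc - conc0) * (digamma(conc) - digamma(s[..., None, :]))
                   ).sum(axis=-2)
    return float(term.sum())


def free_energy(history: History, lnA: np.ndarray, lnB: np.ndarray,
                lnC: np.ndarray | None = None, lnD: np.ndarray | None = None,
                lnE: np.ndarray | None = None, Gamma_t: float = 0.0, *,
                form: str = "forward", bank: DirichletBank | None = None,
                include_parameter_complexity: bool = False) -> FreeEnergyReport:
    """Variational free energy of a history under frozen (filtered) beliefs.

    Two algebraically linked evaluations are supported:

    * ``form='forward'`` uses the generative log-mappings: ``lnB`` has the
      forward shape ``(N_s, N_s, 2, 2)`` (``[factor, prev_factor, k, l]``)
      and ``lnC`` the forward ``(N_d, N_s, 2, 2)``; priors do not appear.
    * ``form='inverse'`` uses inverse mappings plus explicit log-priors:
      ``lnB`` is ``(N_s_prev, N_s, 2, 2)``, ``lnC`` is ``(N_s, N_d, 2, 2)``
      and ``lnD``/``lnE`` are required.  For single-input-factor models the
      two forms agree identically when the inverse mappings satisfy the
      Bayes identity.

    The risk enters past decision terms through ``(1 - 2*Gamma_t)``; the
    current step is always unmodulated (its consequences are unseen).
    Parameter complexity (the Dirichlet KL, which grows only
    logarithmically with history length) is added only on request.
    """
    T = history.T
    o, s = history.observations, history.states
    per_time = np.zeros(T)
    state_total = 0.0
    decision_total = 0.0
    for t in range(1, T + 1):
        st, sp = s[t], s[t - 1]
        ent = float(np.sum(st * floor_log(st)))
        ev_A = np.einsum("ijmk,mi->kj", lnA, o[t - 1])
        if form == "forward":
            ev_B = np.einsum("jpkl,lp->kj", lnB, sp)
            state_t = ent - float(np.sum(st * (ev_A + ev_B)))
        elif form == "inverse":
            ev_B = np.einsum("pjlk,lp->kj", lnB, sp)
            state_t = ent - float(np.sum(st * (ev_A + ev_B + lnD)))
        else:
            raise ValueError(f"unknown form {form!r}")
        per_time[t - 1] += state_t
        state_total += state_t
        if history.decisions is not None and lnC is not None:
            dt = history.decisions[t - 1]
            gamma = 0.0 if t == T else Gamma_t
            mod = 1.0 - 2.0 * gamma
            d_ent = float(np.sum(dt * floor_log(dt)))
            if form == "forward":
                ev_C = np.einsum("kjml,lj->mk", lnC, sp)
                dec_t = d_ent - mod * float(np.sum(dt * ev_C))
            else:
                ev_C = np.einsum("jklm,lj->mk", lnC, sp)
                dec_t = d_ent - float(np.sum(dt * (mod * ev_C + lnE)))
            per_time[t - 1] += dec_t
            decision_total += dec_t
    param = 0.0
    if include_parameter_complexity:
        if bank is None:
            raise ValueError("parameter complexity requires a DirichletBank")
        param = (_dirichlet_kl(bank.a, bank.a0) + _dirichlet_kl(bank.b, bank.b0)
                 + _dirichlet_kl(bank.c, bank.c0))
    g = min(max(Gamma_t, PROB_FLOOR), 1.0 - PROB_FLOOR)
    return FreeEnergyReport(
        total=state_total + decision_total + param,
        accuracy_state_term=state_total,
        decision_term=decision_total,
        parameter_complexity=param,
        per_time=per_time,
        risk_entropy=float(-g * np.log(g) - (1 - g) * np.log(1 - g)),
    )


def free_energy_to_tsv(report: FreeEnergyReport, path) -> None:
    import pandas as pd

    pd.DataFrame(report.to_rows(), columns=["time", "term", "value"]).to_csv(
        path, sep="\t", index=False)
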