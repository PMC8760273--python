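"""Dictionary between network quantities and Bayesian beliefs.

The bindings (the ``sig``/``sig^{-1}`` pairs):

* sensory weights  ``W_l  <->  sig^{-1}`` of the likelihood mean columns,
* recurrent weights ``K_l <->  sig^{-1}`` of the inverse-transition mean,
* output weights   ``V_l  <->  sig^{-1}`` of the inverse-policy mean,
* threshold perturbations ``phi <-> ln D`` and ``psi <-> ln E``,
* modulator ``Gamma(t) <->`` risk function ``Gamma_t``,
* initial weights scaled by the inverse learning rates ``lam`` ``<->``
  Dirichlet prior concentrations.

Under these bindings the sigmoid activity fixed point *is* the per-factor
softmax posterior update, and the network cost equals the variational free
energy up to residuals that are constant in the optimized variables
(parameter complexity, the order-one weight term, and — for modulated past
steps — a modulated-threshold cross term, each reported separately).  The
identity is exact in the log-ratio expectation regime; with exact digamma
expectations the gap is bounded by the reciprocal total concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import (DirichletBank, History, dirichlet_expectations,
                        infer_decision, infer_state)
from .network import (SynapticWeights, ThresholdSpec, activity_fixed_point,
                      sig, sig_inv, synaptic_fixed_point)
from .pomdp import PROB_FLOOR, floor_log

__all__ = [
    "CorrespondenceMap",
    "bank_to_inverse_maps",
    "beliefs_to_weights",
    "weights_to_beliefs",
    "run_bayes",
    "run_network",
    "verify_equivalence",
    "EquivalenceReport",
]


@dataclass
class CorrespondenceMap:
    """Explicit record of the weight/belief bindings for reporting."""

    bindings: tuple = (
        ("W_l", "sig^-1(A_1l^T)"),
        ("K_l", "sig^-1(Binv_1l^T)"),
        ("V_l", "sig^-1(Cinv_1l^T)"),
        ("phi", "ln D"),
        ("psi", "ln E"),
        ("Gamma(t)", "Gamma_t"),
        ("lam * sig(w_init)", "prior concentrations"),
    )


def bank_to_inverse_maps(bank: DirichletBank, mode: str = "logratio"
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-expectation mappings in the form the posterior updates consume.

    Returns ``(lnA, lnBinv, lnCinv)``: the likelihood log-mean in the
    generative direction and the transition/policy log-means in the inverse
    (recognition) direction, rearranged to the inverse-mapping index
    convention ``[input_factor_of_original, output_factor, l, k]``.
    """
    lnA = dirichlet_expectations(bank.a, mode=mode, axis="out")[1]
    lnB_in = dirichlet_expectations(bank.b, mode=mode, axis="in")[1]
    lnC_in = dirichlet_expectations(bank.c, mode=mode, axis="in")[1]
    lnBinv = np.transpose(lnB_in, (1, 0, 3, 2))
    lnCinv = np.transpose(lnC_in, (1, 0, 3, 2))
    return lnA, lnBinv, lnCinv


def beliefs_to_weights(bank: DirichletBank, D1: np.ndarray, E1: np.ndarray,
                       lam: tuple[float, float, float] = (1.0, 1.0, 1.0)
                       ) -> tuple[SynapticWeights, ThresholdSpec]:
    """Apply the dictionary: Dirichlet means become synaptic strengths,
    log-priors become threshold perturbations.

    Raises if a prior entry is 0 or 1 (its log would be undefined).
    """
    D1, E1 = np.asarray(D1, float), np.asarray(E1, float)
    for name, p in (("D", D1), ("E", E1)):
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError(f"prior {name} entries must lie strictly in (0, 1)")
    A = bank.mean("a", axis="out")     # [i, j, k, l]
    B_in = bank.mean("b", axis="in")   # [j, p, k, l] -> P(prev_p = 1-l | s_j = 1-k)
    C_in = bank.mean("c", axis="in")   # [k, j, m, l]
    weights = SynapticWeights(
        W1=sig_inv(A[:, :, 0, 0].T), W0=sig_inv(A[:, :, 0, 1].T),
        K1=sig_inv(B_in[:, :, 0, 0]), K0=sig_inv(B_in[:, :, 1, 0]),
        V1=sig_inv(C_in[:, :, 0, 0]), V0=sig_inv(C_in[:, :, 1, 0]),
        lam_W=lam[0], lam_K=lam[1], lam_V=lam[2],
    )
    thresholds = ThresholdSpec.from_priors(D1, E1)
    return weights, thresholds


def weights_to_beliefs(weights: SynapticWeights, thresholds: ThresholdSpec
                       ) -> dict[str, np.ndarray]:
    """Invert the dictionary: read posterior means and priors off a network."""
    n_o, n_s, n_d = weights.n_o, weights.n_x, weights.n_y
    A = np.empty((n_o, n_s, 2, 2))
    A[:, :, 0, 0] = sig(weights.W1).T
    A[:, :, 0, 1] = sig(weights.W0).T
    A[:, :, 1, :] = 1.0 - A[:, :, 0, :]
    B_in = np.empty((n_s, n_s, 2, 2))
    B_in[:, :, 0, 0] = sig(weights.K1)
    B_in[:, :, 1, 0] = sig(weights.K0)
    B_in[:, :, :, 1] = 1.0 - B_in[:, :, :, 0]
    C_in = np.empty((n_d, n_s, 2, 2))
    C_in[:, :, 0, 0] = sig(weights.V1)
    C_in[:, :, 1, 0] = sig(weights.V0)
    C_in[:, :, :, 1] = 1.0 - C_in[:, :, :, 0]
    return {
        "A_mean": A,
        "Binv_mean": B_in,
        "Cinv_mean": C_in,
        "D1": np.exp(thresholds.phi1),
        "E1": np.exp(thresholds.psi1),
    }


# ---------------------------------------------------------------------------
# paired runs
# ---------------------------------------------------------------------------


def run_bayes(o_seq: np.ndarray, s0_p1: np.ndarray, bank: DirichletBank,
              D1: np.ndarray, E1: np.ndarray, mode: str = "logratio"
              ) -> tuple[np.ndarray, np.ndarray]:
    """Filtered posterior sequence from the variational updates.

    ``o_seq``: (T, N_o) binary observations.  Returns state beliefs
    ``(T + 1, 2, N_s)`` (entry 0 is the initial belief) and decision
    beliefs ``(T, 2, N_d)``.
    """
    lnA, lnBinv, lnCinv = bank_to_inverse_maps(bank, mode=mode)
    D1 = np.asarray(D1, float)
    E1 = np.asarray(E1, float)
    lnD = floor_log(np.stack([D1, 1 - D1]))
    lnE = floor_log(np.stack([E1, 1 - E1]))
    T = o_seq.shape[0]
    n_s, n_d = lnBinv.shape[1], lnCinv.shape[1]
    s_seq = np.empty((T + 1, 2, n_s))
    d_seq = np.empty((T, 2, n_d))
    s_seq[0] = np.stack([s0_p1, 1 - s0_p1])
    for t in range(T):
        o_block = np.stack([o_seq[t], 1 - o_seq[t]]).astype(float)
        d_seq[t] = infer_decision(s_seq[t], lnCinv, lnE).block
        s_seq[t + 1] = infer_state(o_block, s_seq[t], lnA, lnBinv, lnD).block
    return s_seq, d_seq


def run_network(o_seq: np.ndarray, x0: np.ndarray, weights: SynapticWeights,
                thresholds: ThresholdSpec) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state activity sequence of the network on the same input.

    Returns middle-layer rates ``(T + 1, N_x)`` (entry 0 is the initial
    condition) and output rates ``(T, N_y)``; the recurrent and output
    drives use the one-step-delayed middle layer.
    """
    T = o_seq.shape[0]
    x_seq = np.empty((T + 1, weights.n_x))
    y_seq = np.empty((T, weights.n_y))
    x_seq[0] = x0
    for t in range(T):
        x, y = activity_fixed_point(o_seq[t].astype(float), x_seq[t],
                                    weights, thresholds)
        x_seq[t + 1] = x
        y_seq[t] = y
    return x_seq, y_seq


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


@dataclass
class EquivalenceReport:
    max_state_activity_gap: float
    max_decision_activity_gap: float
    max_cost_gap_per_step: float
    max_raw_cost_gap_per_step: float
    plasticity_vs_counts_gap: float
    mode: str
    T: int

    def to_dict(self) -> dict:
        return {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in self.__dict__.items()}


def _modulated_threshold_residual(y_block: np.ndarray, weights: SynapticWeights,
                                  gamma: float) -> float:
    """Cross term by which the modulated cost and free energy differ on past
    steps: the modulation multiplies the inverse-policy log-evidence on the
    Bayes side but not the threshold's weight part on the network side."""
    # ln of the 0-valued previous-state component: ln(1 - sig(V_l))
    ln_comp = np.stack([np.log1p(-np.clip(sig(weights.V1), None, 1 - PROB_FLOOR)),
                        np.log1p(-np.clip(sig(weights.V0), None, 1 - PROB_FLOOR))])
    sums = ln_comp.sum(axis=2)  # (2, N_y): sum_j ln Cinv[j,k][0-val, m]
    return -2.0 * gamma * float(np.sum(y_block * sums))


def verify_equivalence(bank: DirichletBank, D1: np.ndarray, E1: np.ndarray,
                       o_seq: np.ndarray, x0: np.ndarray | None = None,
                       Gamma_t: float = 0.0, mode: str = "logratio"
                       ) -> EquivalenceReport:
    """Drive the network and the Bayesian scheme with the same observations
    from mapped initial conditions and report their discrepancies.

    The cost comparison excludes parameter complexity, the order-one weight
    residual and (for modulated past steps) the modulated-threshold cross
    term; the raw per-step gap is reported alongside.
    """
    o_seq = np.asarray(o_seq)
    n_s = bank.b.shape[0]
    if x0 is None:
        x0 = np.asarray(D1, float).copy()
    s_seq, d_seq = run_bayes(o_seq, x0, bank, D1, E1, mode=mode)
    weights, thresholds = beliefs_to_weights(bank, D1, E1)
    x_seq, y_seq = run_network(o_seq, x0, weights, thresholds)

    gap_x = float(np.max(np.abs(x_seq[1:] - s_seq[1:, 0, :])))
    gap_y = float(np.max(np.abs(y_seq - d_seq[:, 0, :])))

    # per-step cost vs free energy on the shared (network) trajectory
    T = o_seq.shape[0]
    o_blocks = np.stack([o_seq, 1 - o_seq], axis=1).astype(float)
    lnA, lnBinv, lnCinv = bank_to_inverse_maps(bank, mode=mode)
    lnD = floor_log(np.stack([np.asarray(D1, float), 1 - np.asarray(D1, float)]))
    lnE = floor_log(np.stack([np.asarray(E1, float), 1 - np.asarray(E1, float)]))
    from .network import cost_integrand

    max_gap = 0.0
    max_raw = 0.0
    for t in range(1, T + 1):
        gamma = 0.0 if t == T else Gamma_t  # the current window is unmodulated
        F_step = _modulated_free_energy_step(
            o_blocks[t - 1], s_seq[t - 1], s_seq[t], d_seq[t - 1],
            lnA, lnBinv, lnCinv, lnD, lnE, gamma)
        L_step = cost_integrand(o_seq[t - 1].astype(float), x_seq[t],
                                y_seq[t - 1], x_seq[t - 1], weights,
                                thresholds, gamma)
        raw = abs(L_step - F_step)
        resid = _modulated_threshold_residual(d_seq[t - 1], weights, gamma)
        max_raw = max(max_raw, raw)
        max_gap = max(max_gap, abs(L_step - F_step - resid))

    # plasticity vs pseudo-count identity on the shared trajectory
    from .inference import update_parameters
    tiny = DirichletBank.flat(bank.a.shape[0], n_s, bank.c.shape[0], value=1e-12)
    hist = History(o_blocks, s_seq, d_seq)
    counts = update_parameters(tiny, hist, 0.0)
    w_fp = synaptic_fixed_point(s_seq[1:, 0, :], o_blocks[:, 0, :])
    a_ratio = dirichlet_expectations(counts.a, mode="logratio", axis="out")[0]
    gap_p = float(np.max(np.abs(sig(w_fp) - a_ratio[:, :, 0, 0].T)))
    k_fp = synaptic_fixed_point(s_seq[1:, 0, :], s_seq[:-1, 0, :])
    b_ratio = dirichlet_expectations(counts.b, mode="logratio", axis="in")[0]
    gap_p = max(gap_p, float(np.max(np.abs(sig(k_fp) - b_ratio[:, :, 0, 0]))))

    return EquivalenceReport(
        max_state_activity_gap=gap_x,
        max_decision_activity_gap=gap_y,
        max_cost_gap_per_step=max_gap,
        max_raw_cost_gap_per_step=max_raw,
        plasticity_vs_counts_gap=gap_p,
        mode=mode,
        T=T,
    )


def _modulated_free_energy_step(o_block, s_prev, s_t, d_t, lnA, lnBinv, lnCinv,
                                lnD, lnE, gamma: float) -> float:
    """One past-step free-energy contribution with explicit modulation."""
    ev_A = np.einsum("ijmk,mi->kj", lnA, o_block)
    ev_B = np.einsum("pjlk,lp->kj", lnBinv, s_prev)
    state = float(np.sum(s_t * (floor_log(s_t) - ev_A - ev_B - lnD)))
    ev_C = np.einsum("jklm,lj->mk", lnCinv, s_prev)
    mod = 1.0 - 2.0 * gamma
    dec = float(np.sum(d_t * (floor_log(d_t) - mod * ev_C - lnE)))
    return state + dec
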