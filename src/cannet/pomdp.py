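"""Discrete generative model with binary factors.

The world model is a partially observable Markov decision process in which
every observation, hidden state and decision is a vector of binary factors.
Beliefs over such vectors are carried as *block vectors*: the probabilities
that each factor equals 1, stacked on top of their complements (the
probabilities that each factor equals 0).  All mappings between variables
(likelihood ``A``, transition ``B``, policy ``C``) factorize into 2x2
column-stochastic submatrices, one per (output factor, input factor) pair;
the full mapping is the outer product of the submatrices.

Array conventions used throughout the package
---------------------------------------------
* block vectors are arrays of shape ``(2, N)``; row 0 holds the
  "factor = 1" probabilities, row 1 the "factor = 0" complements.  The
  flattened order (all 1-components, then all 0-components) is the order
  used for serialization and for the network layer pairing.
* factorized mappings are arrays of shape ``(n_out, n_in, 2, 2)``;
  ``sub[i, j, k, l]`` is the probability-like weight that output factor
  ``i`` takes value ``1 - k`` given input factor ``j`` has value ``1 - l``
  (array index 0 <-> logical value 1).  Columns (axis 2) sum to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "PROB_FLOOR",
    "BeliefBlock",
    "FactorizedMapping",
    "PriorVector",
    "RiskSample",
    "TrajectorySample",
    "expand_mapping",
    "contract_mapping",
    "bayes_invert",
    "fictive_decision_loglik",
    "sample_generative_process",
    "floor_log",
    "save_mapping_archive",
    "load_mapping_archive",
]

#: global probability floor applied before any logarithm; the model's logs
#: are undefined at exact 0/1, a single floor keeps all modules consistent.
PROB_FLOOR = 1e-9

#: clip bound for ratios entering the inverse sigmoid (synaptic fixed points).
RATIO_CLIP = 1e-6

BLOCK_ORDER = "ones-then-zeros"


def floor_log(p: np.ndarray) -> np.ndarray:
    """Elementwise ``log`` with the global probability floor applied."""
    return np.log(np.maximum(p, PROB_FLOOR))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BeliefBlock:
    """Probabilities that each of ``N`` binary factors equals 1, with
    complements; the common currency for states, decisions and activity."""

    block: np.ndarray  # shape (2, N)

    def __post_init__(self) -> None:
        self.block = np.asarray(self.block, dtype=float)
        if self.block.ndim != 2 or self.block.shape[0] != 2:
            raise ValueError("belief block must have shape (2, N)")

    @classmethod
    def from_p1(cls, p1: np.ndarray) -> "BeliefBlock":
        p1 = np.asarray(p1, dtype=float)
        return cls(np.stack([p1, 1.0 - p1]))

    @classmethod
    def from_onehot(cls, values: np.ndarray) -> "BeliefBlock":
        """Degenerate belief at a binary realization (vector over factors)."""
        return cls.from_p1(np.asarray(values, dtype=float))

    @property
    def p1(self) -> np.ndarray:
        return self.block[0]

    @property
    def p0(self) -> np.ndarray:
        return self.block[1]

    @property
    def n_factors(self) -> int:
        return self.block.shape[1]

    def flattened(self) -> np.ndarray:
        """1-components first, then 0-components."""
        return self.block.reshape(-1)

    def validate(self, atol: float = 1e-12) -> None:
        if np.any(self.block < -atol) or np.any(self.block > 1 + atol):
            raise ValueError("belief entries outside [0, 1]")
        if np.max(np.abs(self.block.sum(axis=0) - 1.0)) > atol:
            raise ValueError("belief components do not sum to 1")


@dataclass
class FactorizedMapping:
    """Stochastic mapping stored as per-factor-pair 2x2 submatrices.

    ``kind`` is one of ``"A"`` (likelihood: state -> observation),
    ``"B"`` (transition: previous state -> state) or ``"C"`` (policy:
    previous state -> decision).
    """

    kind: str
    sub: np.ndarray  # (n_out, n_in, 2, 2)

    def __post_init__(self) -> None:
        self.sub = np.asarray(self.sub, dtype=float)
        if self.sub.ndim != 4 or self.sub.shape[2:] != (2, 2):
            raise ValueError("submatrix array must have shape (n_out, n_in, 2, 2)")

    @property
    def n_out(self) -> int:
        return self.sub.shape[0]

    @property
    def n_in(self) -> int:
        return self.sub.shape[1]

    def validate(self, atol: float = 1e-12) -> None:
        cols = self.sub.sum(axis=2)
        if np.max(np.abs(cols - 1.0)) > atol:
            raise ValueError(f"{self.kind}: submatrix columns must sum to 1")

    @classmethod
    def flat(cls, kind: str, n_out: int, n_in: int) -> "FactorizedMapping":
        return cls(kind, np.full((n_out, n_in, 2, 2), 0.5))

    @classmethod
    def identity(cls, kind: str, n: int, fidelity: float = 1.0) -> "FactorizedMapping":
        """Diagonal pairs copy the input factor with probability ``fidelity``;
        off-diagonal pairs are flat (uninformative)."""
        sub = np.full((n, n, 2, 2), 0.5)
        diag = np.array([[fidelity, 1 - fidelity], [1 - fidelity, fidelity]])
        for i in range(n):
            sub[i, i] = diag
        return cls(kind, sub)

    @classmethod
    def random(cls, kind: str, n_out: int, n_in: int, rng: np.random.Generator,
               low: float = 0.05, high: float = 0.95) -> "FactorizedMapping":
        p1 = rng.uniform(low, high, size=(n_out, n_in, 2))
        sub = np.stack([p1, 1.0 - p1], axis=2)  # (n_out, n_in, 2(k), 2(l))
        return cls(kind, sub)

    def log(self) -> np.ndarray:
        return floor_log(self.sub)


@dataclass
class PriorVector:
    """Prior belief over a binary-factor variable (state prior D or
    decision prior E), stored as a belief block."""

    values: BeliefBlock

    @classmethod
    def uniform(cls, n: int) -> "PriorVector":
        return cls(BeliefBlock.from_p1(np.full(n, 0.5)))

    @classmethod
    def from_p1(cls, p1: np.ndarray) -> "PriorVector":
        return cls(BeliefBlock.from_p1(p1))

    @property
    def block(self) -> np.ndarray:
        return self.values.block

    def log(self) -> np.ndarray:
        return floor_log(self.block)


@dataclass
class RiskSample:
    """Risk level ``Gamma`` in [0, 1] and a binary draw with
    ``Prob[gamma = 1] = Gamma``."""

    Gamma: float
    gamma: int

    @classmethod
    def draw(cls, Gamma: float, rng: np.random.Generator) -> "RiskSample":
        if not 0.0 <= Gamma <= 1.0:
            raise ValueError("Gamma must lie in [0, 1]")
        return cls(float(Gamma), int(rng.random() < Gamma))


@dataclass
class TrajectorySample:
    """One forward draw of the generative process: binary observations,
    hidden states and decisions per time step (axes: time, factor)."""

    observations: np.ndarray  # (T, N_o) in {0, 1}
    states: np.ndarray        # (T, N_s)
    decisions: np.ndarray | None = None  # (T, N_d) or None
    risks: np.ndarray | None = None

    @property
    def T(self) -> int:
        return self.observations.shape[0]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _check_mapping(m: FactorizedMapping) -> None:
    if m.sub.shape[0] != m.n_out or m.sub.shape[1] != m.n_in:
        raise ValueError("factor counts inconsistent with submatrix grid")


def expand_mapping(m: FactorizedMapping, normalize: bool = True) -> np.ndarray:
    """Expand the per-pair submatrices into the full outer-product mapping.

    Returns an array of shape ``(n_out, 2, 2**n_in)``: the weight that
    output factor ``i`` takes value 1-k given the joint input assignment
    (assignments enumerated with input factor 0 as the most significant
    bit; bit 0 encodes logical value 1, matching the array convention).
    With ``normalize=True`` each column is normalized over k so entries
    are conditional probabilities; with ``normalize=False`` entries are
    the raw products of submatrix entries (which preserves the product
    structure exactly and makes the expansion invertible).
    """
    _check_mapping(m)
    n_out, n_in = m.n_out, m.n_in
    n_assign = 2 ** n_in
    out = np.ones((n_out, 2, n_assign))
    for a in range(n_assign):
        # digit j of assignment a: index l of input factor j
        for j in range(n_in):
            l = (a >> (n_in - 1 - j)) & 1
            out[:, :, a] *= m.sub[:, j, :, l]
    if normalize:
        out = out / out.sum(axis=1, keepdims=True)
    return out


def contract_mapping(expanded: np.ndarray, n_in: int) -> np.ndarray:
    """Recover the per-pair submatrices from an *unnormalized* expansion.

    Inverse of ``expand_mapping(..., normalize=False)`` for mappings whose
    submatrices have column-stochastic 2x2 blocks with distinct columns.
    """
    n_out = expanded.shape[0]
    sub = np.empty((n_out, n_in, 2, 2))
    base = expanded[:, :, 0]  # all-zero-index assignment (all factors = 1)
    for j in range(n_in):
        a_j = 1 << (n_in - 1 - j)  # factor j flipped to index 1 (value 0)
        u = expanded[:, :, a_j] / base  # sub[j,k,1] / sub[j,k,0]
        # column l=0 entries s_k satisfy s_1 + s_0 = 1 and u_1 s_1 + u_0 s_0 = 1
        u1, u0 = u[:, 0], u[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            s1 = np.where(np.abs(u1 - u0) > 1e-12, (1.0 - u0) / (u1 - u0), 0.5)
        s0 = 1.0 - s1
        sub[:, j, 0, 0] = s1
        sub[:, j, 1, 0] = s0
        sub[:, j, 0, 1] = u1 * s1
        sub[:, j, 1, 1] = u0 * s0
    return sub


def bayes_invert(m: FactorizedMapping, prior: PriorVector) -> np.ndarray:
    """Bayes-invert a factorized mapping under the prior on its outputs.

    For the transition mapping this is ``B^+ = B^T diag[D]^{-1}`` (and
    ``C^+ = C^T diag[E]^{-1}`` for the policy mapping), applied per
    factor-pair submatrix with a flat prior on the mapping's inputs.

    Returns an inverse-mapping array of shape ``(n_in, n_out, 2, 2)`` with
    ``inv[j, i, l, k] = m.sub[i, j, k, l] / prior[i][k]``, so that per pair
    ``inv^T * diag[prior] == sub`` holds exactly.
    """
    _check_mapping(m)
    pb = prior.block  # (2, n_out)
    if np.any(pb <= 0.0):
        bad = np.argwhere(pb <= 0.0)
        raise ZeroDivisionError(
            f"prior has nonpositive entries at (component, factor) {bad.tolist()}"
        )
    # inv[j, i, l, k] = sub[i, j, k, l] / prior[k, i]
    inv = np.transpose(m.sub, (1, 0, 3, 2)) / pb.T[None, :, None, :]
    return inv


def fictive_decision_loglik(C: FactorizedMapping, s_prev: BeliefBlock,
                            Gamma: float) -> np.ndarray:
    """Risk-switched log-weight of each decision component.

    The generative model conditions past decisions on the current binarized
    risk: decisions come from the policy mapping ``C`` when the risk draw is
    0 and from its elementwise reciprocal (up to normalization) when it is
    1.  Averaging over the risk and dropping the normalizer leaves the
    log-weight ``(1 - 2*Gamma) * ln(C s_prev)`` per decision component,
    where ``ln C`` is taken elementwise (mean-field expectation) and the
    probability floor is applied before the logarithm.

    Returns an array of shape ``(2, n_decision_factors)``.
    """
    if not 0.0 <= Gamma <= 1.0:
        raise ValueError("Gamma must lie in [0, 1]")
    s_prev.validate(atol=1e-9)
    logC = C.log()  # (n_d, n_s, 2, 2)
    contrib = np.einsum("kjml,lj->mk", logC, s_prev.block)
    return (1.0 - 2.0 * Gamma) * contrib


def _conditional_p1(sub: np.ndarray, given: np.ndarray) -> np.ndarray:
    """P(output factor = 1 | binary input vector), via the normalized
    outer-product rule.  ``sub``: (n_out, n_in, 2, 2); ``given``: (n_in,)
    in {0, 1} (or batched (R, n_in)).  Returns (n_out,) (or (R, n_out))."""
    given = np.asarray(given)
    l_idx = (1 - given).astype(int)  # value 1 -> index 0
    if given.ndim == 1:
        picked = sub[:, np.arange(sub.shape[1]), :, l_idx]  # (n_in, n_out, 2)
        logp = floor_log(picked).sum(axis=0)  # (n_out, 2)
        m = logp.max(axis=1, keepdims=True)
        w = np.exp(logp - m)
        return (w[:, 0] / w.sum(axis=1))
    return np.stack([_conditional_p1(sub, g) for g in given])


def sample_generative_process(
    A: FactorizedMapping,
    B: FactorizedMapping | Callable[[np.ndarray | None], FactorizedMapping],
    D: PriorVector,
    policy: Callable[[np.random.Generator, np.ndarray, int], np.ndarray] | None,
    T: int,
    seed: int | np.random.Generator,
) -> TrajectorySample:
    """Draw one trajectory from the generative process.

    ``s_1`` is drawn per factor from the prior ``D``; each observation
    factor from the likelihood given the current joint state; each next
    state from the (possibly decision-conditioned) transition.  ``policy``
    maps ``(rng, previous_state, t)`` to a binary decision vector; pass
    ``None`` for a decision-free chain.  ``B`` may be a mapping or a
    callable of the previous decision returning one.  Deterministic given
    the seed.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if policy is not None and not callable(policy):
        raise TypeError("policy must be callable (rng, s_prev, t) -> decision vector")

    n_s = D.block.shape[1]
    states = np.empty((T, n_s), dtype=np.int8)
    obs = np.empty((T, A.n_out), dtype=np.int8)
    decisions = [] if policy is not None else None

    s = (rng.random(n_s) < D.block[0]).astype(np.int8)
    for t in range(T):
        if t > 0:
            if callable(B) and not isinstance(B, FactorizedMapping):
                Bt = B(decisions[-1] if decisions else None)
            else:
                Bt = B
            p1 = _conditional_p1(Bt.sub, s)
            s = (rng.random(n_s) < p1).astype(np.int8)
        states[t] = s
        p_o = _conditional_p1(A.sub, s)
        obs[t] = (rng.random(A.n_out) < p_o).astype(np.int8)
        if policy is not None:
            try:
                d = np.asarray(policy(rng, s.copy(), t), dtype=np.int8)
            except TypeError as exc:
                raise TypeError("policy callback must accept (rng, s_prev, t)") from exc
            decisions.append(d)
    return TrajectorySample(
        observations=obs,
        states=states,
        decisions=np.asarray(decisions) if decisions is not None else None,
    )


# ---------------------------------------------------------------------------
# serialization: directory of CSV matrices + JSON sidecar
# ---------------------------------------------------------------------------


def save_mapping_archive(path: str | Path, mappings: dict[str, FactorizedMapping],
                         priors: dict[str, PriorVector] | None = None) -> None:
    """Write mappings/priors to a directory of CSV matrices with a JSON
    sidecar recording factor counts and the block-ordering convention."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta: dict = {"block_order": BLOCK_ORDER, "mappings": {}, "priors": {}}
    for name, m in mappings.items():
        meta["mappings"][name] = {"kind": m.kind, "n_out": m.n_out, "n_in": m.n_in}
        # one CSV per (k, l) submatrix component, each an n_out x n_in matrix
        for k in range(2):
            for l in range(2):
                np.savetxt(path / f"{name}_{k}{l}.csv", m.sub[:, :, k, l],
                           delimiter=",")
    for name, p in (priors or {}).items():
        meta["priors"][name] = {"n": p.block.shape[1]}
        np.savetxt(path / f"{name}.csv", p.block, delimiter=",")
    (path / "archive.json").write_text(json.dumps(meta, indent=2))


def load_mapping_archive(path: str | Path) -> tuple[dict[str, FactorizedMapping],
                                                    dict[str, PriorVector]]:
    path = Path(path)
    meta = json.loads((path / "archive.json").read_text())
    mappings: dict[str, FactorizedMapping] = {}
    priors: dict[str, PriorVector] = {}
    for name, info in meta["mappings"].items():
        sub = np.empty((info["n_out"], info["n_in"], 2, 2))
        for k in range(2):
            for l in range(2):
                sub[:, :, k, l] = np.loadtxt(
                    path / f"{name}_{k}{l}.csv", delimiter=","
                ).reshape(info["n_out"], info["n_in"])
        mappings[name] = FactorizedMapping(info["kind"], sub)
    for name, info in meta["priors"].items():
        block = np.loadtxt(path / f"{name}.csv", delimiter=",").reshape(2, info["n"])
        priors[name] = PriorVector(BeliefBlock(block))
    return mappings, priors
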