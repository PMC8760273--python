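"""Maze training protocol: action phases, delayed-risk learning phases,
multi-session training and metrics.

The agent is the canonical two-layer network.  Each decision period it
observes the 11 x 11 window around its position, updates the middle layer
(its state belief; the recurrent input carries the previous period's
activity), reads a 256-way decision distribution from the output layer,
samples one decision, and executes its four actions.  After the period
the environment scores the rightward displacement with a delayed risk
level.

Learning is run in belief space, as the equivalence licenses: the agent
carries Dirichlet pseudo-counts for its mappings and, at each session end,
adds the risk-modulated co-occurrence counts of realized decisions with
previous-state activity (the delayed post hoc evaluation; counts from bad
periods enter with a negative weight and are floored).  Synaptic weights
are then rebuilt from the count ratios through the weight/belief
dictionary, so the action phase always runs as the plain sigmoid network.
Sensory and recurrent counts are accumulated at a much smaller scale to
keep the focus on policy learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from numba import njit

from .inference import CONC_FLOOR, DirichletBank
from .maze import MazeGrid, N_DECISIONS, RiskParams, decode_decision
from .network import SynapticWeights, ThresholdSpec, sig

__all__ = [
    "AgentConfig",
    "MazeAgent",
    "SessionLog",
    "TrainingCurve",
    "decision_prior_vector",
    "build_agent",
    "run_action_phase",
    "run_learning_phase",
    "train",
    "weight_trajectory_to_tsv",
]


def decision_prior_vector(E_right: float = 1.0 / N_DECISIONS,
                          E_left: float | None = None,
                          E_up: float | None = None,
                          E_down: float | None = None) -> np.ndarray:
    """Per-element decision prior, constant within each first-action group
    (the prior probability of selecting a decision whose next step moves in
    that direction)."""
    default = 1.0 / N_DECISIONS
    by_dir = {"right": E_right,
              "left": default if E_left is None else E_left,
              "up": default if E_up is None else E_up,
              "down": default if E_down is None else E_down}
    E1 = np.empty(N_DECISIONS)
    for k in range(N_DECISIONS):
        E1[k] = by_dir[decode_decision(k)[0]]
    return E1


@dataclass
class AgentConfig:
    window: int = 11
    identity_mix: float = 0.95   # likelihood init: mix * identity + (1 - mix) * flat
    #: per-session weight of the session-averaged policy statistics, in
    #: pseudo-count units (every session contributes equally, regardless of
    #: its length — the averages of the plasticity rules)
    lr_V: float = 300.0
    lr_WK: float = 0.3           # sensory/recurrent session weight
    prior_counts_V: float = 5.0   # initial policy concentration per entry
    prior_counts_WK: float = 100.0
    #: per-session retention of accumulated counts (1.0 = perfect memory;
    #: < 1 gives exponential forgetting toward the prior)
    retention: float = 1.0
    risk: RiskParams = field(default_factory=RiskParams)
    delayed_modulation: bool = True

    @property
    def n_units(self) -> int:
        return self.window * self.window


@dataclass
class MazeAgent:
    weights: SynapticWeights
    thresholds: ThresholdSpec
    config: AgentConfig
    bank: DirichletBank = None
    D1: np.ndarray = None
    E1: np.ndarray = None
    x0: np.ndarray = None
    # cached drive terms, refreshed after plasticity
    _Wd: np.ndarray = None
    _Kd: np.ndarray = None
    _Vd: np.ndarray = None
    _hd: np.ndarray = None
    _md: np.ndarray = None

    def __post_init__(self) -> None:
        if self.weights is None:
            self.rebuild_weights()
        else:
            self.refresh_cache()
        if self.x0 is None:
            self.x0 = np.full(self.weights.n_x, 0.5)

    def refresh_cache(self) -> None:
        w, thr = self.weights, self.thresholds
        h1, h0 = thr.h(w)
        m1, m0 = thr.m(w)
        self._Wd = w.W1 - w.W0
        self._Kd = w.K1 - w.K0
        self._Vd = w.V1 - w.V0
        self._hd = h1 - h0
        self._md = m1 - m0

    def rebuild_weights(self) -> None:
        """Rebuild the synaptic matrices from the pseudo-count ratios via
        the weight/belief dictionary."""
        from .equivalence import beliefs_to_weights

        self.weights, self.thresholds = beliefs_to_weights(
            self.bank, self.D1, self.E1)
        self.refresh_cache()

    def copy(self) -> "MazeAgent":
        return MazeAgent(self.weights.copy(), self.thresholds, self.config,
                         self.bank.copy() if self.bank is not None else None,
                         None if self.D1 is None else self.D1.copy(),
                         None if self.E1 is None else self.E1.copy(),
                         self.x0.copy())


def build_agent(E1: np.ndarray | None = None, D1: np.ndarray | None = None,
                config: AgentConfig | None = None) -> MazeAgent:
    """Standard initialization.

    Sensory counts encode a near-identity likelihood (so the sensory
    weights start at the inverse sigmoid of a near-identity stochastic
    matrix), recurrent and policy counts are flat (weights zero), and the
    thresholds carry the given priors.  Deterministic: no randomness in
    initialization."""
    config = config or AgentConfig()
    n = config.n_units
    if E1 is None:
        E1 = np.full(N_DECISIONS, 1.0 / N_DECISIONS)
    E1 = np.asarray(E1, float)
    if D1 is None:
        D1 = np.full(n, 0.5)
    D1 = np.asarray(D1, float)
    # likelihood counts: identity pairs at the mixing fidelity, others flat
    fid = config.identity_mix + (1 - config.identity_mix) * 0.5
    a = np.full((n, n, 2, 2), 0.5)
    idx = np.arange(n)
    a[idx, idx, 0, 0] = fid
    a[idx, idx, 1, 0] = 1 - fid
    a[idx, idx, 0, 1] = 1 - fid
    a[idx, idx, 1, 1] = fid
    bank = DirichletBank(
        a=config.prior_counts_WK * a,
        b=np.full((n, n, 2, 2), 0.5 * config.prior_counts_WK),
        c=np.full((N_DECISIONS, n, 2, 2), config.prior_counts_V),
    )
    agent = MazeAgent(weights=None, thresholds=None, config=config, bank=bank,
                      D1=D1, E1=E1, x0=D1.copy())
    return agent


# ---------------------------------------------------------------------------
# session logs
# ---------------------------------------------------------------------------


@dataclass
class SessionLog:
    """Record of one action phase.

    Per-period records (positions at period starts, sampled decision
    indices, risk levels) plus session-averaged activity sums and the
    Hebbian/homeostatic accumulators the learning phase consumes.  Full
    per-period activity is kept only when ``record_activity`` was set.
    """

    positions: np.ndarray        # (periods + 1, 2) period-start positions
    decisions: np.ndarray        # (periods,) indices in [0, 256)
    gammas: np.ndarray           # (periods,) risk per period
    mods: np.ndarray             # (periods,) modulation factor applied
    duration: int                # steps taken
    success: bool
    T: int
    n_periods: int
    steps_final_period: int
    session_index: int = 0
    seed: int | None = None
    sum_x: np.ndarray = None     # (N_x,) summed middle rates over periods
    sum_y: np.ndarray = None     # (N_y,) summed output rates
    accum: dict = field(default_factory=dict)
    x_seq: np.ndarray | None = None
    y_seq: np.ndarray | None = None

    @property
    def failed(self) -> bool:
        return not self.success

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "period": np.arange(self.n_periods),
            "row": self.positions[:-1, 0],
            "col": self.positions[:-1, 1],
            "decision": self.decisions,
            "gamma": self.gammas,
        }).to_csv(path, sep="\t", index=False)


#: decision index -> four (dr, dc) moves, in the base-4 action code order
_DECISION_MOVES = np.zeros((N_DECISIONS, 4, 2), dtype=np.int64)
_MOVE_OF = {"up": (-1, 0), "down": (1, 0), "left": (0, -1), "right": (0, 1)}
for _k in range(N_DECISIONS):
    for _a, _name in enumerate(decode_decision(_k)):
        _DECISION_MOVES[_k, _a] = _MOVE_OF[_name]


@njit(cache=True)
def _session_kernel(padded, maze_h, maze_w, half, start_r, start_c, T,
                    Wd, Kd, Vd, hd, md, x0, moves,
                    g_succ, g_part, g_fail, d_star, kernel_seed):
    """Jitted period loop: observe, fixed-point activity, one categorical
    decision draw over the one-hot block, four movement steps with wall
    rejection, and the delayed risk of the period."""
    np.random.seed(kernel_seed)
    n = x0.shape[0]
    n_dec = Vd.shape[0]
    maxp = T // 4 + 1
    o_hist = np.empty((maxp, n))
    x_hist = np.empty((maxp + 1, n))
    y_hist = np.empty((maxp, n_dec))
    decisions = np.empty(maxp, np.int64)
    gammas = np.empty(maxp)
    positions = np.empty((maxp + 1, 2), np.int64)
    x_hist[0] = x0
    r, c = start_r, start_c
    positions[0, 0] = r
    positions[0, 1] = c
    steps = 0
    p = 0
    success = c == maze_w - 1
    steps_final = 0
    win = 2 * half + 1
    while not success and steps < T:
        o = padded[r:r + win, c:c + win].copy().reshape(n)
        x_prev = x_hist[p]
        x = 1.0 / (1.0 + np.exp(-(Wd @ o + Kd @ x_prev + hd)))
        # within a period the observation is constant and the middle layer
        # sits at its fixed point, so the output reads the current-period
        # x (the one-period delay applies to the recurrent pathway)
        y = 1.0 / (1.0 + np.exp(-(Vd @ x + md)))
        o_hist[p] = o
        x_hist[p + 1] = x
        y_hist[p] = y
        u = np.random.random() * y.sum()
        acc = 0.0
        k = n_dec - 1
        for i in range(n_dec):
            acc += y[i]
            if u < acc:
                k = i
                break
        decisions[p] = k
        col0 = c
        steps_this = 0
        for a in range(4):
            nr = r + moves[k, a, 0]
            nc = c + moves[k, a, 1]
            if 0 <= nr < maze_h and 0 <= nc < maze_w \
                    and padded[nr + half, nc + half] > 0.5:
                r, c = nr, nc
            steps += 1
            steps_this += 1
            if c == maze_w - 1:
                success = True
                break
            if steps >= T:
                break
        dx = c - col0
        if dx >= d_star:
            gammas[p] = g_succ
        elif dx > 0:
            gammas[p] = g_part
        else:
            gammas[p] = g_fail
        positions[p + 1, 0] = r
        positions[p + 1, 1] = c
        steps_final = steps_this
        p += 1
    return (o_hist[:p], x_hist[:p + 1], y_hist[:p], decisions[:p],
            gammas[:p], positions[:p + 1], steps, success, steps_final)


def run_action_phase(agent: MazeAgent, maze: MazeGrid, T: int = 20_000,
                     seed: int | np.random.Generator = 0,
                     record_activity: bool = False,
                     start: tuple[int, int] | None = None) -> SessionLog:
    """One action phase: observe / infer / decide / act until the goal or
    the step budget ``T`` is reached.  Deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = agent.config
    half = cfg.window // 2
    H, W = maze.cells.shape
    padded = np.zeros((H + 2 * half, W + 2 * half))
    padded[half:half + H, half:half + W] = maze.cells

    pos = start if start is not None else maze.start
    if not maze.cells[pos]:
        raise ValueError("start position is on a wall")
    n = cfg.n_units
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    risk = cfg.risk
    (o_hist, x_hist, y_hist, decisions, gammas, positions, steps, success,
     steps_final) = _session_kernel(
        padded, H, W, half, int(pos[0]), int(pos[1]), T,
        agent._Wd, agent._Kd, agent._Vd, agent._hd, agent._md,
        agent.x0, _DECISION_MOVES,
        risk.Gamma_success, risk.Gamma_partial, risk.Gamma_fail,
        int(risk.d_star), kernel_seed)
    p = len(decisions)
    sum_y = y_hist.sum(axis=0) if p else np.zeros(N_DECISIONS)

    gam = gammas[:p]
    if cfg.delayed_modulation:
        mods = 1.0 - 2.0 * gam
    else:
        # immediate ablation: a period's plasticity sees the *previous*
        # period's risk (the most recent available at plasticity time)
        shifted = np.concatenate([[0.5], gam[:-1]]) if p else gam
        mods = 1.0 - 2.0 * shifted

    # session-end accumulators (BLAS batch forms of the plasticity averages)
    o_h, x_h, xp_h = o_hist[:p], x_hist[1:p + 1], x_hist[:p]
    accum = {}
    if p:
        accum["heb_W1"] = x_h.T @ o_h
        accum["heb_W0"] = (1.0 - x_h).T @ o_h
        accum["heb_K1"] = x_h.T @ xp_h
        accum["heb_K0"] = (1.0 - x_h).T @ xp_h
        accum["post_x"] = x_h.sum(axis=0)
        heb_V1 = np.zeros((N_DECISIONS, n))
        np.add.at(heb_V1, decisions[:p], mods[:, None] * x_h)
        accum["heb_V1"] = heb_V1
        accum["heb_V0"] = (mods[:, None] * x_h).sum(axis=0)[None, :] - heb_V1
        accum["post_V1"] = np.bincount(decisions[:p], minlength=N_DECISIONS).astype(float)
        accum["post_V0"] = p - accum["post_V1"]
        accum["w1sum"] = np.bincount(decisions[:p], weights=mods,
                                     minlength=N_DECISIONS)
        accum["modsum"] = float(mods.sum())
        accum["sum_o"] = o_h.sum(axis=0)
    return SessionLog(
        positions=np.asarray(positions), decisions=decisions[:p].copy(),
        gammas=gam.copy(), mods=mods.copy(), duration=steps, success=success,
        T=T, n_periods=p, steps_final_period=steps_final,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
        sum_x=x_h.sum(axis=0) if p else np.zeros(n), sum_y=sum_y,
        accum=accum,
        x_seq=x_h.copy() if record_activity else None,
        y_seq=y_hist[:p].copy() if record_activity else None,
    )


def run_learning_phase(agent: MazeAgent, log: SessionLog,
                       lr_V: float | None = None,
                       lr_WK: float | None = None) -> MazeAgent:
    """Batch parameter learning from one session's accumulators.

    Adds the session's co-occurrence pseudo-counts to the agent's
    Dirichlet bank — policy counts carry the per-period risk modulation
    ``(1 - 2*Gamma)`` and use the realized one-hot decisions — then
    rebuilds the synaptic matrices from the count ratios.  Count
    increments are scaled by the learning rates (small for the sensory and
    recurrent mappings).  Concentrations driven nonpositive by
    anti-Hebbian decrements are floored.  Mutates and returns the agent."""
    if log.n_periods == 0:
        return agent
    P = float(log.n_periods)
    eta_V = agent.config.lr_V if lr_V is None else lr_V
    eta_WK = agent.config.lr_WK if lr_WK is None else lr_WK
    acc = log.accum
    bank = agent.bank
    post_x = acc["post_x"]
    sum_o = acc["sum_o"]

    # likelihood counts: outer products of observation and state blocks
    da = np.empty_like(bank.a)
    da[:, :, 0, 0] = acc["heb_W1"].T
    da[:, :, 0, 1] = acc["heb_W0"].T
    da[:, :, 1, 0] = post_x[None, :] - acc["heb_W1"].T
    da[:, :, 1, 1] = (P - post_x)[None, :] - acc["heb_W0"].T
    # transition counts: current state against previous state
    db = np.empty_like(bank.b)
    db[:, :, 0, 0] = acc["heb_K1"]
    db[:, :, 0, 1] = post_x[:, None] - acc["heb_K1"]
    db[:, :, 1, 0] = acc["heb_K0"]
    db[:, :, 1, 1] = (P - post_x)[:, None] - acc["heb_K0"]
    # policy counts: realized decisions against previous state, modulated
    dc = np.empty_like(bank.c)
    dc[:, :, 0, 0] = acc["heb_V1"]
    dc[:, :, 0, 1] = acc["w1sum"][:, None] - acc["heb_V1"]
    dc[:, :, 1, 0] = acc["heb_V0"]
    dc[:, :, 1, 1] = (acc["modsum"] - acc["w1sum"])[:, None] - acc["heb_V0"]

    rho = agent.config.retention
    bank.a = np.maximum(bank.a0 + rho * (bank.a - bank.a0) + eta_WK * da / P,
                        CONC_FLOOR)
    bank.b = np.maximum(bank.b0 + rho * (bank.b - bank.b0) + eta_WK * db / P,
                        CONC_FLOOR)
    bank.c = np.maximum(bank.c0 + rho * (bank.c - bank.c0) + eta_V * dc / P,
                        CONC_FLOOR)
    agent.rebuild_weights()
    return agent


# ---------------------------------------------------------------------------
# multi-session training
# ---------------------------------------------------------------------------


@dataclass
class TrainingCurve:
    durations: np.ndarray   # (n_sessions,)
    successes: np.ndarray   # (n_sessions,) bool

    @property
    def n_sessions(self) -> int:
        return len(self.durations)

    def failure_probability(self, window: int = 10) -> np.ndarray:
        """Mean failure rate over consecutive session windows."""
        fails = (~self.successes).astype(float)
        n = len(fails) // window
        return fails[:n * window].reshape(n, window).mean(axis=1)

    def failure_over(self, sessions: slice) -> float:
        return float((~self.successes[sessions]).mean())

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "session": np.arange(1, self.n_sessions + 1),
            "duration": self.durations,
            "success": self.successes.astype(int),
        }).to_csv(path, sep="\t", index=False)


def train(agent: MazeAgent, maze_source, n_sessions: int = 100,
          seed: int = 0, T: int = 20_000, collect_logs: bool = False,
          weight_trajectory: list | None = None) -> TrainingCurve | tuple:
    """Alternate action and learning phases over ``n_sessions``.

    ``maze_source`` may be a single maze, a list cycled per session, or a
    callable ``(session_index) -> MazeGrid``.  Every stochastic draw flows
    from ``seed`` (one child generator per session), so curves are
    reproducible bit for bit.  Pass a list as ``weight_trajectory`` to
    collect per-session convergence rows ``(session, matrix, frobenius
    norm, max abs change)``."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    durations = np.empty(n_sessions, dtype=np.int64)
    successes = np.empty(n_sessions, dtype=bool)
    logs = []
    for s in range(n_sessions):
        if isinstance(maze_source, MazeGrid):
            maze = maze_source
        elif callable(maze_source):
            maze = maze_source(s)
        else:
            maze = maze_source[s % len(maze_source)]
        rng = np.random.default_rng([int(seed), s])
        log = run_action_phase(agent, maze, T=T, seed=rng)
        log.session_index = s
        durations[s] = log.duration
        successes[s] = log.success
        if collect_logs:
            logs.append(log)
        if weight_trajectory is not None:
            before = {k: getattr(agent.weights, k).copy()
                      for k in ("W1", "W0", "K1", "K0", "V1", "V0")}
        run_learning_phase(agent, log)
        if weight_trajectory is not None:
            for name, old in before.items():
                new = getattr(agent.weights, name)
                weight_trajectory.append(
                    (s, name, float(np.linalg.norm(new)),
                     float(np.max(np.abs(new - old)))))
    curve = TrainingCurve(durations, successes)
    return (curve, logs) if collect_logs else curve


def weight_trajectory_to_tsv(rows: list, path) -> None:
    """Write collected weight-trajectory rows as TSV (for convergence
    plots): session, matrix, Frobenius norm, max abs change."""
    import pandas as pd

    pd.DataFrame(rows, columns=["session", "matrix", "frobenius_norm",
                                "max_abs_change"]).to_csv(path, sep="\t",
                                                          index=False)
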