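"""Deterministic fixture bundle used across the test suite.

Small enumerable models (exact posteriors computable by brute force), a
hand-built 5 x 5 maze, and a canned activity log from a miniature agent.
Everything is generated programmatically from the seed.
"""

from __future__ import annotations

import numpy as np

from .experiment import AgentConfig, build_agent, run_action_phase
from .maze import MazeGrid
from .pomdp import FactorizedMapping, PriorVector

__all__ = ["HAND_MAZE_TEXT", "hand_maze", "one_factor_pomdp", "make_fixtures"]

#: 5 x 5 maze with a single corridor and one detour; start on the left edge.
HAND_MAZE_TEXT = """\
#####
S...#
###.#
#....
#####
"""


def hand_maze() -> MazeGrid:
    cells = np.array([[ch in ".S" for ch in row]
                      for row in HAND_MAZE_TEXT.strip("\n").split("\n")])
    return MazeGrid(cells, (1, 0))


def one_factor_pomdp(rng: np.random.Generator):
    """A single-state-factor model whose exact posterior is enumerable."""
    A = FactorizedMapping.random("A", 1, 1, rng)
    B = FactorizedMapping.random("B", 1, 1, rng)
    C = FactorizedMapping.random("C", 2, 1, rng)
    D = PriorVector.from_p1(rng.uniform(0.2, 0.8, size=1))
    E = PriorVector.from_p1(rng.uniform(0.2, 0.8, size=2))
    return A, B, C, D, E


def make_fixtures(seed: int = 0) -> dict:
    """Emit the bundle: tiny POMDPs, the hand maze, and a canned activity
    log from a window-3 agent on it.  Regeneration is deterministic."""
    rng = np.random.default_rng(seed)
    A, B, C, D, E = one_factor_pomdp(rng)
    maze = hand_maze()
    agent = build_agent(config=AgentConfig(window=3))
    log = run_action_phase(agent, maze, T=200, seed=seed, record_activity=True)
    return {
        "pomdp": {"A": A, "B": B, "C": C, "D": D, "E": E},
        "maze": maze,
        "agent": agent,
        "activity_log": log,
    }
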