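"""Maze environment: the generative process the agent acts in.

A rectangular grid of pathway/wall cells.  The agent starts at the left
edge and must reach any pathway cell in the rightmost column within a step
budget.  It senses the surrounding 11 x 11 window of cells as binary
inputs (1 = pathway, cells beyond the grid read as wall), and acts in
four-step decisions: each decision is one of 4^4 = 256 sequences over
(up, down, left, right).  A move into a wall is rejected but still
consumes the step, so every decision lasts exactly four steps.

After each decision period the environment emits a delayed risk level:
0 if the agent advanced rightwards by at least the displacement threshold,
0.45 if it advanced but fell short, 0.55 if it did not advance at all.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ACTIONS",
    "MazeGrid",
    "DecisionCode",
    "RiskParams",
    "generate_maze",
    "observe",
    "decode_decision",
    "encode_decision",
    "step",
    "evaluate_risk",
    "read_maze",
    "write_maze",
]

#: action order as used in the decision code digits
ACTIONS = ("up", "down", "left", "right")
_MOVES = {"up": (-1, 0), "down": (1, 0), "left": (0, -1), "right": (0, 1)}

N_ACTION_STEPS = 4
N_DECISIONS = len(ACTIONS) ** N_ACTION_STEPS  # 256


@dataclass
class MazeGrid:
    """Grid over {pathway, wall} with a start on the left edge; the goal is
    any pathway cell in the rightmost column."""

    cells: np.ndarray  # (H, W) bool: True = pathway
    start: tuple[int, int]
    certificate: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    def is_goal(self, pos: tuple[int, int]) -> bool:
        return pos[1] == self.cells.shape[1] - 1

    def solvable(self) -> bool:
        """Breadth-first search certificate from start to the right edge."""
        H, W = self.cells.shape
        prev: dict[tuple[int, int], tuple[int, int] | None] = {self.start: None}
        q = deque([self.start])
        goal = None
        while q:
            pos = q.popleft()
            if pos[1] == W - 1:
                goal = pos
                break
            for dr, dc in _MOVES.values():
                nxt = (pos[0] + dr, pos[1] + dc)
                if (0 <= nxt[0] < H and 0 <= nxt[1] < W
                        and self.cells[nxt] and nxt not in prev):
                    prev[nxt] = pos
                    q.append(nxt)
        if goal is None:
            return False
        path = [goal]
        while prev[path[-1]] is not None:
            path.append(prev[path[-1]])
        self.certificate = path[::-1]
        return True


@dataclass
class DecisionCode:
    """A decision index in [0, 255] and its four-action sequence."""

    index: int
    actions: tuple[str, str, str, str]

    @classmethod
    def from_index(cls, index: int) -> "DecisionCode":
        return cls(index, decode_decision(index))

    @classmethod
    def from_actions(cls, actions) -> "DecisionCode":
        return cls(encode_decision(actions), tuple(actions))


@dataclass
class RiskParams:
    """Delayed risk levels and the rightward displacement threshold
    (cells per evaluation period)."""

    Gamma_success: float = 0.0
    Gamma_partial: float = 0.45
    Gamma_fail: float = 0.55
    d_star: int = 2

    def __post_init__(self) -> None:
        for g in (self.Gamma_success, self.Gamma_partial, self.Gamma_fail):
            if not 0.0 <= g <= 1.0:
                raise ValueError("risk levels must lie in [0, 1]")


# ---------------------------------------------------------------------------
# maze generation
# ---------------------------------------------------------------------------


def _carve(height: int, width: int, rng: np.random.Generator,
           extra_opening_density: float,
           horizontal_bias: float = 2.0) -> np.ndarray:
    """Randomized depth-first corridor carving on the odd lattice, plus a
    configurable density of extra openings (loops).

    ``horizontal_bias`` weights east/west over north/south moves during
    carving, favouring east-west corridors: this gives the maze enough
    rightward structure for a right-biased policy to exploit while leaving
    an unbiased random walker lost."""
    cells = np.zeros((height, width), dtype=bool)
    nodes_r = np.arange(1, height, 2)
    nodes_c = np.arange(1, width, 2)
    start = (int(rng.choice(nodes_r)), int(rng.choice(nodes_c)))
    cells[start] = True
    stack = [start]
    while stack:
        r, c = stack[-1]
        neigh = [(r + dr, c + dc) for dr, dc in ((-2, 0), (2, 0), (0, -2), (0, 2))
                 if 1 <= r + dr < height - 1 and 1 <= c + dc < width - 1
                 and not cells[r + dr, c + dc]]
        if not neigh:
            stack.pop()
            continue
        w = np.array([horizontal_bias if dc else 1.0 for dr, dc in
                      [(n[0] - r, n[1] - c) for n in neigh]])
        nr, nc = neigh[rng.choice(len(neigh), p=w / w.sum())]
        cells[(r + nr) // 2, (c + nc) // 2] = True
        cells[nr, nc] = True
        stack.append((nr, nc))
    # extra openings: knock down interior walls that separate two pathways
    if extra_opening_density > 0:
        interior = np.argwhere(~cells[1:-1, 1:-1]) + 1
        for r, c in interior:
            horiz = cells[r, c - 1] and cells[r, c + 1]
            vert = cells[r - 1, c] and cells[r + 1, c]
            if (horiz or vert) and rng.random() < extra_opening_density:
                cells[r, c] = True
    return cells


def _baffle(height: int, width: int, rng: np.random.Generator,
            gaps: int, clutter: float) -> MazeGrid:
    """Vertical baffle walls with sparse gaps and cluttered compartments.

    Every second interior column is a wall pierced by ``gaps`` randomly
    placed openings; one designated gap per wall is chained by a protected
    vertical corridor so the maze is solvable by construction, and the
    remaining compartment cells are blocked with probability ``clutter``.
    An unbiased random walker diffuses too slowly through the sequence of
    bottlenecks to reach the right edge within the usual step budget,
    while a rightward-biased walker passes wall after wall.
    """
    cells = np.ones((height, width), dtype=bool)
    cells[0, :] = False
    cells[-1, :] = False
    wall_cols = list(range(2, width - 1, 2))
    interior = np.arange(1, height - 1)
    chain_rows: dict[int, int] = {}
    for c in wall_cols:
        cells[:, c] = False
        rows = rng.choice(interior, size=min(gaps, len(interior)),
                          replace=False)
        cells[rows, c] = True
        chain_rows[c] = int(rows[int(rng.integers(len(rows)))])
    start_row = int(rng.integers(1, height - 1))
    exit_row = int(rng.integers(1, height - 1))
    chain_rows[0] = start_row
    chain_rows[width - 1] = exit_row
    protected = np.zeros((height, width), dtype=bool)
    cols = [0] + wall_cols + [width - 1]
    for cl, cr in zip(cols, cols[1:]):
        rl, rr = chain_rows[cl], chain_rows[cr]
        lo, hi = min(rl, rr), max(rl, rr)
        protected[lo:hi + 1, cl + 1] = True
    for c in range(1, width - 1, 2):
        block = (rng.random(len(interior)) < clutter) & ~protected[interior, c]
        cells[interior[block], c] = False
    cells[start_row, 0] = True
    cells[exit_row, width - 1] = True
    return MazeGrid(cells, (start_row, 0))


def generate_maze(height: int = 21, width: int = 41,
                  seed: int | np.random.Generator = 0,
                  style: str = "baffle", gaps: int = 1, clutter: float = 0.3,
                  extra_opening_density: float = 0.12,
                  max_retries: int = 20) -> MazeGrid:
    """Generate a solvable random maze; deterministic per seed.

    Two families are available.  The default ``style='baffle'`` (vertical
    walls with sparse gaps, cluttered compartments) is calibrated so that
    an unbiased random walker typically fails to cross within the standard
    step budget while a rightward-biased walker succeeds — the property
    the training task needs.  ``style='dfs'`` gives classic randomized
    depth-first corridor carving with ``extra_opening_density`` loops.
    Dimensions must be odd and at least 5; generation retries (bounded)
    until the breadth-first solvability certificate passes.
    """
    if height < 5 or width < 5:
        raise ValueError("maze dimensions must be at least 5")
    if height % 2 == 0 or width % 2 == 0:
        raise ValueError("maze dimensions must be odd")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_retries):
        if style == "baffle":
            maze = _baffle(height, width, rng, gaps, clutter)
        elif style == "dfs":
            cells = _carve(height, width, rng, extra_opening_density)
            start_row = int(rng.choice(np.arange(1, height, 2)))
            cells[start_row, 0] = True
            cells[start_row, 1] = True
            for _ in range(2):  # two exits on the right edge
                exit_row = int(rng.choice(np.arange(1, height, 2)))
                cells[exit_row, width - 1] = True
                cells[exit_row, width - 2] = True
            maze = MazeGrid(cells, (start_row, 0))
        else:
            raise ValueError(f"unknown maze style {style!r}")
        if maze.solvable():
            return maze
    raise RuntimeError("maze generation retry budget exhausted")


# ---------------------------------------------------------------------------
# observation, decisions, movement, risk
# ---------------------------------------------------------------------------


def observe(maze: MazeGrid, position: tuple[int, int], window: int = 11) -> np.ndarray:
    """Binary row-major window of cells centred on the agent (1 = pathway);
    cells outside the grid read as wall."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not maze.cells[position]:
        raise ValueError(f"position {position} is on a wall")
    half = window // 2
    H, W = maze.cells.shape
    padded = np.zeros((H + 2 * half, W + 2 * half), dtype=bool)
    padded[half:half + H, half:half + W] = maze.cells
    r, c = position[0] + half, position[1] + half
    win = padded[r - half:r + half + 1, c - half:c + half + 1]
    return win.reshape(-1).astype(np.float64)


def decode_decision(index: int) -> tuple[str, str, str, str]:
    """Base-4 positional code over (up, down, left, right); the most
    significant digit is the first step."""
    if not 0 <= index < N_DECISIONS:
        raise ValueError(f"decision index {index} out of range [0, {N_DECISIONS})")
    digits = []
    rem = index
    for _ in range(N_ACTION_STEPS):
        digits.append(ACTIONS[rem % 4])
        rem //= 4
    return tuple(reversed(digits))


def encode_decision(actions) -> int:
    actions = tuple(actions)
    if len(actions) != N_ACTION_STEPS:
        raise ValueError("a decision is a four-action sequence")
    index = 0
    for a in actions:
        index = index * 4 + ACTIONS.index(a)
    return index


def step(maze: MazeGrid, position: tuple[int, int], action: str) -> tuple[int, int]:
    """Move one cell if the target is a pathway; a rejected move leaves the
    position unchanged (and still consumes the step)."""
    dr, dc = _MOVES[action]
    nxt = (position[0] + dr, position[1] + dc)
    H, W = maze.cells.shape
    if 0 <= nxt[0] < H and 0 <= nxt[1] < W and maze.cells[nxt]:
        return nxt
    return position


def evaluate_risk(x_displacement: int, params: RiskParams | None = None) -> float:
    """Delayed risk from the rightward displacement over one period."""
    params = params or RiskParams()
    if x_displacement >= params.d_star:
        return params.Gamma_success
    if x_displacement > 0:
        return params.Gamma_partial
    return params.Gamma_fail


# ---------------------------------------------------------------------------
# plain-text maze format
# ---------------------------------------------------------------------------


def write_maze(maze: MazeGrid, path: str | Path) -> None:
    rows = []
    for r in range(maze.cells.shape[0]):
        row = "".join(
            "S" if (r, c) == maze.start else ("." if maze.cells[r, c] else "#")
            for c in range(maze.cells.shape[1]))
        rows.append(row)
    Path(path).write_text("\n".join(rows) + "\n")


def read_maze(path: str | Path) -> MazeGrid:
    lines = Path(path).read_text().strip("\n").split("\n")
    H, W = len(lines), len(lines[0])
    cells = np.zeros((H, W), dtype=bool)
    start = None
    for r, line in enumerate(lines):
        if len(line) != W:
            raise ValueError("ragged maze file")
        for c, ch in enumerate(line):
            if ch == "S":
                start = (r, c)
                cells[r, c] = True
            elif ch == ".":
                cells[r, c] = True
            elif ch != "#":
                raise ValueError(f"unknown cell character {ch!r}")
    if start is None:
        raise ValueError("maze file lacks a start cell")
    return MazeGrid(cells, start)
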