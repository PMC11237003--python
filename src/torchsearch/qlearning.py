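"""Tabular Q-learning of efficient torchlight search.

The agent learns action values ``Q(s, a, c)`` indexed by current location
``s``, move destination ``a`` and episode cue ``c``, with the standard
temporal-difference update

    Q(s,a,c) <- Q(s,a,c) + alpha * [r + gamma * max_a' Q(s',a',c) - Q(s,a,c)]

under an epsilon-greedy policy (epsilon = 0.5 by default: half the moves
maximize Q, half explore uniformly among the neighbors).  Because the Uniform
condition rewards the target only after the cue has been visited, and the
gate is not part of the table index, the environment is non-Markovian for
the agent; what it can learn is that moves toward the cue are valuable on
average.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import (
    ConditionSpec,
    SpatialLayout,
    env_step,
    sample_episode_setup,
)

__all__ = [
    "AgentParams",
    "QTable",
    "Episode",
    "GridSearchResult",
    "q_update",
    "select_action",
    "run_episode",
    "train_agent",
    "evaluate_agent",
    "grid_search",
    "extract_sequences",
]


@dataclass(frozen=True)
class AgentParams:
    """Learning rate, discount factor and exploration probability."""

    alpha: float
    gamma: float
    epsilon: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.5 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0.5, 1]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


class QTable:
    """Action values on a dense ``(state, destination, cue)`` array.

    Entries exist only for ``destination in neighbors(state)`` and ``cue`` in
    the layout's cue states; indexing anything else raises ``IndexError``.
    Values start at zero.
    """

    def __init__(self, layout: SpatialLayout) -> None:
        self.layout = layout
        self._cue_index = {c: i for i, c in enumerate(layout.cue_states)}
        self._values = np.zeros((8, 8, len(layout.cue_states)))
        self._valid = np.zeros((8, 8), dtype=bool)
        for s in layout.states:
            for a in layout.adjacency[s]:
                self._valid[s, a] = True

    def _check(self, s: int, a: int, c: int) -> int:
        if c not in self._cue_index:
            raise IndexError(f"{c} is not a cue state")
        if not (0 <= s < 8) or not self._valid[s, a]:
            raise IndexError(f"({s}, {a}) is not a valid state/action pair")
        return self._cue_index[c]

    def __getitem__(self, key: tuple[int, int, int]) -> float:
        s, a, c = key
        return float(self._values[s, a, self._check(s, a, c)])

    def __setitem__(self, key: tuple[int, int, int], value: float) -> None:
        s, a, c = key
        self._values[s, a, self._check(s, a, c)] = value

    def max_next(self, s_next: int, c: int) -> float:
        """``max_a' Q(s', a', c)`` over the neighbors of ``s_next``."""
        ci = self._cue_index[c]
        nbrs = self.layout.adjacency[s_next]
        return float(self._values[s_next, list(nbrs), ci].max())

    def copy(self) -> "QTable":
        out = QTable(self.layout)
        out._values = self._values.copy()
        return out

    @property
    def values(self) -> np.ndarray:
        """Dense view of the table (invalid entries are structural zeros)."""
        return self._values


@dataclass(frozen=True)
class Episode:
    """One episode's trajectory and outcome."""

    visited_states: tuple[int, ...]
    cue_state: int
    target_state: int
    rewarded: bool
    n_steps: int

    def __post_init__(self) -> None:
        if self.n_steps != len(self.visited_states) - 1:
            raise ValueError("n_steps must equal len(visited_states) - 1")


@dataclass(frozen=True)
class GridSearchResult:
    grid: pd.DataFrame  # columns: alpha, gamma, mean_test_steps
    best_params: AgentParams
    best_mean_steps: float
    grid_mean_steps: float


def q_update(
    Q: QTable,
    s: int,
    a: int,
    c: int,
    r: int,
    s_next: int,
    params: AgentParams,
) -> float:
    """Apply one temporal-difference update; returns the new entry."""
    old = Q[s, a, c]
    target = r + params.gamma * Q.max_next(s_next, c)
    new = old + params.alpha * (target - old)
    Q[s, a, c] = new
    return new


def select_action(
    Q: QTable,
    s: int,
    c: int,
    epsilon: float,
    rng: np.random.Generator,
) -> int:
    """Epsilon-greedy move selection with uniform random tie-breaking."""
    nbrs = Q.layout.adjacency[s]
    if rng.random() < epsilon:
        return int(nbrs[rng.integers(len(nbrs))])
    ci = Q._cue_index[c]
    q = Q._values[s, list(nbrs), ci]
    best = np.flatnonzero(q == q.max())
    return int(nbrs[best[rng.integers(len(best))]])


def run_episode(
    Q: QTable,
    spec: ConditionSpec,
    params: AgentParams,
    layout: SpatialLayout,
    rng: np.random.Generator,
    learn: bool = True,
) -> Episode:
    """Run one episode; updates ``Q`` in place only when ``learn`` is True.

    The episode terminates at the first reward or at the condition's step
    cap, whichever comes first.
    """
    # Hot path: operate on the raw arrays rather than the checked accessors.
    values = Q._values
    adjacency = layout.adjacency
    cue_index = Q._cue_index
    state = sample_episode_setup(layout, spec, rng)
    s = state.current_state
    c = state.cue_state
    ci = cue_index[c]
    alpha, gamma, epsilon = params.alpha, params.gamma, params.epsilon
    visited = [s]
    rewarded = False
    for _ in range(spec.step_cap):
        nbrs = adjacency[s]
        if rng.random() < epsilon:
            a = nbrs[rng.integers(len(nbrs))]
        else:
            q = values[s, list(nbrs), ci]
            best = np.flatnonzero(q == q.max())
            a = nbrs[best[rng.integers(len(best))]]
        result = env_step(state, a, spec, layout)
        if learn:
            boot = values[a, list(adjacency[a]), ci].max()
            values[s, a, ci] += alpha * (result.reward + gamma * boot - values[s, a, ci])
        s = a
        visited.append(s)
        if result.reward:
            rewarded = True
        if result.terminal:
            break
    return Episode(
        visited_states=tuple(visited),
        cue_state=c,
        target_state=state.target_state,
        rewarded=rewarded,
        n_steps=len(visited) - 1,
    )


def train_agent(
    params: AgentParams,
    spec: ConditionSpec,
    layout: SpatialLayout,
    rng: np.random.Generator,
    n_train: int = 300,
) -> tuple[QTable, list[Episode]]:
    """Train a fresh zero-initialized table for ``n_train`` episodes.

    All training episodes are returned (including the early, still-random
    ones) because the whole learning trajectory is what the scan-path
    complexity analysis consumes.
    """
    if n_train < 1:
        raise ValueError("n_train must be at least 1")
    Q = QTable(layout)
    episodes = [run_episode(Q, spec, params, layout, rng, learn=True) for _ in range(n_train)]
    return Q, episodes


def evaluate_agent(
    Q: QTable,
    spec: ConditionSpec,
    params: AgentParams,
    layout: SpatialLayout,
    rng: np.random.Generator,
    n_test: int = 1000,
    greedy: bool = False,
) -> float:
    """Mean steps-to-target over ``n_test`` frozen-Q episodes.

    The policy keeps its epsilon unless ``greedy`` is set; the table is never
    modified.  Episodes that hit the step cap contribute the cap value.
    """
    eval_params = params if not greedy else AgentParams(params.alpha, params.gamma, 0.0)
    steps = [
        run_episode(Q, spec, eval_params, layout, rng, learn=False).n_steps
        for _ in range(n_test)
    ]
    return float(np.mean(steps))


def grid_search(
    alpha_grid: np.ndarray,
    gamma_grid: np.ndarray,
    specs: list[ConditionSpec],
    layout: SpatialLayout,
    rng: np.random.Generator,
    n_train: int = 300,
    n_test: int = 1000,
    epsilon: float = 0.5,
) -> GridSearchResult:
    """Train and evaluate every (alpha, gamma) cell, per condition.

    Each cell's score is the mean test steps pooled across the supplied
    conditions (a fresh agent is trained for each condition).  Returns the
    per-cell table, the argmin cell and the unweighted grid mean.
    """
    alpha_grid = np.atleast_1d(np.asarray(alpha_grid, dtype=float))
    gamma_grid = np.atleast_1d(np.asarray(gamma_grid, dtype=float))
    if alpha_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("alpha and gamma grids must be nonempty")
    tol = 1e-9
    if alpha_grid.min() < -tol or alpha_grid.max() > 1 + tol:
        raise ValueError("alpha grid must lie within [0, 1]")
    if gamma_grid.min() < 0.5 - tol or gamma_grid.max() > 1 + tol:
        raise ValueError("gamma grid must lie within [0.5, 1]")
    alpha_grid = alpha_grid.clip(0.0, 1.0)
    gamma_grid = gamma_grid.clip(0.5, 1.0)
    if not specs:
        raise ValueError("at least one condition spec is required")

    rows = []
    for alpha, gamma in itertools.product(alpha_grid, gamma_grid):
        params = AgentParams(float(alpha), float(gamma), epsilon)
        per_condition = []
        for spec in specs:
            Q, _ = train_agent(params, spec, layout, rng, n_train=n_train)
            per_condition.append(
                evaluate_agent(Q, spec, params, layout, rng, n_test=n_test)
            )
        rows.append(
            {
                "alpha": float(alpha),
                "gamma": float(gamma),
                "mean_test_steps": float(np.mean(per_condition)),
            }
        )
    grid = pd.DataFrame(rows)
    best_row = grid.loc[grid["mean_test_steps"].idxmin()]
    best_params = AgentParams(float(best_row["alpha"]), float(best_row["gamma"]), epsilon)
    return GridSearchResult(
        grid=grid,
        best_params=best_params,
        best_mean_steps=float(best_row["mean_test_steps"]),
        grid_mean_steps=float(grid["mean_test_steps"].mean()),
    )


def extract_sequences(episodes: list[Episode]) -> list[list[int]]:
    """Per-episode visited-state sequences, in training order."""
    return [list(ep.visited_states) for ep in episodes]
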