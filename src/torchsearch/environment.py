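"""Spatial task environment for the torchlight search paradigm.

The search display is a 2 x 4 arrangement of eight areas of interest (AOIs):
four possible hiding locations (``0..3``, top row) above four cue locations
(``4..7``, bottom row), one cue per screen column.  An agent (or a
participant's gaze) moves between 4-connected neighbors on this grid.  Reward
semantics differ by condition:

* **Skewed** - the target location is predetermined for the whole block, and
  entering it is immediately rewarded.
* **Uniform** - the target is the column-pair of the episode's cue, and the
  reward is *gated*: it is delivered only if the cue location was visited at
  some earlier point of the episode.  The gate is what makes the problem
  non-Markovian from the agent's point of view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np

__all__ = [
    "SpatialLayout",
    "ConditionSpec",
    "EnvState",
    "StepResult",
    "build_layout",
    "neighbors",
    "sample_episode_setup",
    "env_step",
    "shortest_path_length",
    "DEFAULT_STEP_CAP",
]

#: Episodes are truncated after this many transitions so that an unlucky
#: exploration run cannot loop forever.
DEFAULT_STEP_CAP = 100

SKEWED = "Skewed"
UNIFORM = "Uniform"


class InvalidStateError(KeyError):
    """Raised when a location id is not part of the layout."""


class InvalidActionError(ValueError):
    """Raised when a move is attempted between non-adjacent locations."""


@dataclass(frozen=True)
class SpatialLayout:
    """The 8-location screen graph.

    Parameters
    ----------
    states
        Ordered tuple of location ids.
    adjacency
        Symmetric, irreflexive neighbor map.
    cue_states, target_states
        The two 4-element partitions of ``states`` (bottom/top row).
    column_pairing
        Bijection from each cue to the target sharing its screen column.
    """

    states: tuple[int, ...]
    adjacency: Mapping[int, tuple[int, ...]]
    cue_states: tuple[int, ...]
    target_states: tuple[int, ...]
    column_pairing: Mapping[int, int]

    def __post_init__(self) -> None:
        states = set(self.states)
        if len(self.states) != 8 or len(states) != 8:
            raise ValueError("layout must contain exactly 8 distinct states")
        if set(self.cue_states) | set(self.target_states) != states:
            raise ValueError("cue and target states must partition the states")
        if set(self.cue_states) & set(self.target_states):
            raise ValueError("cue and target states must be disjoint")
        if len(self.cue_states) != 4 or len(self.target_states) != 4:
            raise ValueError("expected 4 cue and 4 target states")
        for s, nbrs in self.adjacency.items():
            if s in nbrs:
                raise ValueError(f"state {s} is adjacent to itself")
            for n in nbrs:
                if s not in self.adjacency[n]:
                    raise ValueError("adjacency is not symmetric")
        if set(self.column_pairing) != set(self.cue_states):
            raise ValueError("column_pairing must be keyed by the cue states")
        if set(self.column_pairing.values()) != set(self.target_states):
            raise ValueError("column_pairing must cover all target states")
        for cue, target in self.column_pairing.items():
            if target not in self.adjacency[cue]:
                raise ValueError(
                    f"cue {cue} is not adjacent to its column target {target}"
                )
        if not nx.is_connected(self.graph()):
            raise ValueError("layout graph must be connected")

    def graph(self) -> nx.Graph:
        """The adjacency structure as an undirected :class:`networkx.Graph`."""
        g = nx.Graph()
        g.add_nodes_from(self.states)
        for s, nbrs in self.adjacency.items():
            g.add_edges_from((s, n) for n in nbrs)
        return g

    def neighbors(self, s: int) -> tuple[int, ...]:
        if s not in self.adjacency:
            raise InvalidStateError(f"unknown state id: {s!r}")
        return tuple(self.adjacency[s])

    def column_of(self, s: int) -> int:
        """Screen column (0-3) that location ``s`` belongs to."""
        if s in self.target_states:
            return self.target_states.index(s)
        if s in self.cue_states:
            return self.target_states.index(self.column_pairing[s])
        raise InvalidStateError(f"unknown state id: {s!r}")

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "states": list(self.states),
            "adjacency": {str(s): list(n) for s, n in self.adjacency.items()},
            "cue_states": list(self.cue_states),
            "target_states": list(self.target_states),
            "column_pairing": {str(c): t for c, t in self.column_pairing.items()},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SpatialLayout":
        raw = json.loads(text)
        return cls(
            states=tuple(raw["states"]),
            adjacency={int(s): tuple(n) for s, n in raw["adjacency"].items()},
            cue_states=tuple(raw["cue_states"]),
            target_states=tuple(raw["target_states"]),
            column_pairing={int(c): t for c, t in raw["column_pairing"].items()},
        )


@dataclass(frozen=True)
class ConditionSpec:
    """Condition semantics for episode setup and reward delivery.

    ``skewed_target`` is the predetermined hiding location used by every
    episode of a Skewed block.  In the Uniform condition the target is always
    the column pair of the episode's cue and ``skewed_target`` is ignored.
    """

    condition_name: str
    skewed_target: int | None = None
    step_cap: int = DEFAULT_STEP_CAP

    def __post_init__(self) -> None:
        if self.condition_name not in (SKEWED, UNIFORM):
            raise ValueError(
                f"condition_name must be {SKEWED!r} or {UNIFORM!r}, "
                f"got {self.condition_name!r}"
            )
        if self.condition_name == SKEWED and self.skewed_target is None:
            raise ValueError("Skewed condition requires a predetermined target")
        if self.step_cap < 1:
            raise ValueError("step_cap must be positive")

    @property
    def is_skewed(self) -> bool:
        return self.condition_name == SKEWED


@dataclass
class EnvState:
    """Mutable within-episode state.

    ``cue_visited`` is the reward gate: it flips to True the first time the
    cue location is entered (or when the episode starts there) and never
    resets within the episode.
    """

    current_state: int
    cue_state: int
    target_state: int
    cue_visited: bool = False
    steps_taken: int = 0


@dataclass(frozen=True)
class StepResult:
    next_state: int
    reward: int
    terminal: bool


def build_layout() -> SpatialLayout:
    """Construct the canonical 2 x 4 torchlight layout.

    Targets ``0..3`` sit on the top row, cues ``4..7`` directly below them,
    and adjacency is 4-connectivity on the grid (no diagonal moves), e.g. the
    neighbors of location ``0`` are ``{1, 4}``.
    """
    targets = (0, 1, 2, 3)
    cues = (4, 5, 6, 7)
    adjacency: dict[int, tuple[int, ...]] = {}
    for col in range(4):
        top, bottom = targets[col], cues[col]
        top_nbrs = [bottom]
        bottom_nbrs = [top]
        if col > 0:
            top_nbrs.append(targets[col - 1])
            bottom_nbrs.append(cues[col - 1])
        if col < 3:
            top_nbrs.append(targets[col + 1])
            bottom_nbrs.append(cues[col + 1])
        adjacency[top] = tuple(sorted(top_nbrs))
        adjacency[bottom] = tuple(sorted(bottom_nbrs))
    return SpatialLayout(
        states=targets + cues,
        adjacency=adjacency,
        cue_states=cues,
        target_states=targets,
        column_pairing={4: 0, 5: 1, 6: 2, 7: 3},
    )


def neighbors(layout: SpatialLayout, s: int) -> tuple[int, ...]:
    """Available move destinations A(s) from location ``s``."""
    return layout.neighbors(s)


def sample_episode_setup(
    layout: SpatialLayout,
    spec: ConditionSpec,
    rng: np.random.Generator,
) -> EnvState:
    """Randomly initialize an episode.

    The start state is uniform over all eight locations and the cue is
    uniform over the four cue locations.  In the Skewed condition the target
    is the block's predetermined location; in the Uniform condition it is the
    column pair of the sampled cue.  Starting on the cue immediately sets the
    reward gate; starting on the target grants nothing (reward requires a
    transition *into* the target).
    """
    start = int(rng.choice(layout.states))
    cue = int(rng.choice(layout.cue_states))
    if spec.is_skewed:
        target = int(spec.skewed_target)  # type: ignore[arg-type]
    else:
        target = int(layout.column_pairing[cue])
    return EnvState(
        current_state=start,
        cue_state=cue,
        target_state=target,
        cue_visited=(start == cue),
        steps_taken=0,
    )


def env_step(
    state: EnvState,
    action: int,
    spec: ConditionSpec,
    layout: SpatialLayout,
) -> StepResult:
    """Execute one move and update ``state`` in place.

    The cue-visited gate is updated *before* the reward is evaluated, so the
    move onto the cue itself can never be rewarded (the cue is never a
    target), but any later entry into the target is.
    """
    if action not in layout.adjacency[state.current_state]:
        raise InvalidActionError(
            f"illegal move {state.current_state} -> {action}: not adjacent"
        )
    if action == state.cue_state:
        state.cue_visited = True
    if spec.is_skewed:
        reward = int(action == state.target_state)
    else:
        reward = int(action == state.target_state and state.cue_visited)
    state.current_state = action
    state.steps_taken += 1
    terminal = reward == 1 or state.steps_taken >= spec.step_cap
    return StepResult(next_state=action, reward=reward, terminal=terminal)


def shortest_path_length(layout: SpatialLayout, from_state: int, to_state: int) -> int:
    """BFS distance between two locations (oracle for convergence tests)."""
    for s in (from_state, to_state):
        if s not in layout.adjacency:
            raise InvalidStateError(f"unknown state id: {s!r}")
    return int(nx.shortest_path_length(layout.graph(), from_state, to_state))
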