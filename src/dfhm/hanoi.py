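"""Tower-of-Hanoi state graph, minimal-move solver, and trial protocol.

The puzzle has three pegs and ``n`` discs of graduated size; a legal move
takes the top disc of one peg to a peg whose top disc is larger (or which
is empty). The trial protocol mirrors a computerized administration in
which the minimal move count is announced, planning time is the latency
to the first move, and any move that would lengthen the solution aborts
the trial and restarts it from the initial configuration (one "error").
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "TOHState",
    "TOHTrial",
    "TOHResult",
    "Agent",
    "full_tower",
    "all_states",
    "legal_moves",
    "apply_move",
    "min_moves",
    "state_graph",
    "generate_trial",
    "run_trial",
]

Move = tuple[int, int]  # (from peg, to peg)


@dataclass(frozen=True, order=True)
class TOHState:
    """Three pegs, each a bottom-to-top tuple of disc sizes (1 = smallest)."""

    pegs: tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]

    def __post_init__(self) -> None:
        if len(self.pegs) != 3:
            raise ValueError("exactly 3 pegs required")
        discs = sorted(d for peg in self.pegs for d in peg)
        if discs != list(range(1, len(discs) + 1)):
            raise ValueError("discs must be exactly sizes 1..n, each once")
        for peg in self.pegs:
            if any(peg[i] <= peg[i + 1] for i in range(len(peg) - 1)):
                raise ValueError("larger discs must lie below smaller ones")

    @property
    def n_discs(self) -> int:
        return sum(len(p) for p in self.pegs)


def full_tower(n_discs: int, peg: int = 0) -> TOHState:
    """All ``n_discs`` stacked on one peg (the canonical start/goal)."""
    pegs: list[tuple[int, ...]] = [(), (), ()]
    pegs[peg] = tuple(range(n_discs, 0, -1))
    return TOHState(tuple(pegs))  # type: ignore[arg-type]


def legal_moves(state: TOHState) -> list[Move]:
    """Moves available from ``state``; between 1 and 3 for any valid puzzle."""
    moves = []
    for src in range(3):
        if not state.pegs[src]:
            continue
        disc = state.pegs[src][-1]
        for dst in range(3):
            if dst == src:
                continue
            if not state.pegs[dst] or state.pegs[dst][-1] > disc:
                moves.append((src, dst))
    return moves


def apply_move(state: TOHState, move: Move) -> TOHState:
    src, dst = move
    if move not in legal_moves(state):
        raise ValueError(f"illegal move {move} from {state}")
    pegs = [list(p) for p in state.pegs]
    pegs[dst].append(pegs[src].pop())
    return TOHState(tuple(tuple(p) for p in pegs))  # type: ignore[arg-type]


def all_states(n_discs: int) -> list[TOHState]:
    """All 3**n configurations (each disc independently assigned a peg)."""
    states = []
    for code in range(3**n_discs):
        pegs: list[list[int]] = [[], [], []]
        c = code
        # place discs largest-first so stacking order is forced
        for disc in range(n_discs, 0, -1):
            pegs[c % 3].append(disc)
            c //= 3
        states.append(TOHState(tuple(tuple(p) for p in pegs)))  # type: ignore[arg-type]
    return states


@functools.lru_cache(maxsize=8)
def state_graph(n_discs: int) -> nx.Graph:
    """The legal-move graph on all 3**n states (moves are reversible)."""
    g = nx.Graph()
    states = all_states(n_discs)
    g.add_nodes_from(states)
    for s in states:
        for mv in legal_moves(s):
            g.add_edge(s, apply_move(s, mv))
    return g


def min_moves(start: TOHState, goal: TOHState) -> int:
    """Breadth-first-search distance between two configurations."""
    if start.n_discs != goal.n_discs:
        raise ValueError("start and goal must use the same number of discs")
    return nx.shortest_path_length(state_graph(start.n_discs), start, goal)


@dataclass(frozen=True)
class TOHTrial:
    start: TOHState
    goal: TOHState
    n_discs: int
    min_moves: int
    phase: str = "main"  # {"familiarization", "learning", "main"}

    def to_dict(self) -> dict:
        return {
            "start": [list(p) for p in self.start.pegs],
            "goal": [list(p) for p in self.goal.pegs],
            "n_discs": self.n_discs,
            "min_moves": self.min_moves,
            "phase": self.phase,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TOHTrial":
        return cls(
            start=TOHState(tuple(tuple(p) for p in d["start"])),  # type: ignore[arg-type]
            goal=TOHState(tuple(tuple(p) for p in d["goal"])),  # type: ignore[arg-type]
            n_discs=int(d["n_discs"]),
            min_moves=int(d["min_moves"]),
            phase=d.get("phase", "main"),
        )


def generate_trial(n_discs: int, target: int, seed: int, phase: str = "main") -> TOHTrial:
    """A uniformly drawn (start, goal) pair at BFS distance exactly ``target``.

    The draw is seeded and uniform over all ordered qualifying pairs.
    Distance-0 pairs (start = goal) are not trials and raise, as does a
    target beyond the graph diameter for ``n_discs``.
    """
    if target <= 0:
        raise ValueError("target must be >= 1 (start = goal is not a trial)")
    if target > 2**n_discs - 1:
        raise ValueError(
            f"no {n_discs}-disc pair is {target} moves apart "
            f"(diameter is {2**n_discs - 1})"
        )
    g = state_graph(n_discs)
    states = sorted(g.nodes)
    pairs = [
        (s, t)
        for s in states
        for t, d in sorted(nx.single_source_shortest_path_length(g, s).items())
        if d == target
    ]
    if not pairs:
        raise ValueError(f"no {n_discs}-disc pair at distance {target}")
    rng = np.random.default_rng(seed)
    start, goal = pairs[int(rng.integers(len(pairs)))]
    return TOHTrial(start=start, goal=goal, n_discs=n_discs, min_moves=target, phase=phase)


@dataclass
class TOHResult:
    planning_time: float
    errors: int
    completed: bool
    move_log: list[tuple[int, int, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planning_time": self.planning_time,
            "errors": self.errors,
            "completed": self.completed,
            "move_log": [list(m) for m in self.move_log],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


class ProtocolError(RuntimeError):
    """An agent returned an illegal move, or the trial failed to terminate."""


@dataclass
class Agent:
    """Simulated solver: optimal with probability ``p_optimal``, else a random
    legal alternative. Planning time is log-normal with the given natural-log
    parameters (``planning_sigma = 0`` makes it deterministic), matching the
    right-skewed planning-time distributions the cohort generator emulates.
    """

    p_optimal: float = 1.0
    planning_mu: float = np.log(15.0)
    planning_sigma: float = 0.5
    move_interval: float = 1.5  # seconds between executed moves

    def draw_planning_time(self, rng: np.random.Generator) -> float:
        if self.planning_sigma == 0:
            return float(np.exp(self.planning_mu))
        return float(rng.lognormal(self.planning_mu, self.planning_sigma))

    def choose(self, state: TOHState, goal: TOHState, rng: np.random.Generator) -> Move:
        moves = legal_moves(state)
        d = {mv: min_moves(apply_move(state, mv), goal) for mv in moves}
        best = min(d.values())
        optimal = sorted(mv for mv, dist in d.items() if dist == best)
        if self.p_optimal >= 1.0 or rng.random() < self.p_optimal:
            return optimal[int(rng.integers(len(optimal)))]
        others = sorted(mv for mv in moves if mv not in optimal)
        pool = others or optimal
        return pool[int(rng.integers(len(pool)))]


def run_trial(
    trial: TOHTrial,
    agent: Agent,
    rng: np.random.Generator,
    max_moves: int = 100_000,
) -> TOHResult:
    """Execute a trial under the restart-on-suboptimal-move protocol.

    A move is an error iff it strictly increases the remaining minimal move
    count relative to the best available continuation (i.e. it is not one of
    the distance-reducing moves). On an error the board resets to the start
    configuration and the error counter increments; the move itself is not
    executed further. Planning time is the latency before the first move.
    """
    planning_time = agent.draw_planning_time(rng)
    state = trial.start
    t = planning_time
    errors = 0
    log: list[tuple[int, int, float]] = []
    while state != trial.goal:
        if len(log) >= max_moves:
            raise ProtocolError(f"trial did not terminate within {max_moves} moves")
        mv = agent.choose(state, trial.goal, rng)
        if mv not in legal_moves(state):
            raise ProtocolError(f"agent proposed illegal move {mv}")
        log.append((mv[0], mv[1], t))
        t += agent.move_interval
        d_before = min_moves(state, trial.goal)
        nxt = apply_move(state, mv)
        if min_moves(nxt, trial.goal) > d_before - 1:
            errors += 1
            state = trial.start
        else:
            state = nxt
    return TOHResult(planning_time=planning_time, errors=errors, completed=True, move_log=log)
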