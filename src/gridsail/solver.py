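"""Ground-truth path computation for a key-mapping on the grid.

Because a key-mapping restricts movement to three of the eight compass
directions, shortest paths are generally zigzags and a goal can usually be
reached by several distinct optimal key sequences.  This module provides the
exact answers the rest of the package relies on: minimal press counts
(breadth-first search over cursor positions — the environment is memoryless,
so position is the full state), enumeration of all optimal key sequences in a
fixed lexicographic key order, and the straight-path check used as a design
constraint (a well-posed SG pair must not be solvable by hammering a single
key).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .environment import KEYS, GridSpec, KeyMapping, Position, SGPair, step

__all__ = [
    "PathQueryResult",
    "shortest_path_length",
    "enumerate_optimal_sequences",
    "has_straight_solution",
]


@dataclass(frozen=True)
class PathQueryResult:
    reachable: bool
    shortest_len: Optional[int]  # None when unreachable
    n_optimal_sequences: int  # 0 when unreachable


def _distances_from(origin: Position, km: KeyMapping, grid: GridSpec,
                    reverse: bool = False) -> Dict[Position, int]:
    """BFS distance map under the KM's three moves (reversed edges if asked)."""
    dist = {origin: 0}
    frontier = deque([origin])
    moves = [km.direction(k) for k in KEYS]
    while frontier:
        pos = frontier.popleft()
        for d in moves:
            nxt = (Position(pos.x - d.dx, pos.y - d.dy) if reverse else pos.moved(d))
            if grid.contains(nxt) and nxt not in dist:
                dist[nxt] = dist[pos] + 1
                frontier.append(nxt)
    return dist


def shortest_path_length(km: KeyMapping, sg: SGPair, grid: GridSpec) -> PathQueryResult:
    """Exact minimal press count from start to goal, by BFS over positions.

    Unreachable goals are a value (``reachable=False``), not an error.  The
    optimal-sequence count is included so callers get the full query result in
    one call.
    """
    dist = _distances_from(sg.start, km, grid)
    if sg.goal not in dist:
        return PathQueryResult(reachable=False, shortest_len=None, n_optimal_sequences=0)
    n = len(enumerate_optimal_sequences(km, sg, grid))
    return PathQueryResult(reachable=True, shortest_len=dist[sg.goal], n_optimal_sequences=n)


def enumerate_optimal_sequences(
    km: KeyMapping,
    sg: SGPair,
    grid: GridSpec,
    max_count: Optional[int] = None,
) -> List[Tuple[str, ...]]:
    """All key sequences of minimal length from start to goal, lexicographic in key order.

    Uses the BFS distance-to-goal map (reverse edges) and walks every press
    that strictly decreases the remaining distance, trying keys in the fixed
    order K1 < K2 < K3 so the output order is reproducible.  Truncates after
    ``max_count`` sequences when given.

    Raises ``ValueError`` when the goal is unreachable (check with
    :func:`shortest_path_length` first).
    """
    to_goal = _distances_from(sg.goal, km, grid, reverse=True)
    if sg.start not in to_goal:
        raise ValueError(
            f"goal unreachable for KM {km.id!r} / SG {sg.id!r}; "
            "see shortest_path_length"
        )
    out: List[Tuple[str, ...]] = []
    stack: List[Tuple[Position, Tuple[str, ...]]] = [(sg.start, ())]
    # Depth-first with keys pushed in reverse so K1 is explored first.
    while stack:
        pos, seq = stack.pop()
        if pos == sg.goal:
            out.append(seq)
            if max_count is not None and len(out) >= max_count:
                break
            continue
        for key in reversed(KEYS):
            nxt, valid = step(pos, key, km, grid)
            if valid and to_goal.get(nxt, -1) == to_goal[pos] - 1:
                stack.append((nxt, seq + (key,)))
    return out


def has_straight_solution(km: KeyMapping, sg: SGPair, grid: GridSpec) -> bool:
    """True iff repeating a single key walks from start to goal without leaving the grid."""
    for key in KEYS:
        pos = sg.start
        limit = max(grid.width, grid.height)  # a straight walk cannot exceed the span
        for _ in range(limit):
            pos, valid = step(pos, key, km, grid)
            if not valid:
                break
            if pos == sg.goal:
                return True
    return False
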