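"""Grid-sailing world: grid geometry, key-mapping movement rules, and trial execution.

The task is navigation of a cursor on a small grid (default 5 x 5) from a start
square to a goal square.  Three response keys are available, and a *key-mapping*
(KM) assigns each key to one of the eight compass directions; only three of the
eight moves are therefore ever available, which forces zigzag trajectories for
most start-goal (SG) pairs.  A key press whose move would leave the grid is
*invalid*: the cursor blinks and does not move.  A trial ends when the cursor
reaches the goal or when the simulated response clock exceeds the response
limit (default 6 s).  The reward score is 100 points for a shortest-length
press sequence, minus 5 points per excess keystroke, and 0 for a miss.

Coordinates are 0-based with the origin at the bottom-left corner; ``y``
increases northward.  All timing is simulated, driven by a per-press latency
and a planning-time charge supplied by the agent, never by the wall clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "KEYS",
    "Direction",
    "GridSpec",
    "Position",
    "KeyMapping",
    "SGPair",
    "TimingModel",
    "TrialSpec",
    "TrialContext",
    "TrialResult",
    "step",
    "score_trial",
    "run_trial",
]

#: The three response keys, in canonical (tie-break) order.
KEYS: Tuple[str, str, str] = ("K1", "K2", "K3")


class Direction(Enum):
    """The eight compass directions as unit king-moves ``(dx, dy)``."""

    N = (0, 1)
    NE = (1, 1)
    E = (1, 0)
    SE = (1, -1)
    S = (0, -1)
    SW = (-1, -1)
    W = (-1, 0)
    NW = (-1, 1)

    @property
    def dx(self) -> int:
        return self.value[0]

    @property
    def dy(self) -> int:
        return self.value[1]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular grid geometry; the task default is 5 x 5."""

    width: int = 5
    height: int = 5

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("grid must be at least 2 x 2")

    def contains(self, pos: "Position") -> bool:
        return 0 <= pos.x < self.width and 0 <= pos.y < self.height

    def positions(self) -> Iterable["Position"]:
        for y in range(self.height):
            for x in range(self.width):
                yield Position(x, y)


@dataclass(frozen=True, order=True)
class Position:
    """Grid square, 0-based, origin bottom-left, y increasing northward."""

    x: int
    y: int

    def moved(self, d: Direction) -> "Position":
        return Position(self.x + d.dx, self.y + d.dy)


@dataclass(frozen=True)
class KeyMapping:
    """A key-mapping rule: each of the three keys moves in one fixed direction.

    ``cursor_angle`` is the acute angle of the triangular cursor that cues the
    rule to the subject (90, 180 or 270 degrees); it is a label only and has no
    effect on the dynamics.
    """

    id: str
    cursor_angle: int
    mapping: Tuple[Tuple[str, Direction], ...]

    def __post_init__(self) -> None:
        keys = tuple(k for k, _ in self.mapping)
        if keys != KEYS:
            raise ValueError(f"mapping must assign exactly the keys {KEYS} in order")
        dirs = [d for _, d in self.mapping]
        if len(set(dirs)) != 3:
            raise ValueError("the three mapped directions must be pairwise distinct")
        if self.cursor_angle not in (90, 180, 270):
            raise ValueError("cursor_angle must be one of 90, 180, 270")

    def direction(self, key: str) -> Direction:
        for k, d in self.mapping:
            if k == key:
                return d
        raise ValueError(f"unknown key label {key!r}; expected one of {KEYS}")

    @property
    def directions(self) -> Tuple[Direction, Direction, Direction]:
        return tuple(d for _, d in self.mapping)  # type: ignore[return-value]

    @classmethod
    def from_names(cls, id: str, cursor_angle: int, names: Sequence[str]) -> "KeyMapping":
        """Build from three direction names, assigned to K1, K2, K3 in order."""
        if len(names) != 3:
            raise ValueError("need exactly three direction names")
        return cls(id, cursor_angle, tuple(zip(KEYS, (Direction[n] for n in names))))


@dataclass(frozen=True)
class SGPair:
    """A start-goal pair: one navigation problem on the grid."""

    id: str
    start: Position
    goal: Position

    def __post_init__(self) -> None:
        if self.start == self.goal:
            raise ValueError("start and goal must differ")


@dataclass(frozen=True)
class TimingModel:
    """Simulated trial timing.

    Each press consumes ``press_latency`` seconds of the response clock and
    registers at its completion; the agent's planning charge (reaction time)
    is added before the first press.  A press completing exactly at
    ``response_limit`` still counts.
    """

    press_latency: float = 0.4
    response_limit: float = 6.0
    delay_range: Tuple[float, float] = (4.0, 6.0)

    def __post_init__(self) -> None:
        if self.press_latency <= 0 or self.response_limit <= 0:
            raise ValueError("press_latency and response_limit must be positive")
        if self.delay_range[0] > self.delay_range[1]:
            raise ValueError("delay_range min must not exceed max")


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: which KM-SG set, when the response may start."""

    km: str
    sg: str
    condition: str  # C1 | C2 | C3 | TRAIN
    start_mode: str  # immediate | delayed
    delay_s: float
    block: int
    position_in_block: int
    subunit: int = 0  # short-block (training) or nonet (test) index within the session

    def __post_init__(self) -> None:
        if self.start_mode not in ("immediate", "delayed"):
            raise ValueError("start_mode must be 'immediate' or 'delayed'")
        if self.start_mode == "immediate" and self.delay_s != 0:
            raise ValueError("immediate start implies delay_s = 0")
        if self.start_mode == "delayed" and self.delay_s <= 0:
            raise ValueError("delayed start requires delay_s > 0")


@dataclass(frozen=True)
class TrialContext:
    """Everything an agent may observe about the current trial.

    The goal is visible on screen, so agents see it; the shortest path length
    is ground truth and deliberately *not* exposed here.
    """

    km: KeyMapping
    sg: SGPair
    grid: GridSpec
    spec: TrialSpec


@dataclass
class TrialResult:
    """Outcome of one executed trial."""

    presses: Tuple[Tuple[str, bool], ...]  # (key, valid-flag), in press order
    path: Tuple[Position, ...]  # visited positions, path[0] == start
    reached: bool
    n_keystrokes: int
    oversteps: Optional[int]  # n_keystrokes - shortest_len when reached, else None
    reward: int
    rt_s: float  # go signal to first press (planning charge)
    et_s: float  # first press to last press
    shortest_len: int = 0


def step(
    pos: Position, key: str, km: KeyMapping, grid: GridSpec
) -> Tuple[Position, bool]:
    """Apply one key press; invalid (off-grid) presses leave the cursor in place.

    Returns ``(new_position, valid)``.  Raises ``ValueError`` for an unknown
    key label, which signals a malformed agent action rather than a task event.
    """
    d = km.direction(key)  # raises on unknown key
    nxt = pos.moved(d)
    if grid.contains(nxt):
        return nxt, True
    return pos, False


def score_trial(reached: bool, n_keystrokes: int, shortest_len: int) -> int:
    """Reward rule: 100 for an optimal sequence, -5 per excess press, 0 on a miss."""
    if shortest_len < 1:
        raise ValueError("shortest_len must be at least 1")
    if not reached:
        return 0
    if n_keystrokes < shortest_len:
        raise ValueError(
            f"reached with {n_keystrokes} presses but shortest length is "
            f"{shortest_len}; shortest_len is not minimal"
        )
    return max(0, 100 - 5 * (n_keystrokes - shortest_len))


def run_trial(
    agent,
    spec: TrialSpec,
    km: KeyMapping,
    sg: SGPair,
    grid: GridSpec,
    timing: TimingModel,
    rng,
    shortest_len: Optional[int] = None,
    count_invalid_presses: bool = True,
) -> TrialResult:
    """Execute one trial with the given agent.

    The agent protocol (all hooks optional except ``choose``):

    ``begin_trial(ctx)``
        called once before the delay/go.
    ``on_delay(ctx, delay_s, rng)``
        called for delayed-start trials only, before the go signal.
    ``start_response(ctx, rng) -> float``
        called at the go signal; returns the planning-time charge (rt_s).
    ``choose(ctx, pos, rng) -> key | None``
        next key press; ``None`` means the agent stops responding.
    ``observe(ctx, pos, key, valid, new_pos)``
        called after every press.
    ``finish_trial(ctx, result)``
        called once with the scored result (learning happens here).

    Raises ``ValueError`` at setup when the KM-SG pair is unsolvable.
    """
    from .solver import shortest_path_length  # local import: solver builds on step()

    if shortest_len is None:
        q = shortest_path_length(km, sg, grid)
        if not q.reachable:
            raise ValueError(
                f"KM {km.id!r} cannot reach goal of SG {sg.id!r}: unsolvable trial"
            )
        shortest_len = q.shortest_len

    ctx = TrialContext(km=km, sg=sg, grid=grid, spec=spec)

    if hasattr(agent, "begin_trial"):
        agent.begin_trial(ctx)
    if spec.start_mode == "delayed" and hasattr(agent, "on_delay"):
        agent.on_delay(ctx, spec.delay_s, rng)
    rt_s = float(agent.start_response(ctx, rng)) if hasattr(agent, "start_response") else 0.0

    presses: list[Tuple[str, bool]] = []
    path: list[Position] = [sg.start]
    pos = sg.start
    reached = False
    eps = 1e-9  # float guard: a press completing exactly at the limit counts
    while True:
        t_next = rt_s + (len(presses) + 1) * timing.press_latency
        if t_next > timing.response_limit + eps:
            break  # out of time before the next press could register
        key = agent.choose(ctx, pos, rng)
        if key is None:
            break
        new_pos, valid = step(pos, key, km, grid)
        presses.append((key, valid))
        path.append(new_pos)  # invalid presses repeat the position (cursor blinks in place)
        if hasattr(agent, "observe"):
            agent.observe(ctx, pos, key, valid, new_pos)
        pos = new_pos
        if pos == sg.goal:
            reached = True
            break

    n_keystrokes = len(presses) if count_invalid_presses else sum(v for _, v in presses)
    reward = score_trial(reached, n_keystrokes, shortest_len)
    result = TrialResult(
        presses=tuple(presses),
        path=tuple(path),
        reached=reached,
        n_keystrokes=n_keystrokes,
        oversteps=(n_keystrokes - shortest_len) if reached else None,
        reward=reward,
        rt_s=rt_s,
        et_s=max(0, len(presses) - 1) * timing.press_latency,
        shortest_len=shortest_len,
    )
    if hasattr(agent, "finish_trial"):
        agent.finish_trial(ctx, result)
    return result
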