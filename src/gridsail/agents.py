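"""The three action-selection strategies the grid-sailing paradigm dissociates.

* **Exploratory (model-free)** — a tabular actor-critic.  A critic learns state
  values by temporal-difference (TD) errors; the same errors update the actor's
  key preferences, which drive a softmax policy.  The only reward is the trial
  score rescaled to [0, 1], delivered at the terminal transition — mirroring the
  task's single feedback event.
* **Model-based** — learns an internal model of the key-mapping (which key
  moves which way; one observed valid move fixes an entry, since transitions
  are noiseless) and searches it with a node-budgeted breadth-first planner.
  A pre-start delay buys extra planning budget, which is where the delayed-start
  advantage comes from.  While the model is incomplete the agent probes
  unobserved keys (directed model-learning exploration).
* **Motor-memory** — stores the best successful key sequence per KM-SG set and
  replays it press by press, with an optional per-press lapse probability.

An arbitrated agent stacks them in the fixed priority the paradigm
hypothesises for the stages of learning: motor-memory when a good-enough
sequence is stored, else model-based when any of the key-mapping is known,
else exploratory.  All three learning systems update from every trial
regardless of which one acted; arbitration only decides who chooses presses.

States are keyed by ``(km id, sg id, position)`` for the actor-critic (no
generalisation across sets) and by ``km id`` alone for the internal model —
the asymmetry that lets model knowledge, but not habit, transfer to novel
goals.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .environment import (
    KEYS,
    Direction,
    GridSpec,
    Position,
    TrialContext,
    TrialResult,
)

__all__ = [
    "AgentConfig",
    "CriticActorState",
    "LearnedModel",
    "MotorMemory",
    "softmax_select",
    "td_update",
    "plan",
    "memory_update",
    "ScriptedAgent",
    "OptimalScriptedAgent",
    "ExploratoryAgent",
    "ModelBasedAgent",
    "MotorMemoryAgent",
    "ArbitratedAgent",
    "make_agent",
]


@dataclass(frozen=True)
class AgentConfig:
    """Strategy parameters (all dimensionless unless noted).

    alpha_critic, alpha_actor : TD learning rates for critic values / actor
        preferences.
    gamma : discount per press.
    beta : softmax inverse temperature on actor preferences.
    epsilon_motor : per-press lapse probability during motor replay.
    budget_immediate : planner node budget available from trial onset.
    budget_per_delay_second : extra planner nodes per second of pre-start delay.
    memory_threshold : minimum stored reward (points) for motor replay to take
        control under arbitration.
    rt_charge_s : reaction-time charge (seconds) for a trial that was not
        pre-planned during the delay; counts against the response clock.
    """

    alpha_critic: float = 0.3
    alpha_actor: float = 0.3
    gamma: float = 0.9
    beta: float = 3.0
    epsilon_motor: float = 0.02
    budget_immediate: int = 8
    budget_per_delay_second: float = 50.0
    memory_threshold: float = 80.0
    rt_charge_s: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.alpha_critic <= 1 and 0 < self.alpha_actor <= 1):
            raise ValueError("learning rates must lie in (0, 1]")
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0 <= self.epsilon_motor <= 1:
            raise ValueError("epsilon_motor must lie in [0, 1]")
        if self.budget_immediate < 0 or self.budget_per_delay_second < 0:
            raise ValueError("planning budgets must be non-negative")
        if self.rt_charge_s < 0:
            raise ValueError("rt_charge_s must be non-negative")


State = Tuple[str, str, Position]  # (km id, sg id, position)


@dataclass
class CriticActorState:
    """Tabular critic values V(s) and actor preferences H(s, key); defaults 0."""

    V: Dict[State, float] = field(default_factory=lambda: defaultdict(float))
    H: Dict[Tuple[State, str], float] = field(default_factory=lambda: defaultdict(float))


@dataclass
class LearnedModel:
    """Partial internal model of each key-mapping: key -> Direction, per KM id."""

    known: Dict[str, Dict[str, Direction]] = field(default_factory=dict)

    def entries(self, km_id: str) -> Dict[str, Direction]:
        return self.known.setdefault(km_id, {})

    def is_complete(self, km_id: str) -> bool:
        return len(self.entries(km_id)) == 3

    def observe(self, km_id: str, key: str, pos: Position, new_pos: Position) -> None:
        """One valid move fixes the key's direction; invalid presses teach nothing."""
        if new_pos == pos:
            return
        self.entries(km_id)[key] = Direction((new_pos.x - pos.x, new_pos.y - pos.y))


@dataclass
class MotorMemory:
    """Best successful key sequence (valid presses only) per (km id, sg id)."""

    store: Dict[Tuple[str, str], Tuple[Tuple[str, ...], int]] = field(default_factory=dict)

    def stored_reward(self, km_id: str, sg_id: str) -> int:
        entry = self.store.get((km_id, sg_id))
        return entry[1] if entry else 0

    def sequence(self, km_id: str, sg_id: str) -> Optional[Tuple[str, ...]]:
        entry = self.store.get((km_id, sg_id))
        return entry[0] if entry else None


def softmax_select(preferences: Sequence[float], beta: float, rng) -> str:
    """Sample a key with probability proportional to exp(beta * preference)."""
    if len(preferences) != 3:
        raise ValueError("need exactly one preference per key")
    z = [beta * p for p in preferences]
    m = max(z)
    w = [math.exp(v - m) for v in z]
    total = sum(w)
    u = rng.random() * total
    acc = 0.0
    for key, wi in zip(KEYS, w):
        acc += wi
        if u <= acc:
            return key
    return KEYS[-1]


def td_update(
    state: CriticActorState,
    transition: Tuple[State, str, State, float, bool],
    cfg: AgentConfig,
) -> float:
    """One actor-critic TD update; returns the TD error delta.

    delta = r + gamma * V(s') * (not terminal) - V(s);
    V(s) += alpha_critic * delta;  H(s, key) += alpha_actor * delta.
    """
    s, key, s2, r, terminal = transition
    delta = r + (0.0 if terminal else cfg.gamma * state.V[s2]) - state.V[s]
    state.V[s] += cfg.alpha_critic * delta
    state.H[(s, key)] += cfg.alpha_actor * delta
    return delta


def plan_with_cost(
    model: LearnedModel,
    km_id: str,
    start: Position,
    goal: Position,
    grid: GridSpec,
    budget: int,
) -> Tuple[Optional[Tuple[str, ...]], int]:
    """Budgeted breadth-first planning over the *learned* model.

    Expands at most ``budget`` nodes, using only key->direction entries the
    model has actually observed.  Returns ``(sequence, nodes_expanded)``; the
    sequence is a goal-reaching key sequence (shortest under the known keys)
    or ``None`` — partial plans are never returned.
    """
    if start == goal:
        return (), 0
    entries = model.entries(km_id)
    if budget <= 0 or not entries:
        return None, 0
    from collections import deque

    parent: Dict[Position, Tuple[Position, str]] = {}
    seen = {start}
    frontier = deque([start])
    expanded = 0
    while frontier and expanded < budget:
        pos = frontier.popleft()
        expanded += 1
        for key in KEYS:  # fixed order keeps planning deterministic
            d = entries.get(key)
            if d is None:
                continue
            nxt = pos.moved(d)
            if not grid.contains(nxt) or nxt in seen:
                continue
            parent[nxt] = (pos, key)
            if nxt == goal:
                seq: List[str] = []
                cur = nxt
                while cur != start:
                    cur, k = parent[cur]
                    seq.append(k)
                return tuple(reversed(seq)), expanded
            seen.add(nxt)
            frontier.append(nxt)
    return None, expanded


def plan(
    model: LearnedModel,
    km_id: str,
    start: Position,
    goal: Position,
    grid: GridSpec,
    budget: int,
) -> Optional[Tuple[str, ...]]:
    """Like :func:`plan_with_cost` but returning only the key sequence (or None)."""
    return plan_with_cost(model, km_id, start, goal, grid, budget)[0]


def memory_update(mem: MotorMemory, km_id: str, sg_id: str, result: TrialResult) -> None:
    """Keep the best successful sequence per set; never overwrite with worse.

    Only goal-reaching trials (reward > 0) are stored, so that any stored
    sequence replays to the goal; the stored presses are the valid ones only.
    """
    if result.reward <= mem.stored_reward(km_id, sg_id) or not result.reached:
        return
    seq = tuple(key for key, valid in result.presses if valid)
    mem.store[(km_id, sg_id)] = (seq, result.reward)


class ScriptedAgent:
    """Replays a fixed key sequence; used for tests and worked examples."""

    name = "scripted"

    def __init__(self, sequence: Sequence[Optional[str]], repeat: bool = False):
        self.sequence = list(sequence)
        self.repeat = repeat
        self._i = 0

    def begin_trial(self, ctx: TrialContext) -> None:
        self._i = 0

    def start_response(self, ctx: TrialContext, rng) -> float:
        return 0.0

    def choose(self, ctx: TrialContext, pos: Position, rng) -> Optional[str]:
        if self._i >= len(self.sequence):
            if not self.repeat or not self.sequence:
                return None
            self._i = 0
        key = self.sequence[self._i]
        self._i += 1
        return key


class OptimalScriptedAgent:
    """Oracle agent: replays a ground-truth optimal sequence for every trial.

    Useful as a positive control — every trial it runs scores 100.
    """

    name = "scripted"

    def __init__(self, cfg: Optional[AgentConfig] = None):
        self.cfg = cfg or AgentConfig()
        self._seq: List[str] = []

    def begin_trial(self, ctx: TrialContext) -> None:
        from .solver import enumerate_optimal_sequences  # lazy: avoids module cycle

        self._seq = list(
            enumerate_optimal_sequences(ctx.km, ctx.sg, ctx.grid, max_count=1)[0]
        )

    def start_response(self, ctx: TrialContext, rng) -> float:
        return 0.0

    def choose(self, ctx: TrialContext, pos: Position, rng) -> Optional[str]:
        return self._seq.pop(0) if self._seq else None


class ExploratoryAgent:
    """Model-free actor-critic: softmax over learned key preferences, TD learning.

    Transitions are buffered during the trial and updated in order at trial
    end, when the terminal reward (score / 100) is known; intermediate
    transitions carry zero reward.
    """

    name = "exploratory"

    def __init__(self, cfg: Optional[AgentConfig] = None):
        self.cfg = cfg or AgentConfig()
        self.state = CriticActorState()
        self._transitions: List[Tuple[State, str, State]] = []

    def _s(self, ctx: TrialContext, pos: Position) -> State:
        return (ctx.km.id, ctx.sg.id, pos)

    def begin_trial(self, ctx: TrialContext) -> None:
        self._transitions = []

    def start_response(self, ctx: TrialContext, rng) -> float:
        return self.cfg.rt_charge_s

    def choose(self, ctx: TrialContext, pos: Position, rng) -> str:
        s = self._s(ctx, pos)
        prefs = [self.state.H[(s, k)] for k in KEYS]
        return softmax_select(prefs, self.cfg.beta, rng)

    def observe(self, ctx: TrialContext, pos: Position, key: str, valid: bool,
                new_pos: Position) -> None:
        self._transitions.append((self._s(ctx, pos), key, self._s(ctx, new_pos)))

    def finish_trial(self, ctx: TrialContext, result: TrialResult) -> None:
        r_terminal = result.reward / 100.0
        n = len(self._transitions)
        for i, (s, key, s2) in enumerate(self._transitions):
            terminal = i == n - 1
            td_update(self.state, (s, key, s2, r_terminal if terminal else 0.0, terminal),
                      self.cfg)
        self._transitions = []


class ModelBasedAgent:
    """Plans over a learned internal model of the key-mapping.

    The pre-start delay converts waiting time into planner node budget
    (``budget_immediate + budget_per_delay_second * delay_s``); a plan found
    during the delay is cached and executed from the go signal with zero
    reaction-time charge.  Without a cached plan the agent plans at go with the
    remaining budget; while the model is incomplete it presses unobserved keys
    to complete it, preferring ones not already seen to fail at the current
    position, in fixed key order.
    """

    name = "model_based"

    def __init__(self, cfg: Optional[AgentConfig] = None):
        self.cfg = cfg or AgentConfig()
        self.model = LearnedModel()
        self._plan: Optional[List[str]] = None
        self._plan_pos: Optional[Position] = None  # expected cursor position
        self._preplanned = False
        self._budget_left = 0
        self._failed_here: set[Tuple[Position, str]] = set()

    def begin_trial(self, ctx: TrialContext) -> None:
        self._plan = None
        self._plan_pos = None
        self._preplanned = False
        self._budget_left = self.cfg.budget_immediate
        self._failed_here = set()

    def on_delay(self, ctx: TrialContext, delay_s: float, rng) -> None:
        self._budget_left = int(
            self.cfg.budget_immediate + self.cfg.budget_per_delay_second * delay_s
        )
        self._try_plan(ctx, ctx.sg.start)
        if self._plan is not None:
            self._preplanned = True

    def start_response(self, ctx: TrialContext, rng) -> float:
        return 0.0 if self._preplanned else self.cfg.rt_charge_s

    def _try_plan(self, ctx: TrialContext, pos: Position) -> None:
        seq, expanded = plan_with_cost(
            self.model, ctx.km.id, pos, ctx.sg.goal, ctx.grid, self._budget_left
        )
        if seq:
            self._plan = list(seq)
            self._plan_pos = pos
        self._budget_left = max(0, self._budget_left - expanded)

    def choose(self, ctx: TrialContext, pos: Position, rng) -> str:
        # follow the cached plan while the cursor is where the plan expects
        if self._plan and self._plan_pos == pos:
            key = self._plan.pop(0)
            d = self.model.entries(ctx.km.id).get(key)
            self._plan_pos = pos.moved(d) if d is not None else None
            return key
        self._plan = None
        entries = self.model.entries(ctx.km.id)
        if len(entries) < 3:
            # directed model-learning exploration: probe an unobserved key
            for key in KEYS:
                if key not in entries and (pos, key) not in self._failed_here:
                    return key
            for key in KEYS:
                if key not in entries:
                    return key
        else:
            self._try_plan(ctx, pos)
            if self._plan and self._plan_pos == pos:
                key = self._plan.pop(0)
                self._plan_pos = pos.moved(self.model.entries(ctx.km.id)[key])
                return key
        # planning failed: fall back to a uniform (zero-preference softmax) choice
        return softmax_select([0.0, 0.0, 0.0], self.cfg.beta, rng)

    def observe(self, ctx: TrialContext, pos: Position, key: str, valid: bool,
                new_pos: Position) -> None:
        if valid:
            self.model.observe(ctx.km.id, key, pos, new_pos)
        else:
            self._failed_here.add((pos, key))


class MotorMemoryAgent:
    """Replays the best stored sequence for the current KM-SG set.

    Each press lapses to a uniformly random key with probability
    ``epsilon_motor``; replay continues regardless (habitual execution is
    open-loop).  With nothing stored the agent presses uniformly at random —
    under arbitration it would not have been selected in that case.
    """

    name = "motor_memory"

    def __init__(self, cfg: Optional[AgentConfig] = None,
                 memory: Optional[MotorMemory] = None):
        self.cfg = cfg or AgentConfig()
        self.memory = memory if memory is not None else MotorMemory()
        self._seq: Optional[Tuple[str, ...]] = None
        self._i = 0

    def begin_trial(self, ctx: TrialContext) -> None:
        self._seq = self.memory.sequence(ctx.km.id, ctx.sg.id)
        self._i = 0

    def start_response(self, ctx: TrialContext, rng) -> float:
        return 0.0 if self._seq else self.cfg.rt_charge_s

    def choose(self, ctx: TrialContext, pos: Position, rng) -> str:
        if self._seq is not None and self._i < len(self._seq):
            key = self._seq[self._i]
            self._i += 1
            if self.cfg.epsilon_motor > 0 and rng.random() < self.cfg.epsilon_motor:
                key = KEYS[rng.integers(0, 3)]
            return key
        return KEYS[rng.integers(0, 3)]

    def finish_trial(self, ctx: TrialContext, result: TrialResult) -> None:
        memory_update(self.memory, ctx.km.id, ctx.sg.id, result)


class ArbitratedAgent:
    """Fixed-priority stack over the three strategies.

    Per trial: motor-memory acts when the stored reward for this KM-SG set
    reaches ``memory_threshold``; otherwise model-based acts when at least one
    key of this KM is known; otherwise the exploratory actor-critic acts.  All
    three systems learn from every trial; the acting strategy is recorded in
    ``acting_strategy`` for logging.
    """

    name = "arbitrated"

    def __init__(self, cfg: Optional[AgentConfig] = None):
        self.cfg = cfg or AgentConfig()
        self.exploratory = ExploratoryAgent(self.cfg)
        self.model_based = ModelBasedAgent(self.cfg)
        self.motor = MotorMemoryAgent(self.cfg)
        self.acting_strategy: str = "exploratory"

    def arbitrate(self, ctx: TrialContext) -> str:
        if self.motor.memory.stored_reward(ctx.km.id, ctx.sg.id) >= self.cfg.memory_threshold:
            return "motor_memory"
        if self.model_based.model.entries(ctx.km.id):
            return "model_based"
        return "exploratory"

    def _actor(self):
        return {
            "exploratory": self.exploratory,
            "model_based": self.model_based,
            "motor_memory": self.motor,
        }[self.acting_strategy]

    def begin_trial(self, ctx: TrialContext) -> None:
        self.acting_strategy = self.arbitrate(ctx)
        self.exploratory.begin_trial(ctx)
        self.model_based.begin_trial(ctx)
        self.motor.begin_trial(ctx)

    def on_delay(self, ctx: TrialContext, delay_s: float, rng) -> None:
        if self.acting_strategy == "model_based":
            self.model_based.on_delay(ctx, delay_s, rng)

    def start_response(self, ctx: TrialContext, rng) -> float:
        return self._actor().start_response(ctx, rng)

    def choose(self, ctx: TrialContext, pos: Position, rng) -> str:
        return self._actor().choose(ctx, pos, rng)

    def observe(self, ctx: TrialContext, pos: Position, key: str, valid: bool,
                new_pos: Position) -> None:
        self.exploratory.observe(ctx, pos, key, valid, new_pos)
        self.model_based.observe(ctx, pos, key, valid, new_pos)

    def finish_trial(self, ctx: TrialContext, result: TrialResult) -> None:
        self.exploratory.finish_trial(ctx, result)
        self.motor.finish_trial(ctx, result)


def make_agent(kind: str, cfg: Optional[AgentConfig] = None):
    """Factory for the named strategies (exploratory, model_based, motor_memory, arbitrated)."""
    kinds = {
        "scripted": OptimalScriptedAgent,
        "exploratory": ExploratoryAgent,
        "model_based": ModelBasedAgent,
        "motor_memory": MotorMemoryAgent,
        "arbitrated": ArbitratedAgent,
    }
    if kind not in kinds:
        raise ValueError(f"unknown agent kind {kind!r}; expected one of {sorted(kinds)}")
    return kinds[kind](cfg)
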