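"""The experimental protocol: inventories, counterbalancing, and trial schedules.

The paradigm runs over two days.  On day 1 (training) each subject practices
four KM-SG sets — two key-mappings, each paired with two start-goal pairs —
for 60 trials per set, split over three blocks.  Day 2 (test) crosses three
key-mappings (the two trained ones plus a novel one) with three start-goal
pairs (one retested pair per trained KM plus a never-trained pair), yielding
nine KM-SG sets labelled by condition:

* **C1** — the novel KM with each of the three test SGs (3 sets): both the
  mapping and the sequences must be learned.
* **C2** — a trained KM with an SG it was never paired with (4 sets): the
  internal model is known, the sequence is new.
* **C3** — the retested trained sets (2 sets): well-learned sequences.

Group assignment rotates which KM is novel so that, across the three groups,
every KM serves as the novel one exactly once.  Start modes (immediate vs
delayed) alternate between consecutive short-blocks of four trials in
training and between consecutive nonets of nine trials in test.  All
randomisation is driven by the supplied generator, so a schedule is exactly
reproducible from (group, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .environment import GridSpec, KeyMapping, Position, SGPair, TimingModel, TrialSpec
from .solver import has_straight_solution, shortest_path_length

__all__ = [
    "WorldInventory",
    "GroupAssignment",
    "Schedule",
    "ValidationReport",
    "GROUPS",
    "default_inventory",
    "make_group_assignment",
    "make_training_schedule",
    "make_test_schedule",
    "make_refresher_schedule",
    "validate_inventory",
]

GROUPS = ("G1", "G2", "G3")


@dataclass(frozen=True)
class WorldInventory:
    """The task world: exactly 3 key-mappings and 5 start-goal pairs."""

    kms: Tuple[KeyMapping, ...]
    sgs: Tuple[SGPair, ...]
    grid: GridSpec = GridSpec()

    def __post_init__(self) -> None:
        if len(self.kms) != 3 or len(self.sgs) != 5:
            raise ValueError("inventory must hold exactly 3 KMs and 5 SG pairs")

    def km(self, km_id: str) -> KeyMapping:
        for km in self.kms:
            if km.id == km_id:
                return km
        raise KeyError(km_id)

    def sg(self, sg_id: str) -> SGPair:
        for sg in self.sgs:
            if sg.id == sg_id:
                return sg
        raise KeyError(sg_id)


def default_inventory() -> WorldInventory:
    """The package's default world.

    The three direction triples (one per cursor angle) are 90-degree rotations
    of one another, each positively spanning the plane so every square stays
    reachable from every other; the five SG pairs were chosen so that every
    KM x SG pairing is reachable in 2-5 presses with no straight single-key
    solution (checked by :func:`validate_inventory`).
    """
    kms = (
        KeyMapping.from_names("KM1", 90, ["N", "E", "SW"]),
        KeyMapping.from_names("KM2", 180, ["E", "S", "NW"]),
        KeyMapping.from_names("KM3", 270, ["S", "W", "NE"]),
    )
    sgs = (
        SGPair("SG1", Position(0, 0), Position(2, 1)),
        SGPair("SG2", Position(1, 1), Position(3, 2)),
        SGPair("SG3", Position(2, 1), Position(3, 3)),
        SGPair("SG4", Position(4, 1), Position(2, 2)),
        SGPair("SG5", Position(1, 0), Position(0, 2)),
    )
    return WorldInventory(kms=kms, sgs=sgs)


@dataclass(frozen=True)
class GroupAssignment:
    """Which KM-SG sets a group trains on and is tested with.

    ``test_sgs`` holds one retested SG per trained KM plus the never-trained
    SG; the test session crosses all three KMs with these three SGs.
    """

    group: str
    trained_kms: Tuple[str, str]
    new_km: str
    trained_sgs: Dict[str, Tuple[str, str]]  # trained KM id -> its two SG ids
    retested_sgs: Dict[str, str]  # trained KM id -> the one SG retested as C3
    new_sg: str

    @property
    def test_sgs(self) -> Tuple[str, str, str]:
        return (
            self.retested_sgs[self.trained_kms[0]],
            self.retested_sgs[self.trained_kms[1]],
            self.new_sg,
        )

    @property
    def trained_sets(self) -> Tuple[Tuple[str, str], ...]:
        """The four trained (km, sg) sets, in a fixed order."""
        return tuple(
            (km, sg) for km in self.trained_kms for sg in self.trained_sgs[km]
        )

    def test_sets(self) -> List[Tuple[str, str, str]]:
        """The nine test (km, sg, condition) sets, conditions partitioned 3/4/2."""
        sets: List[Tuple[str, str, str]] = []
        for sg in self.test_sgs:
            sets.append((self.new_km, sg, "C1"))
        for km in self.trained_kms:
            for sg in self.test_sgs:
                if sg == self.retested_sgs[km]:
                    sets.append((km, sg, "C3"))
                else:
                    sets.append((km, sg, "C2"))
        c1 = sum(1 for s in sets if s[2] == "C1")
        c2 = sum(1 for s in sets if s[2] == "C2")
        c3 = sum(1 for s in sets if s[2] == "C3")
        if (c1, c2, c3) != (3, 4, 2):
            raise ValueError(f"condition partition must be 3/4/2, got {c1}/{c2}/{c3}")
        return sets


def make_group_assignment(inv: WorldInventory, group: str, rng) -> GroupAssignment:
    """Counterbalanced assignment: group G_i treats KM_i as novel.

    The four training SGs are the first four of the inventory, rotated by
    group index so KM-SG combinations differ across groups; the fifth SG is
    never trained and serves as the novel test SG for every group.  Which of
    each trained KM's two SGs is retested in C3 is drawn from ``rng``.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    g = GROUPS.index(group)
    km_ids = [km.id for km in inv.kms]
    new_km = km_ids[g]
    trained = (km_ids[(g + 1) % 3], km_ids[(g + 2) % 3])
    pool = [inv.sgs[(g + i) % 4].id for i in range(4)]
    trained_sgs = {trained[0]: (pool[0], pool[1]), trained[1]: (pool[2], pool[3])}
    retested = {km: trained_sgs[km][int(rng.integers(0, 2))] for km in trained}
    return GroupAssignment(
        group=group,
        trained_kms=trained,  # type: ignore[arg-type]
        new_km=new_km,
        trained_sgs=trained_sgs,
        retested_sgs=retested,
        new_sg=inv.sgs[4].id,
    )


@dataclass
class Schedule:
    session: str  # training | refresher | test
    group: str
    trials: List[TrialSpec] = field(default_factory=list)


def _sample_delay(rng, timing: TimingModel) -> float:
    lo, hi = timing.delay_range
    return float(lo + (hi - lo) * rng.random())


def _alternating_modes(n: int, rng) -> List[str]:
    first = int(rng.integers(0, 2))
    modes = ("immediate", "delayed")
    return [modes[(first + i) % 2] for i in range(n)]


def make_training_schedule(
    assign: GroupAssignment, rng, timing: Optional[TimingModel] = None
) -> Schedule:
    """Day-1 training: 3 blocks x 20 short-blocks x 4 trials = 240 trials.

    Each short-block presents the four trained sets once in random order; the
    start mode alternates between consecutive short-blocks (first mode drawn
    from ``rng``), so each set accumulates 60 trials (20 per block, 10
    immediate + 10 delayed).
    """
    timing = timing or TimingModel()
    sets = list(assign.trained_sets)
    if len(sets) != 4:
        raise ValueError("training needs exactly 4 trained KM-SG sets")
    sched = Schedule(session="training", group=assign.group)
    modes = _alternating_modes(3 * 20, rng)
    for block in range(1, 4):
        pos_in_block = 0
        for sb in range(20):
            subunit = (block - 1) * 20 + sb
            mode = modes[subunit]
            order = list(rng.permutation(4))
            for idx in order:
                km, sg = sets[idx]
                pos_in_block += 1
                sched.trials.append(
                    TrialSpec(
                        km=km,
                        sg=sg,
                        condition="TRAIN",
                        start_mode=mode,
                        delay_s=_sample_delay(rng, timing) if mode == "delayed" else 0.0,
                        block=block,
                        position_in_block=pos_in_block,
                        subunit=subunit,
                    )
                )
    return sched


def make_test_schedule(
    assign: GroupAssignment, rng, timing: Optional[TimingModel] = None
) -> Schedule:
    """Day-2 test: 2 blocks x 10 nonets x 9 trials = 180 trials.

    Each nonet presents the nine test sets once in random order; start mode
    alternates every nonet, so each set accumulates 20 trials (10 per block,
    5 immediate + 5 delayed).
    """
    timing = timing or TimingModel()
    sets = assign.test_sets()
    sched = Schedule(session="test", group=assign.group)
    modes = _alternating_modes(2 * 10, rng)
    for block in range(1, 3):
        pos_in_block = 0
        for nonet in range(10):
            subunit = (block - 1) * 10 + nonet
            mode = modes[subunit]
            order = list(rng.permutation(9))
            for idx in order:
                km, sg, cond = sets[idx]
                pos_in_block += 1
                sched.trials.append(
                    TrialSpec(
                        km=km,
                        sg=sg,
                        condition=cond,
                        start_mode=mode,
                        delay_s=_sample_delay(rng, timing) if mode == "delayed" else 0.0,
                        block=block,
                        position_in_block=pos_in_block,
                        subunit=subunit,
                    )
                )
    return sched


def make_refresher_schedule(
    assign: GroupAssignment, rng, timing: Optional[TimingModel] = None
) -> Schedule:
    """Pre-test refresher: 12 trials over the 4 trained sets, 6 immediate + 6 delayed.

    Three short-blocks of four (each trained set once per short-block, random
    order) with the start mode alternating every trial, which yields the 6+6
    split exactly.
    """
    timing = timing or TimingModel()
    sets = list(assign.trained_sets)
    sched = Schedule(session="refresher", group=assign.group)
    first = int(rng.integers(0, 2))
    modes = ("immediate", "delayed")
    t = 0
    for sb in range(3):
        order = list(rng.permutation(4))
        for idx in order:
            km, sg = sets[idx]
            mode = modes[(first + t) % 2]
            t += 1
            sched.trials.append(
                TrialSpec(
                    km=km,
                    sg=sg,
                    condition="TRAIN",
                    start_mode=mode,
                    delay_s=_sample_delay(rng, timing) if mode == "delayed" else 0.0,
                    block=1,
                    position_in_block=t,
                    subunit=sb,
                )
            )
    return sched


@dataclass
class ValidationReport:
    passed: bool
    checked: List[Tuple[str, str]]
    violations: List[Tuple[str, str, str]]  # (km, sg, issue)

    def __str__(self) -> str:
        lines = [f"checked {len(self.checked)} KM-SG pairings: "
                 f"{'PASS' if self.passed else 'FAIL'}"]
        for km, sg, issue in self.violations:
            lines.append(f"  {km} x {sg}: {issue}")
        return "\n".join(lines)


def validate_inventory(
    inv: WorldInventory, assign: Optional[GroupAssignment] = None
) -> ValidationReport:
    """Check every scheduled KM-SG pairing against the task's design constraints.

    Constraints: the goal is reachable, needs at least 2 presses, and admits no
    straight (single repeated key) solution.  With no assignment given, all
    3 x 5 pairings are checked — a superset of every group's schedule.
    """
    if assign is None:
        pairs = [(km.id, sg.id) for km in inv.kms for sg in inv.sgs]
    else:
        pairs = sorted(
            set(assign.trained_sets)
            | {(km, sg) for km, sg, _ in assign.test_sets()}
        )
    violations: List[Tuple[str, str, str]] = []
    for km_id, sg_id in pairs:
        km, sg = inv.km(km_id), inv.sg(sg_id)
        q = shortest_path_length(km, sg, inv.grid)
        if not q.reachable:
            violations.append((km_id, sg_id, "goal unreachable"))
            continue
        if q.shortest_len < 2:
            violations.append((km_id, sg_id, f"shortest path {q.shortest_len} < 2"))
        if has_straight_solution(km, sg, inv.grid):
            violations.append((km_id, sg_id, "straight single-key solution exists"))
    return ValidationReport(passed=not violations, checked=pairs, violations=violations)
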