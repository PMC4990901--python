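"""Seeded cohort simulation: run simulated subjects through the full protocol.

Each subject is assigned to a group, then runs training (day 1), the
refresher, and the test session (day 2) with a single persistent agent, so
whatever the agent learned on day 1 carries into the test.  One master seed
spawns independent per-subject, per-session substreams
(:class:`numpy.random.SeedSequence`), which makes whole-cohort simulation
bit-reproducible and subjects statistically independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .agents import AgentConfig, make_agent
from .design import (
    GROUPS,
    Schedule,
    WorldInventory,
    default_inventory,
    make_group_assignment,
    make_refresher_schedule,
    make_test_schedule,
    make_training_schedule,
    validate_inventory,
)
from .environment import TimingModel, TrialSpec, run_trial
from .solver import shortest_path_length
from .stats import LOG_COLUMNS

__all__ = ["RunConfig", "CohortResult", "simulate_cohort", "run_schedule"]


class AgentParams(BaseModel):
    """Pydantic mirror of :class:`gridsail.agents.AgentConfig` for configs."""

    alpha_critic: float = 0.3
    alpha_actor: float = 0.3
    gamma: float = 0.9
    beta: float = 3.0
    epsilon_motor: float = 0.02
    budget_immediate: int = 8
    budget_per_delay_second: float = 50.0
    memory_threshold: float = 80.0
    rt_charge_s: float = 0.5

    def to_config(self) -> AgentConfig:
        return AgentConfig(**self.model_dump())


class TimingParams(BaseModel):
    press_latency: float = 0.4
    response_limit: float = 6.0
    delay_range: Tuple[float, float] = (4.0, 6.0)

    def to_model(self) -> TimingModel:
        return TimingModel(**self.model_dump())


class RunConfig(BaseModel):
    """Configuration of one cohort simulation."""

    seed: int = 0
    cohort_size: int = Field(default=18, ge=1)
    agent: Literal[
        "exploratory", "model_based", "motor_memory", "arbitrated", "scripted"
    ] = "arbitrated"
    group: Literal["G1", "G2", "G3", "rotate"] = "rotate"
    sessions: Tuple[str, ...] = ("training", "refresher", "test")
    agent_params: AgentParams = AgentParams()
    timing: TimingParams = TimingParams()
    count_invalid_presses: bool = True

    @field_validator("sessions")
    @classmethod
    def _known_sessions(cls, v: Tuple[str, ...]) -> Tuple[str, ...]:
        bad = set(v) - {"training", "refresher", "test"}
        if bad:
            raise ValueError(f"unknown sessions: {sorted(bad)}")
        return v

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class CohortResult:
    """Concatenated tidy per-trial logs plus a provenance block."""

    log: pd.DataFrame
    provenance: Dict[str, object]


def run_schedule(
    agent,
    schedule: Schedule,
    inv: WorldInventory,
    timing: TimingModel,
    rng,
    subject: str,
    count_invalid_presses: bool = True,
    shortest_cache: Optional[Dict[Tuple[str, str], int]] = None,
) -> List[dict]:
    """Run one agent through one schedule, returning tidy log rows."""
    if shortest_cache is None:
        shortest_cache = {}
    rows: List[dict] = []
    overall: Dict[Tuple[str, str], int] = {}
    per_mode: Dict[Tuple[str, str, str], int] = {}
    for spec in schedule.trials:
        km, sg = inv.km(spec.km), inv.sg(spec.sg)
        key = (spec.km, spec.sg)
        if key not in shortest_cache:
            q = shortest_path_length(km, sg, inv.grid)
            if not q.reachable:
                raise ValueError(f"unsolvable KM-SG set {key} in schedule")
            shortest_cache[key] = q.shortest_len
        result = run_trial(
            agent,
            spec,
            km,
            sg,
            inv.grid,
            timing,
            rng,
            shortest_len=shortest_cache[key],
            count_invalid_presses=count_invalid_presses,
        )
        overall[key] = overall.get(key, 0) + 1
        mkey = (spec.km, spec.sg, spec.start_mode)
        per_mode[mkey] = per_mode.get(mkey, 0) + 1
        rows.append(
            {
                "subject": subject,
                "group": schedule.group,
                "session": schedule.session,
                "condition": spec.condition,
                "km": spec.km,
                "sg": spec.sg,
                "start_mode": spec.start_mode,
                "block": spec.block,
                "trial_in_set": overall[key],
                "trial_in_set_mode": per_mode[mkey],
                "delay_s": round(spec.delay_s, 6),
                "reward": result.reward,
                "reached": result.reached,
                "n_keystrokes": result.n_keystrokes,
                "oversteps": result.oversteps if result.oversteps is not None else np.nan,
                "rt_s": round(result.rt_s, 6),
                "et_s": round(result.et_s, 6),
                "strategy": getattr(agent, "acting_strategy", getattr(agent, "name", "?")),
            }
        )
    return rows


def simulate_cohort(
    cfg: RunConfig, inv: Optional[WorldInventory] = None
) -> CohortResult:
    """Simulate a cohort of subjects through the configured sessions.

    Subjects rotate through the three groups (or all take ``cfg.group``); each
    subject keeps one agent across sessions.  Aborts with the violation report
    if the inventory fails validation.
    """
    inv = inv or default_inventory()
    report = validate_inventory(inv)
    if not report.passed:
        raise ValueError(f"inventory failed validation:\n{report}")

    timing = cfg.timing.to_model()
    agent_cfg = cfg.agent_params.to_config()
    master = np.random.SeedSequence(cfg.seed)
    subject_seeds = master.spawn(cfg.cohort_size)
    all_rows: List[dict] = []
    shortest_cache: Dict[Tuple[str, str], int] = {}
    for i, sub_ss in enumerate(subject_seeds):
        subject = f"S{i + 1:03d}"
        group = cfg.group if cfg.group != "rotate" else GROUPS[i % 3]
        streams = sub_ss.spawn(4)
        assign_rng = np.random.default_rng(streams[0])
        assign = make_group_assignment(inv, group, assign_rng)
        agent = make_agent(cfg.agent, agent_cfg)
        makers = {
            "training": (make_training_schedule, streams[1]),
            "refresher": (make_refresher_schedule, streams[2]),
            "test": (make_test_schedule, streams[3]),
        }
        for session in cfg.sessions:
            maker, ss = makers[session]
            rng = np.random.default_rng(ss)
            schedule = maker(assign, rng, timing)
            all_rows.extend(
                run_schedule(
                    agent,
                    schedule,
                    inv,
                    timing,
                    rng,
                    subject,
                    cfg.count_invalid_presses,
                    shortest_cache,
                )
            )
    log = pd.DataFrame(all_rows, columns=LOG_COLUMNS)
    provenance = {
        "package": "gridsail",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "cohort_size": cfg.cohort_size,
        "agent": cfg.agent,
    }
    return CohortResult(log=log, provenance=provenance)
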