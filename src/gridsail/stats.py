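"""Behavioral measures over tidy trial logs.

A trial log is a pandas DataFrame with one row per trial (see
:data:`LOG_COLUMNS`).  The measures mirror the standard analyses of the
grid-sailing paradigm:

* trial-by-trial learning curves of reward score, goal reach probability, and
  optimal goal reach probability (proportion of reward-100 trials), with
  between-subject standard errors;
* the first trial at which a curve reaches a learning criterion (80% of the
  measure's ceiling by default);
* the delay gain — delayed-start minus immediate-start mean per KM-SG set —
  the behavioral signature of planning during the pre-start delay;
* trial classification into error (reward 0), suboptimal (0 < reward < 100)
  and optimal (reward 100) trials;
* the mean absolute deviation (MAD) around the mean, an index of exploratory
  variability.

Curves are raw per-index means, no smoothing.  The within-set trial index is
counted per start mode by default (``trial_in_set_mode``); the overall index
(``trial_in_set``) is available via ``index="overall"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "LOG_COLUMNS",
    "LearningCurve",
    "GainSummary",
    "learning_curve",
    "criterion_trial",
    "delay_gain",
    "classify_trials",
    "mad",
    "export_tidy",
    "read_log",
]

#: Canonical tidy-log schema, in column order.  Coordinates in any serialized
#: paths are 0-based, origin bottom-left, y northward.
LOG_COLUMNS = [
    "subject",
    "group",
    "session",
    "condition",
    "km",
    "sg",
    "start_mode",
    "block",
    "trial_in_set",       # 1-based within (subject, session, km, sg)
    "trial_in_set_mode",  # 1-based within the same, per start mode
    "delay_s",
    "reward",
    "reached",
    "n_keystrokes",
    "oversteps",
    "rt_s",
    "et_s",
    "strategy",
]

_MEASURES = ("reward", "reach", "optimal")


def _measure_values(log: pd.DataFrame, measure: str) -> pd.Series:
    if measure == "reward":
        return log["reward"].astype(float)
    if measure == "reach":
        return log["reached"].astype(float)
    if measure == "optimal":
        return (log["reward"] == 100).astype(float)
    raise ValueError(f"measure must be one of {_MEASURES}, got {measure!r}")


def measure_ceiling(measure: str) -> float:
    """The measure's maximum: 100 points for reward, 1.0 for the probabilities."""
    return 100.0 if measure == "reward" else 1.0


def _filtered(
    log: pd.DataFrame,
    condition: Optional[str] = None,
    start_mode: Optional[str] = None,
    block: Optional[int] = None,
    session: Optional[str] = None,
) -> pd.DataFrame:
    out = log
    if session is not None:
        out = out[out["session"] == session]
    if condition is not None:
        out = out[out["condition"] == condition]
    if start_mode is not None:
        out = out[out["start_mode"] == start_mode]
    if block is not None:
        out = out[out["block"] == block]
    return out


@dataclass
class LearningCurve:
    """Per within-set trial index: mean, between-subject standard error, n subjects."""

    measure: str
    table: pd.DataFrame  # index: trial index; columns: mean, sem, n

    @property
    def values(self) -> np.ndarray:
        return self.table["mean"].to_numpy()


def learning_curve(
    log: pd.DataFrame,
    measure: str = "reward",
    condition: Optional[str] = None,
    start_mode: Optional[str] = None,
    block: Optional[int] = None,
    session: Optional[str] = None,
    index: str = "per_mode",
) -> LearningCurve:
    """Trial-by-trial mean of a measure with between-subject standard errors.

    Trials are first averaged within each subject (over that subject's KM-SG
    sets matching the filters) at each within-set trial index; the curve is
    the across-subject mean and its standard error.

    Raises ``ValueError`` on an empty selection.
    """
    sel = _filtered(log, condition, start_mode, block, session)
    if sel.empty:
        raise ValueError("empty selection: no trials match the given filters")
    idx_col = {"per_mode": "trial_in_set_mode", "overall": "trial_in_set"}.get(index)
    if idx_col is None:
        raise ValueError("index must be 'per_mode' or 'overall'")
    sel = sel.assign(_value=_measure_values(sel, measure))
    per_subject = (
        sel.groupby(["subject", idx_col], sort=True)["_value"].mean().reset_index()
    )
    g = per_subject.groupby(idx_col)["_value"]
    table = pd.DataFrame(
        {
            "mean": g.mean(),
            "sem": g.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
            "n": g.size(),
        }
    )
    table.index.name = "trial"
    return LearningCurve(measure=measure, table=table)


def criterion_trial(
    curve: LearningCurve,
    criterion: float = 0.8,
    ceiling: Optional[float] = None,
) -> Optional[int]:
    """First within-set trial index whose curve value reaches criterion x ceiling.

    Returns ``None`` when the criterion is never reached (a learning curve may
    legitimately fail the criterion, as novel-KM goal-reach curves do).
    """
    if not 0 < criterion <= 1:
        raise ValueError("criterion must lie in (0, 1]")
    if ceiling is None:
        ceiling = measure_ceiling(curve.measure)
    threshold = criterion * ceiling
    for trial, value in curve.table["mean"].items():
        if value >= threshold:
            return int(trial)
    return None


@dataclass
class GainSummary:
    """Delayed-minus-immediate means per KM-SG set, with condition aggregates."""

    measure: str
    per_set: pd.DataFrame  # columns: subject, condition, km, sg, gain
    by_condition: pd.DataFrame  # index condition; columns mean, sem, n
    flagged: pd.DataFrame  # sets missing one start mode, excluded from aggregates


def delay_gain(log: pd.DataFrame, measure: str = "reward",
               session: Optional[str] = None) -> GainSummary:
    """Delay gain per KM-SG set: mean(delayed) - mean(immediate).

    Computed per (subject, km, sg); sets missing either start mode are flagged
    and excluded from the condition aggregates, whose standard errors are
    between-subject (subjects averaged over their sets first).
    """
    sel = _filtered(log, session=session)
    if sel.empty:
        raise ValueError("empty selection")
    sel = sel.assign(_value=_measure_values(sel, measure))
    keys = ["subject", "condition", "km", "sg"]
    pivot = (
        sel.groupby(keys + ["start_mode"])["_value"].mean().unstack("start_mode")
    )
    have_both = pivot.notna().all(axis=1) if {"immediate", "delayed"} <= set(
        pivot.columns
    ) else pd.Series(False, index=pivot.index)
    flagged = pivot[~have_both].reset_index()[keys]
    ok = pivot[have_both]
    per_set = ok.reset_index()
    per_set["gain"] = per_set["delayed"] - per_set["immediate"]
    per_set = per_set[keys + ["gain"]]
    per_subj = per_set.groupby(["condition", "subject"])["gain"].mean().reset_index()
    g = per_subj.groupby("condition")["gain"]
    by_condition = pd.DataFrame(
        {
            "mean": g.mean(),
            "sem": g.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
            "n": g.size(),
        }
    )
    return GainSummary(measure=measure, per_set=per_set,
                       by_condition=by_condition, flagged=flagged)


def classify_trials(log: pd.DataFrame,
                    by: Sequence[str] = ("condition", "start_mode")) -> pd.DataFrame:
    """Proportions of error / suboptimal / optimal trials per stratum.

    Classes partition by reward score: error = 0, suboptimal in (0, 100),
    optimal = 100; proportions therefore sum to 1 within each stratum.
    """
    if log.empty:
        raise ValueError("empty log")
    r = log["reward"]
    cls = pd.Series(
        np.where(r == 0, "error", np.where(r == 100, "optimal", "suboptimal")),
        index=log.index,
        name="trial_class",
    )
    out = (
        log.assign(trial_class=cls)
        .groupby(list(by))["trial_class"]
        .value_counts(normalize=True)
        .unstack("trial_class", fill_value=0.0)
    )
    for col in ("error", "suboptimal", "optimal"):
        if col not in out.columns:
            out[col] = 0.0
    return out[["error", "suboptimal", "optimal"]]


def mad(values: Iterable[float]) -> float:
    """Mean absolute deviation around the arithmetic mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mad of an empty list is undefined")
    return float(np.mean(np.abs(arr - arr.mean())))


def _validate_schema(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log is missing required columns: {missing}")
    return df[LOG_COLUMNS]


def export_tidy(log: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write the log in the documented schema; .jsonl writes JSON Lines, else CSV."""
    path = Path(path)
    df = _validate_schema(log)
    if path.suffix == ".jsonl":
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                fh.write(json.dumps(rec) + "\n")
    else:
        df.to_csv(path, index=False)
    return path


def read_log(path: Union[str, Path]) -> pd.DataFrame:
    """Read a trial log written by :func:`export_tidy`, validating the schema."""
    path = Path(path)
    if path.suffix == ".jsonl":
        df = pd.read_json(path, lines=True)
    else:
        df = pd.read_csv(path)
    df = _validate_schema(df)
    df["reached"] = df["reached"].astype(bool)
    return df
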