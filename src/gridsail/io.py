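"""World configuration and schedule serialization.

A world config is a small YAML/JSON document:

.. code-block:: yaml

    grid: {width: 5, height: 5}
    kms:
      - {id: KM1, cursor_angle: 90, directions: [N, E, SW]}
      - {id: KM2, cursor_angle: 180, directions: [E, S, NW]}
      - {id: KM3, cursor_angle: 270, directions: [S, W, NE]}
    sgs:
      - {id: SG1, start: [0, 0], goal: [2, 1]}
      ...

Coordinates are 0-based, origin bottom-left, y northward — the convention is
recorded in every file this module writes.  Schedules serialize to CSV or
JSON Lines with one trial per record.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .design import Schedule, WorldInventory
from .environment import GridSpec, KeyMapping, Position, SGPair

__all__ = ["load_world", "dump_world", "schedule_to_frame", "write_schedule"]

COORD_NOTE = "coordinates: 0-based, origin bottom-left, y increases northward"

SCHEDULE_COLUMNS = [
    "session",
    "group",
    "block",
    "subunit",
    "trial",
    "km",
    "sg",
    "condition",
    "start_mode",
    "delay_s",
]


def load_world(path: Union[str, Path]) -> WorldInventory:
    """Read a world inventory from a YAML (or JSON) config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        grid = GridSpec(**doc.get("grid", {}))
        kms = tuple(
            KeyMapping.from_names(k["id"], int(k["cursor_angle"]), k["directions"])
            for k in doc["kms"]
        )
        sgs = tuple(
            SGPair(s["id"], Position(*s["start"]), Position(*s["goal"]))
            for s in doc["sgs"]
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed world config {path}: {exc}") from exc
    return WorldInventory(kms=kms, sgs=sgs, grid=grid)


def dump_world(inv: WorldInventory, path: Union[str, Path]) -> Path:
    """Write a world inventory as YAML."""
    doc = {
        "note": COORD_NOTE,
        "grid": {"width": inv.grid.width, "height": inv.grid.height},
        "kms": [
            {
                "id": km.id,
                "cursor_angle": km.cursor_angle,
                "directions": [d.name for d in km.directions],
            }
            for km in inv.kms
        ],
        "sgs": [
            {
                "id": sg.id,
                "start": [sg.start.x, sg.start.y],
                "goal": [sg.goal.x, sg.goal.y],
            }
            for sg in inv.sgs
        ],
    }
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def schedule_to_frame(schedule: Schedule) -> pd.DataFrame:
    """Flatten a schedule into a tidy DataFrame, one trial per row."""
    rows = [
        {
            "session": schedule.session,
            "group": schedule.group,
            "block": t.block,
            "subunit": t.subunit,
            "trial": i + 1,
            "km": t.km,
            "sg": t.sg,
            "condition": t.condition,
            "start_mode": t.start_mode,
            "delay_s": round(t.delay_s, 6),
        }
        for i, t in enumerate(schedule.trials)
    ]
    return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def write_schedule(schedule: Schedule, path: Union[str, Path]) -> Path:
    """Write a schedule as CSV (or JSON Lines for a .jsonl path)."""
    path = Path(path)
    df = schedule_to_frame(schedule)
    if path.suffix == ".jsonl":
        df.to_json(path, orient="records", lines=True)
    else:
        df.to_csv(path, index=False)
    return path
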