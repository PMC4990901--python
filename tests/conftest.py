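import numpy as np
import pandas as pd
import pytest

from gridsail.design import default_inventory, make_group_assignment
from gridsail.environment import GridSpec, KeyMapping, Position, SGPair, TimingModel, TrialSpec
from gridsail.stats import LOG_COLUMNS


@pytest.fixture(scope="session")
def inventory():
    return default_inventory()


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def km_nesw():
    """A key-mapping with K1=N, K2=E, K3=SW (positively spanning)."""
    return KeyMapping.from_names("KMA", 90, ["N", "E", "SW"])


def make_spec(km="KM1", sg="SG1", start_mode="immediate", delay_s=0.0,
              condition="TRAIN", block=1, pos=1):
    return TrialSpec(km=km, sg=sg, condition=condition, start_mode=start_mode,
                     delay_s=delay_s, block=block, position_in_block=pos)


def random_log(rng, n_subjects=4, n_sets=3, n_trials=8):
    """A randomized synthetic tidy log for statistics oracles."""
    rows = []
    for s in range(n_subjects):
        for k in range(n_sets):
            counters = {"immediate": 0, "delayed": 0}
            for t in range(n_trials):
                mode = "immediate" if t % 2 == 0 else "delayed"
                counters[mode] += 1
                reached = bool(rng.random() < 0.7)
                over = int(rng.integers(0, 5)) if reached else 0
                reward = max(0, 100 - 5 * over) if reached else 0
                rows.append({
                    "subject": f"S{s + 1:03d}",
                    "group": "G1",
                    "session": "test",
                    "condition": ["C1", "C2", "C3"][k % 3],
                    "km": f"KM{k + 1}",
                    "sg": f"SG{k + 1}",
                    "start_mode": mode,
                    "block": 1 + t // (n_trials // 2),
                    "trial_in_set": t + 1,
                    "trial_in_set_mode": counters[mode],
                    "delay_s": 5.0 if mode == "delayed" else 0.0,
                    "reward": reward,
                    "reached": reached,
                    "n_keystrokes": 3 + over + (0 if reached else 5),
                    "oversteps": over if reached else np.nan,
                    "rt_s": float(rng.random()),
                    "et_s": float(rng.random() * 3),
                    "strategy": "exploratory",
                })
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


@pytest.fixture
def synthetic_log(rng):
    return random_log(rng)
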