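# gridsail

A simulator for the **grid-sailing task**, a behavioral paradigm used to
dissociate three action-selection strategies in sequential motor learning:
model-free exploration, model-based planning, and motor-memory replay.

In the task, a cursor must be steered from a start square to a goal square on
a 5 × 5 grid using three response keys. A *key-mapping* (KM) assigns each key
to one of the eight compass directions, so only three moves are ever
available and most goals require zigzag trajectories. A press that would
leave the grid is invalid (the cursor blinks and stays). Trials start either
immediately or after a 4–6 s delay usable for covert planning, responses must
finish within 6 s, and the reward score is

```
reward = 100                         for a shortest-length press sequence
       = max(0, 100 − 5·oversteps)   for a longer successful sequence
       = 0                           for a miss
```

`gridsail` provides, with no human data required:

- the **environment** (grid, key-mapping dynamics, invalid-press rule,
  simulated trial timing, reward scoring);
- an exact **solver** (BFS shortest path lengths, enumeration of all optimal
  key sequences, straight-path design checks);
- three **agents** plus an arbitration stack:
  - *exploratory*: tabular actor-critic. The critic learns state values
    V(s) by the TD error δ = r + γV(s′) − V(s); the actor's key preferences
    H(s,a) are updated by the same δ and drive a softmax policy
    π(a|s) ∝ exp(βH(s,a)). Reward (score/100) arrives only at the terminal
    transition.
  - *model-based*: learns the key→direction mapping from observed moves and
    plans by breadth-first search over the learned model under a node
    budget; the pre-start delay adds budget (covert simulation time), so
    delayed trials can be fully planned while immediate ones often cannot.
  - *motor-memory*: replays the best stored key sequence for a familiar
    KM-SG (key-mapping × start-goal) set, with a per-press lapse
    probability.
  - *arbitrated*: motor-memory if a good-enough sequence is stored, else
    model-based if any of the mapping is known, else exploratory — the
    hypothesized progression across learning stages.
- the **experimental design**: three counterbalanced groups, day-1 training
  (4 KM-SG sets × 60 trials, short-blocks of four with alternating start
  modes), a 12-trial refresher, and the day-2 test session crossing 3 KMs ×
  3 SGs into conditions C1 (novel KM), C2 (known KM, novel SG) and C3
  (well-learned sets), 20 trials per set in nonets of nine;
- the **behavioral statistics**: trial-by-trial learning curves with
  between-subject standard errors, 80% learning-criterion detection, delay
  gains (delayed − immediate means), error/suboptimal/optimal trial
  classification, and mean absolute deviation (MAD) as a variability index;
- a **CLI** (`gridsail design | validate | simulate | analyze | demo`) and
  tidy CSV/JSON-Lines logs for external statistics.

## Worked example

Simulate ten subjects through the full two-day protocol with the arbitrated
agent and summarize the test session:

```python
from gridsail import RunConfig, simulate_cohort
from gridsail.stats import learning_curve, criterion_trial, delay_gain, mad

res = simulate_cohort(RunConfig(seed=7, cohort_size=10, agent="arbitrated"))
test = res.log[res.log.session == "test"]
for cond in ("C1", "C2", "C3"):
    sel = test[test.condition == cond]
    curve = learning_curve(test, "reward", condition=cond, start_mode="delayed")
    print(f"{cond}: mean reward {sel.reward.mean():5.1f}   "
          f"MAD {mad(sel.reward):5.2f}   "
          f"criterion trial (delayed) {criterion_trial(curve)}")
print(delay_gain(test, "reward").by_condition.round(2))
```

prints

```
C1: mean reward  93.9   MAD 10.83   criterion trial (delayed) 1
C2: mean reward  96.2   MAD  7.27   criterion trial (delayed) 1
C3: mean reward  95.9   MAD  7.42   criterion trial (delayed) 1
           mean   sem   n
condition
C1         4.12  1.92  10
C2        -0.01  1.06  10
C3         0.45  1.60  10
```

Condition 1 (novel key-mapping) is the most variable (largest MAD) and
carries a positive delay gain; condition 3 (well-learned sequences) sits at
ceiling with no delay benefit — the qualitative strategy signatures the
paradigm was designed to elicit. The same tables are produced end-to-end by

```sh
gridsail demo --seed 7 --subjects 10 --out demo/
```

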