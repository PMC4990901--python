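# Methods

## Task model

The environment is a deterministic, memoryless gridworld. State is the cursor
position on a `width × height` grid (default 5 × 5; coordinates 0-based,
origin bottom-left, y northward). A key-mapping (KM) assigns the three
response keys K1–K3 to three pairwise-distinct compass directions (unit
king-moves). A press whose move would leave the grid is *invalid*: the cursor
does not move, and the press still counts toward the keystroke total
(configurable via `count_invalid_presses`, default on — the feedback display
counts keystrokes, and nothing suggests blinked presses are excluded).

Scoring: 100 points for reaching the goal with a shortest-length press
sequence, −5 per excess keystroke, floored at 0; misses score 0. Over-steps
are defined from total presses (valid + invalid).

Timing is simulated, never wall-clock. Each press consumes `press_latency`
seconds (default 0.4 s) and registers at its completion; the agent's
planning charge (`rt_s`) is added before the first press; the trial ends at
the goal or once the next press would complete after `response_limit`
(default 6 s; a press completing exactly at the limit counts). Execution
time is `(n_presses − 1) × press_latency`. Delayed-start trials draw their
delay uniformly from `delay_range` (default [4, 6] s); the uniform choice is
a package decision — only the interval is specified by the paradigm.

## Solver

Shortest press counts come from breadth-first search over positions (the
environment is memoryless, so position is the complete state). Optimal
sequences are enumerated by walking every press that strictly decreases the
BFS distance-to-goal, trying keys in the fixed order K1 < K2 < K3, which
makes enumeration order reproducible. The "no straight path" design check
asks whether any single repeated key walks start → goal without leaving the
grid; when it does, the straight length equals the Chebyshev distance and is
provably minimal. The test suite cross-checks the solver against exhaustive
enumeration of all 3^L key sequences and against an independently built
networkx shortest-path graph.

## Agents

All three learning systems are tabular and keyed deliberately differently:

- **Exploratory (actor-critic).** State is `(km, sg, position)` — no
  generalization across sets, the simplest faithful instantiation of
  habit-like learning. Updates: δ = r + γ·V(s′)·(1 − terminal) − V(s),
  V(s) += α_c·δ, H(s,a) += α_a·δ; softmax policy with inverse temperature β.
  The only reward is the trial score rescaled to [0, 1] at the terminal
  transition (the task delivers a single feedback event); intermediate
  transitions carry r = 0. Transitions are buffered within a trial and
  updated in order at trial end, when the terminal reward is known. No
  eligibility traces.
- **Model-based.** The internal model maps `km → {key → direction}` and is
  keyed by KM only, so it transfers to novel goals — the asymmetry that
  separates this strategy from the other two. Transitions are noiseless, so
  one observed valid move fixes an entry; invalid presses identify nothing
  about direction and teach nothing. Planning is budgeted BFS over the known
  entries; plans are returned whole or not at all. While the model is
  incomplete the agent presses unobserved keys (directed model-learning
  exploration, ties broken K1 < K2 < K3, skipping keys already seen to fail
  at the current position); with a complete model it re-plans from the
  current position with the trial's remaining budget; if planning fails it
  presses uniformly at random. A plan found during the delay is cached and
  executed with zero reaction-time charge.
- **Motor-memory.** Stores, per KM-SG set, the best successful sequence
  (valid presses only) and its reward; never overwrites with worse, and only
  goal-reaching trials are stored so a stored sequence always replays to the
  goal. Replay is open-loop with a per-press lapse probability
  `epsilon_motor`; a lapse substitutes a uniformly random key and replay
  continues regardless.
- **Arbitration** is a fixed priority stack evaluated once per trial:
  motor-memory if the stored reward for the current set ≥ `memory_threshold`,
  else model-based if at least one key of the current KM is known, else
  exploratory. All three systems learn from every trial; arbitration decides
  only who chooses presses. The acting strategy is logged per trial. A
  learned arbitration controller is out of scope.

### Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `alpha_critic`, `alpha_actor` | 0.3 | — | standard tabular TD rates; fast enough to learn a 3–5-press sequence within the 60 training trials the protocol allots |
| `gamma` | 0.9 | per press | mild discounting over ≤15-press horizons |
| `beta` | 3.0 | — | softmax sharp enough for preferences on the δ ∈ [0, 1] scale to dominate by late training |
| `epsilon_motor` | 0.02 | per press | small motor lapse; keeps well-learned performance near, not at, ceiling |
| `budget_immediate` | 8 | nodes | planning capacity at the go signal; see below |
| `budget_per_delay_second` | 50 | nodes/s | covert simulation rate during the delay |
| `memory_threshold` | 80 | points | matches the 80% learning criterion: a sequence this good is worth habitizing |
| `rt_charge_s` | 0.5 | s | reaction-time charge for trials not pre-planned during the delay; counts against the response clock |

The planning budgets are a capacity model of covert simulation, not a
measured human quantity. `budget_immediate` must lie *below* the 10–25 nodes
a typical search on this grid expands, otherwise at-go planning always
completes and immediate and delayed trials become statistically identical —
the budget would be vacuous and the paradigm's delay-dependent planning
advantage could not arise in the simulator. The default of 8 nodes binds for
most KM-SG sets; a 4–6 s delay adds 200–300 nodes, which always suffices.

## Experimental design

Defaults reconstruct the two-day protocol exactly in its counts:

- **Training** (day 1): 4 trained KM-SG sets, 3 blocks × 20 short-blocks × 4
  trials = 240; each short-block presents each set once in seeded-random
  order; start mode alternates between consecutive short-blocks (first mode
  seeded), giving 60 trials per set = 20/block = 10 immediate + 10 delayed.
- **Refresher**: 12 trials over the trained sets as 3 short-blocks of four
  with the start mode alternating every trial — exactly 6 + 6. (Only the
  6 + 6 total over trained sets is specified; the internal structure is a
  package choice.)
- **Test** (day 2): 9 KM-SG sets — novel KM × 3 test SGs (C1), trained KMs ×
  SGs novel for that KM (C2, 4 sets), 2 retested trained sets (C3) — in 2
  blocks × 10 nonets × 9 trials; each nonet presents each set once; start
  mode alternates every nonet; 20 trials per set, 5 + 5 per block.

Group g of the three groups treats KM g as novel, so each KM is novel in
exactly one group; the four training SGs rotate with the group index; the
fifth SG pair is never trained and is every group's novel test SG. Each
trained KM trains on two SGs, and which of the two is retested as C3 is a
seeded choice — no rule is specified for it. The training SG-to-KM split
(two SGs per trained KM; test matrix = one retested SG per trained KM plus
the never-trained SG) is the only arrangement consistent with five prepared
SG pairs, four trained sets, a 3 × 3 test matrix, and the 3/4/2 condition
partition.

The default key→direction triples are package-defined: the cursor-angle
figure that specified them is not machine-recoverable, so the package uses
one triple per cursor angle (90°: {N, E, SW}; 180°: {E, S, NW}; 270°:
{S, W, NE}) — 90°-rotations of each other, each positively spanning the
plane — and validates them, with the five default SG pairs, against the
structural constraints every scheduled pairing must satisfy: reachable,
shortest length ≥ 2 (in fact 2–5), and no straight single-key solution
("no straight path" is read as "no repetition of one key reaches the goal",
i.e. a zigzag is required). Both the mappings and the SG pairs are
config-overridable (`gridsail.io.load_world`).

## Statistics

Learning curves are raw per-index means (no smoothing) over the within-set
trial index, counted per start mode by default (1–10 in the test session);
the overall index (1–20) is available via `index="overall"` — figure-level
sources do not settle which indexing the original analyses used, so both are
supported. Standard errors are between-subject: trials are first averaged
within subject, then the curve is the across-subject mean ± SEM. The
learning criterion is the first index at or above 80% of the measure's
ceiling (80 points; probability 0.8). Delay gain is the per-set
delayed-minus-immediate mean, aggregated by condition with between-subject
SEMs; sets missing a start mode are flagged and excluded. MAD is the mean
absolute deviation around the *mean* (the mean-centered reading of the
term); "number of steps" for MAD uses total keystrokes, consistent with the
keystroke-counting rule. Trial classes partition by reward: error = 0,
suboptimal ∈ (0, 100), optimal = 100. Inferential statistics (ANOVAs,
post-hoc tests) are deliberately out of scope: logs export to tidy CSV /
JSON Lines for external tools.

## Reproducibility

One master seed spawns per-subject `SeedSequence` children, each split into
per-session streams for assignment, schedule generation, and trial
execution; cohorts are therefore bit-reproducible and subjects independent.
Every output embeds the seed and a config hash. The acceptance script runs
an 18-subject cohort (the paradigm's cohort size) plus 50 exploratory-agent
runs of one 60-trial set; the full protocol is 432 trials per subject, and
the whole battery completes in seconds.

## What the simulator does and does not show

The generator emulates the *structure* of the paradigm — its schedules,
scoring, timing skeleton, and the qualitative strategy signatures (novel-KM
variability, delay-dependent planning gains, ceiling performance on
well-learned sets). It does not model human reaction-time distributions
(reaction time is a two-level charge, not a cognitive model), forgetting
between days, generalization across key-mappings, subject-level parameter
variability, or learned arbitration. Simulated agents learn the
three-key mapping far faster than humans (a handful of presses identifies
it), so absolute learning speeds and condition means sit closer to ceiling
than human data; passing behavioral tests therefore supports directional,
not quantitative, claims about real subjects.
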