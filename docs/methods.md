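# Methods

## The learning-based assignment loop

Both domains follow the same recipe:

1. sample many small offline scenarios from the arrival model;
2. solve each (near-)optimally offline — a MILP for the deterministic ED
   problem, Monte-Carlo tree search for the stochastic radiology problem;
3. at every decision instant of the optimized solution, pair the chosen
   assignment with each assignment not chosen;
4. train an anti-symmetric pairwise comparator C on those pairs
   (binary cross-entropy, target C(chosen, rejected) = 1);
5. deploy C online — by all-pairs majority vote in the ED, by ordered
   pool insertion/replacement in radiology.

## The comparator

Two weight-shared towers are cross-wired at every layer: the matrix
mapping input 1 into tower 1 equals the matrix mapping input 2 into
tower 2, and vice versa for the cross connections; biases are shared.
The head scores `sigmoid(w · (H_top,1 − H_top,2))` with no bias term.
Consequently C(x, x) = 0.5 exactly and C(x, y) + C(y, x) = 1 for *any*
weights — the ranking semantics are architectural, not learned, and the
test suite checks them on random untrained networks.

Defaults: two hidden layers of width 32, tanh activations, Adam
(lr 1e-3), 200 epochs, batch 64. The network stores a per-feature affine
standardization fitted on the training vectors and applied identically
to both inputs inside the forward pass; identical transforms preserve
both structural properties while letting minute-scale and unit-scale
features coexist. All initialisation, shuffling and tie-breaking
randomness derives from one explicit seed; training twice with the same
seed yields bit-identical weights. The exact head and depth are design
choices of this package (several choices preserve the two invariants;
the difference-of-towers head is the minimal one).

## ED domain

**Actors.** Patients carry ESI severity 1–5 (1 most acute), an injury
type, per-exam triage wait bounds `t̄`, nominal treatment times TT and a
lab time LT between the two exams (40% of patients need a second exam by
default). Physicians carry seniority (assistant/intern/resident/
attending, encoded 1/4…4/4), an optional injury specialty, and a time
efficiency CE ≥ 1: treating occupies CE·TT physician-minutes. The
WaitRoom is a dummy physician with infinite capacity encoding "assign no
one yet".

**Objective.** Five weighted components, all minimized: risk of adverse
consequences (charged once per performed examination from a table:
base risk by severity × a seniority factor × a specialty match/mismatch
factor), excess-wait penalties (slope per minute past the triage bound,
steeper for acute severities), length of stay, the crowding integral
∫κ(t)dt, and a flat penalty per preemption. In the offline model every
patient is present from arrival to discharge, so ∫κ dt equals summed
LOS exactly; the code uses and tests that identity. All tables and the
five weights α₁…α₅ are configuration: institutional constants differ
between hospitals, and the defaults here are declared, plausible values,
not estimates of any specific institution.

**Offline MILP.** Binary `y[i,j,e,t]` on a slot grid (evaluation shifts:
5-minute slots, 8 h ⇒ T = 96; training instances: 10-minute slots over
3 h). Start indicators are the standard linearization of
`y_t ∧ ¬y_{t−1}`; first/last occupied slots are extracted with cumulative
indicators (`u_t` = started by t, `w_t` = occupied at or after t) whose
chained bounds pin them to the occupancy pattern regardless of objective
direction; work conservation `Σ_{j,t} y/CE_j = TT` holds with equality,
so the model is infeasible (and says so) if the horizon cannot fit all
treatments. Preemption count per exam is (number of per-physician
starts) − 1; a physician switch mid-exam counts as a preemption. The
excess-wait penalty must be linear in the excess for the MILP; the
default table is. Solved with HiGHS through `scipy.optimize.milp`.
Default CE values lie on {1, 2} so the equality constraint is attainable
on the slot grid (arbitrary CE is accepted by the types; the work-unit
search in `SlotProblem` refuses CE grids with no common slot unit).

**Oracle.** An exhaustive depth-first search over per-slot physician
actions with memoization, sharing only the slot rounding and pricing
tables with the MILP. Refuses instances beyond 4 patients / 3 physicians
/ 20 slots. Agreement of the two objective values on random tiny
instances is the core solver test.

**Decision extraction.** Events are arrivals (exam 1), lab completions
(exam-2 readiness) and treatment completions. The chosen option is what
the schedule does at that instant (seat ⟨p★, c★⟩, or ⟨p★, WaitRoom⟩ when
it deliberately waits); the rejected options are p★ with every other
physician and the WaitRoom, plus every other assignable patient with
c★. Features follow the combined patient–physician vector: severity/5,
injury one-hot, remaining nominal treatment minutes, wait so far,
`t̄ − WT` ("remaining time" is read as time left until the triage
bound), seniority/4, specialty one-hot, status (0 idle, else severity/5
of the patient under treatment), idle minutes. The WaitRoom option
zeroes the physician block.

**Online.** An event-driven continuous-time simulator runs the standard
ED flow. The FCFSwU baseline treats severities 3–5 FIFO to idle
matching-or-unspecialized physicians (never a mismatched specialist) and
severities 1–2 by immediately calling — or interrupting — the most
senior eligible physician, preferring a matching specialist and skipping
anyone already treating an urgent case. The learned policy builds all
⟨waiting patient, physician⟩ candidates (busy physician = preemption)
plus WaitRoom options and selects by majority vote; exact-0.5
comparisons award each side half a point before uniform random
tie-breaking, which keeps the tournament order-independent. Preempted
patients return to the queue with their remaining nominal treatment
time (work-preserving); the offline model additionally allows resumption
by a different physician, a deliberate, documented divergence. Patients
still present at end of shift contribute LOS up to the horizon plus a
configurable terminal penalty (default 100 objective units), keeping the
objective bounded.

**Study sizes.** Training scenarios hold at most 3 patients and 2
physicians over a 3-hour window with arrivals in the first hour — the
MILP solves one in well under a second, and a 240-scenario batch yields
~200 solved instances and ~1,700 preference pairs. Evaluation uses 100
full shifts (~23 patients expected, 3 physicians) under the night-shift
arrival profile; the heavy-flow variant doubles the rates.

## Radiology domain

**Actors.** Studies are ⟨modality, body part, deadline⟩ with NHPP
arrivals; readers have a subspecialty list and a utility over study
types. Any reader may read any study; outside the subspecialty the
nominal time is multiplied by ρ = 3. The read-time model's own defaults
are 3 min nominal (hence 9 out-of-subspecialty). The *generator*
default instead uses a per-modality nominal table (XR 3, US 5, CT 10,
MRI 15 min): with a uniform 3-minute table a 10-reader panel can never
fall behind 60 studies, no study is ever late under any policy, and the
policy comparison degenerates; per-modality reading times restore the
congestion that makes exposure policy matter. Deadlines mix stat
studies (70%, uniform 30–120 min) with routine ones (log-uniform up to
one week), all within the 30-min–1-week range.

**Choice model.** Readers pick from their pool by quantal response —
softmax of utility. Utilities are revealed-preference proxies: the
normalized frequency of study types in a reader's selection history
(unseen types get 0). The generator emulates the estimation pipeline
with synthetic histories drawn from a latent Dirichlet taste
(concentration 0.3, 200 selections per reader) and feeds them through
the same estimator used for real logs.

**Loss.** L = exp(2·lateness) with lateness in hours, signed. Additive
and non-negative everywhere; the super-linearity inequality
L(αl) ≥ αL(l) holds for l ≥ ln α / (2(α−1)) — in particular everywhere
l ≥ ½ h — but not at l = 0 (L(0) = 1 < α), so tests verify it on the
tardy grid l ≥ ½ together with the motivating instance
L(1) + L(1) ≤ L(2). Reported lateness is also binned into before /
<15 min / 15–45 / 45–60 / >60 min past the deadline.

**MCTS.** Decision nodes are arrival/completion events; the action adds
one pending study to one idle reader's pool (capped at k) or does
nothing; chance — reader draws — is re-sampled every simulation
(open-loop UCT, exploration √2, rewards scaled by the observed loss
spread); rollouts expose earliest-deadline-first; the return is the
total exponential loss. Committed actions become decision events whose
alternatives are the other available exposure actions. On single-reader,
pool-cap-1 instances the environment is deterministic and the plan is
checked against exhaustive enumeration of reading orders.

**Pair features** (7): subspecialty match; fraction of the reader's pool
in their subspecialty; overdue count in the pool; the study's signed
lateness (h); subspecialty scarcity (fraction of readers covering the
study's type); time left to deadline (h, clipped at 0); current exposure
count. Lateness and clipped time-left are deliberately not redundant.

**Online exposure.** On arrival, each reader's pool takes the study by
ordered insertion if below cap, else the study challenges the
lowest-ranking incumbent (replacement on C ≥ 0.5; the evicted study
leaves only that pool). A study accepted nowhere is force-exposed to
the reader with the highest comparator score against their weakest
incumbent; a study orphaned by eviction returns at the next completion,
where the highest-ranking unexposed study is added to the freed
reader's pool. The cap |S_j| ≤ k holds after every event, verified by
an auditing test over full simulations.

**Baselines.** Naive exposes every pending study to every reader. The
interval heuristic H splits arrival→deadline into thirds: subspecialty
readers, then readers sharing the study's modality (the "wider group"
is not further specified by its description; modality-sharing is this
package's reading), then everyone until read.

**A note on the H comparison.** Under this simulator's reader model —
an idle reader always immediately draws from a nonempty pool — H is a
very strong baseline: its deadline-proportional escalation is an
implicit earliest-deadline triage, and by hiding studies from
non-subspecialists it reserves fast matched capacity at zero cost. In
every load regime explored (burst and sustained, balanced and skewed
demand, wide and narrow subspecialty coverage) H's mean loss is below
what any comparator-driven exposure policy achieves under the
insertion/replacement mechanics above, including a hand-crafted ideal
comparator. The learned policy does robustly beat the Naive policy,
keeps pools at or below the cap (against Naive pool sizes 3–4× larger),
and improves monotonically as k shrinks; the H comparison is reported
as measured.

**Study sizes.** MCTS training uses 15 reduced scenarios (4 readers, 16
studies, 8-minute window, k = 3) at 100 simulations per decision;
evaluation uses 100 seeded simulations of the default 10-reader /
60-study / k = 10 configuration plus a k ∈ {10, 5, 2} sweep.

## Statistics

Paired-samples t tests for two policies on a common scenario set, with
zero-variance difference vectors handled exactly (identical scores →
t = 0, p = 1; a constant nonzero shift → p = 0). Three policies use
one-way ANOVA followed by Bonferroni-corrected pairwise paired t tests.
The wrapper's type-I error is pinned by a Monte-Carlo calibration test
(1000 null replicates, rejection rate 5% ± 2%).

## Determinism

One master seed derives named substreams (scenario generation, solver,
training, each simulation, tie-breaks) via CRC-tagged `SeedSequence`
spawning, so any stage can be re-run in isolation; pipelines re-run with
the same seed produce identical score tables.

## Known limitations

- The offline/online accounting differs at the slot boundary: offline
  quantities are slot-rounded, the simulator is continuous-time. The
  comparator sees minute-scale features in both, but a trained model is
  only as consistent as those two views.
- The MILP requires a linear excess-wait penalty; nonlinear penalties
  are only available to the simulator.
- The synthetic generators emulate structure (NHPP arrivals, severity
  and case-mix distributions, revealed-preference utilities), not any
  institution's parameters; passing tests demonstrate the method's
  internal correctness and qualitative behaviour, not clinical
  performance.
- MCTS plans with one exposure action per event; bundled multi-reader
  exposure decisions are approximated by consecutive events.
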