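# Methods

## Cell model

A cell is a three-state oscillator timed automaton (states F, R, A; one
integer clock; guards `f`, `r`, `a`). The states correspond to the
piecewise-linear phases of the atrial/pacemaker action potential: rapid
depolarisation (F), plateau and repolarisation (R), and diastole (A). We use
*increment-then-check* step semantics: each global step the clock advances by
one (unless halved by a neighbour interaction) and the guard of the current
state is then evaluated, so a state with integer guard θ lasts exactly θ
steps and an isolated cell fires with period exactly `f + r + a`. Clocks are
integers; the refractory guard may be fractional (`r = r0 + r_noise·ξ`), and
the guard test `x ≥ r` makes the effective refractory length `⌈r⌉` steps.

Refusal of the fire transition is a per-step Bernoulli trial with probability
`p_refuse`, re-tested every step while the guard holds, and applies to both
intrinsic (`x ≥ a`) and forced firing. This is the simplest consistent
reading of a cell "refusing" an enabled excitation; it implies the extra
delay before an enabled cell fires is geometric with success probability
`1 − p_refuse` (a property the tests check). Refusal applies to every role —
pacemaker, atrial and AVN cells alike — and can be restricted per role.

Precedence within one step: forced firing (A-cell, more than `N_F` firing
in-neighbours) > clock halving (R-cell, more than `N_R`) > intrinsic guard
transition > time pass. The halving replaces that step's clock increment and
may re-apply on consecutive steps while neighbours keep firing. Interactions
model fast junctional currents, hence their priority over the intrinsic
cycle.

## Tissue

Cells occupy an `L × L` square lattice with open boundaries. Each unordered
neighbour pair is linked independently: vertically with `p_V` (default 1 —
columns always conduct, mimicking the longitudinal fibre direction),
horizontally with `p_H`, diagonally with `p_L`. Sparse transversal coupling
(`p_H = p_L` low) emulates fibrosis. Within the atrium edges are symmetric.

The SAN is an elongated rectangle of self-exciting cells (default 20 rows ×
4 cols at rows 10–29, cols 2–5 of a 100-lattice). SAN-internal links are
drawn with a single common probability (default 1.0 — a dense node). No edge
enters the SAN; one-way SAN→atrium pathways leave a random half of the SAN
cells that border the atrium ("bordering" = having at least one non-SAN cell
in the 8-neighbourhood; the fraction rounds half-up). Exit edges are drawn
with the same direction-class probabilities as atrial edges.

The AVN is a 2 × 4 block centred on the bottom row. Its cells are ordinary
atrial automata; only event counting differs: an AVN excitation is registered
when at least `avn_k` AVN cells are simultaneously in F, edge-triggered (the
detector re-arms when the count drops below `avn_k`), so one wavefront
registers one beat. `avn_k` defaults to 3 of 8; the drifting-fatigue
experiment uses 2, which reduces missed beats.

## Defaults and units

One step ≈ 7 ms (RR series are scaled ×7 for comparison with recordings).

| parameter | default | meaning |
|---|---|---|
| SAN `f, r, a` | 5, 70, 40 steps | `T_SAN` = 115 steps ≈ 805 ms |
| atrial `f, r0, r_noise` | 5, 50, 10 steps | refractory 50–60 steps, 20% spread |
| atrial `a` | 10·T_SAN | atrial cells never self-fire in driven tissue |
| `N_F`, `N_R` | 0, 3 | one firing neighbour excites; >3 prolong refractoriness |
| `p_V` | 1 | columns always conduct |
| `avn_k` | 3 (walk runs: 2) | simultaneous AVN firings per beat |
| transient | 10 beats | discarded before classification |
| `total_steps` | 6000 | ≈52 pacemaker periods, ≈40 analysed beats |

The initial condition is all cells at (A, x = 0): the pacemaker fires first
in unison after `a_SAN` steps. An optional policy randomises SAN clocks to
exercise pacemaker self-organisation.

## Rhythm classification

Labels are decided from the post-transient RR series relative to the
*nominal* `T_SAN = f + r0 + a` (not the empirical rate, which keeps the rule
robust under refusal jitter), in a fixed cascade:

1. empty series, or mean RR > 3·T_SAN → **dead** (over two thirds of
   excitations lost);
2. span(RR) < 0.25·T_SAN and |mean RR/T_SAN − 1| ≤ 0.10 → **normal** — the
   0.25 bound transfers the 200 ms/800 ms variability limit of a healthy
   human rhythm;
3. otherwise, beats < 0.75·T_SAN mark re-entrant doubling and beats
   > 1.25·T_SAN missed beats: short only → **san_arrhythmia**, long only →
   **lost_normal**, both → **lost_arrhythmia**, neither → normal
   (wide-but-bounded fallback, logged).

The 10% mean tolerance is our choice where the rule's prose ("approximates")
gives none; all thresholds are configurable. Fibrillation is not separately
detected from the RR series alone; it folds into lost_arrhythmia. The
cascade is scale-invariant under joint rescaling of RR and `T_SAN`.

## Experiments

**Phase diagram.** For each grid point of (`p_H = p_L`, `p_refuse`), `reps`
independently seeded tissues are simulated and classified; the table holds
per-label frequencies (probability vectors) and the modal label.

**Wavefront velocity.** Because columns always conduct, the first wavefront
reaches the bottom border as fast as the dynamics allow; the signed delay
until the first AVN event, `t_avn_first − t_bottom_first`, measures the
effective slowing by sparse transversal coupling and refusals. On a
deterministic tissue this equals a breadth-first arrival-time computation
from the SAN exit cells (used as an independent oracle in the tests).

**Drifting fatigue.** `p_refuse` performs a random walk on `[0, z]`: each
step, with probability `p_walk`, it moves by ±ε (random sign); moves leaving
the interval are rejected, not clamped. Defaults `p_walk = 0.001`,
`ε = 0.05`, `z = 0.45` at `p_H = p_L = 0.5`, `avn_k = 2`.

## RR editing and pattern matrices

Recorded tachograms are edited to normal-to-normal series: runs of
non-normal beats shorter than 5 are substituted beat-by-beat with the median
of the last seven preceding normal intervals (always 7 values, so the median
is the 4th order statistic); runs of 5 or more — or runs without seven
preceding normals — are deleted and the junction logged. Output is truncated
to 20 000 beats. The edit is idempotent on its own output.

The pattern matrix `P(ΔRR_i, ΔRR_j)` bins consecutive *overlapping*
increment pairs on both axes, bins half-open `[c − w/2, c + w/2)` centred on
zero, support auto-sized symmetric about zero, mass normalised to one. Pairs
are never formed across deletion junctions. Bin width mirrors the data
resolution: 8 ms for Holter series, 7 ms for ×7-scaled model output, 1 step
for raw model output.

## Synthetic fixtures

`gen_synthetic_rr` emulates the *format and increment statistics* of an
edited Holter series: intervals quantised to 8 ms, a reflecting bounded
random walk of the interval around its base value (controlled increment
magnitude), and planted runs of non-normal beats. It carries no autonomic,
circadian or respiratory structure, so tests passing on it demonstrate the
editing/pattern pipeline's correctness, not physiological realism.

## Numerical choices

* Synchronous update from a phase snapshot; the vectorised engine (sparse
  in-adjacency matrix–vector product for neighbour counts) is verified
  state-for-state against the scalar per-cell rule on 12×12 lattices.
* One uniform deviate per cell per step (row-major) for refusal, one per
  unordered pair for edges, one per cell for refractory draws: runs are
  bit-reproducible from the seed, and tissues replay exactly from JSON.
* Strict inequalities where the rules state them: interaction thresholds
  (`> N`), the normal-span bound (`< 0.25·T_SAN`), patching (`< 5`).
* Walk bounds enforced by rejection; with ε not dividing z the walk still
  respects `[0, z]`.
* Problem sizes in the test suite (12×12 oracle runs, 24×24 sweep fixtures,
  50 realizations at L=100 for the critical-density check, a 120 000-step
  walk run) are chosen to keep the full suite around two minutes while
  leaving each check statistically meaningful.

## Known limitations

* The region geometry, timers and thresholds are plausible reconstructions
  (all configurable); quantitative phase-diagram boundaries depend on them.
  With these defaults the normal rhythm dominates already at low transversal
  density — the re-entry-dominated sparse regime requires a larger
  atrial-refractory to pacemaker-period ratio than the defaults give — so
  phase-diagram positions should be read qualitatively.
* Missed-beat epochs under the drifting-fatigue experiment are infrequent at
  `avn_k = 2`; the robust signatures are the widened RR distribution and
  off-origin pattern-matrix mass.
* The AVN is a passive detector (no internal architecture, no conduction
  delay); ventricular propagation is assumed perfect.
* No autonomic regulation, no fibroblast/extracellular-matrix mechanics, no
  anatomically realistic 3-D geometry, and no two-pacemaker (biatrial
  transplant) variant.
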