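# Methods

This note documents the models and procedures implemented in `traminer`, the
assumptions behind them, the synthetic data used to exercise them, and the
numerical and design choices made where the problem left room.

## Problem setting

A single senior lives in a smart home instrumented with passive-infrared
(PIR) ceiling motion sensors and door sensors.  Every sensor activation
witnesses the resident's presence near a known position, so the event stream
induces a coarse position history.  The goal is a screening signal for
cognitive decline: classify locomotion into the three clinical groups
*cognitively healthy*, *MCI* (mild cognitive impairment), and *PwD* (person
with dementia), using the wandering phenomenology of the Martino–Saltzman
model (pacing, lapping, random travel) and low-level gait/trajectory
indicators.  Single movement bouts carry weak signal; the design therefore
classifies every trajectory and aggregates per-person predictions over a long
observation window by majority vote into a hypothesis of diagnosis — a
screening aid, not a diagnosis.

## Pipeline

### Cleaning

PIR positioning is noisy: misfires produce teleport-like jumps.  Two
plausibility thresholds are applied to consecutive record pairs in one
forward scan anchored at the last surviving record:

* maximum speed `T_v` = 15 m/s — faster apparent movement is physically
  impossible indoors;
* maximum step displacement `T_d` = 5 m — adjacent sensors are < 3 m apart,
  so a longer step skipped non-contiguous sensors.

The offending record (the later of the pair) is deleted and the survivor
remains the comparison anchor; this is equivalent to re-scanning the whole
history after every single deletion (asserted against a brute-force re-scan
oracle in the tests).  Records with identical timestamp and position
collapse to one; a zero-time step to a different position implies infinite
speed and is deleted.

### Segmentation

The cleaned history is partitioned into *trajectories*: maximal runs whose
inter-record silence never exceeds `T_s` (30–180 s; 120 s is the default).
A silence longer than `T_s` closes the bout.  The two statements one could
make about the record at a boundary — that trajectories are non-overlapping,
and that the next trajectory starts from the previous bout's last record —
conflict; we honor non-overlap (the partition definition) and start the next
trajectory at the first record after the gap.  `shared_boundary=True`
reproduces the literal shared-record reading.  Trajectories with fewer than
2 records have no drawable path and are dropped.

### Image encodings

All trajectories of a deployment are rasterized onto one fixed canvas
(100 × 130 px over the home's bounding box plus a 0.5 m margin; uniform
scale, top-left origin, ≈ 0.1 m² per pixel), so pixels are spatially
comparable across samples.

* **TRAJ** encodes path geometry: each undirected edge between consecutive
  (mm-quantized) positions is drawn once, white on black, with stroke
  thickness equal to the number of traversals (capped at 7 px so repeated
  pacing does not blob out); proper self-crossings of non-adjacent segments
  are overdrawn as filled red circles of radius max(1 px, 0.25 m).  Collinear
  re-walks are rendered by thickness, not treated as crossings.  Thickness
  captures pacing/lapping; red markers capture the intricacy of random
  travel.
* **SPEED** encodes gait: every consecutive record pair is a constant-speed
  section colored by its speed range — [0,2), [2,4), [4,6), [6,8), [8,10),
  [10,12), [12,15), [15,∞) m/s mapped to purple, violet, blue, cyan, green,
  yellow, orange, red — drawn 1 px wide in temporal order so the most recent
  speed of a re-walked section wins.  The seventh bin extends to 15 m/s so
  the bins tile the half-line with the open-ended red bin starting exactly
  at 15.  The ranges far exceed human gait because apparent inter-firing
  speed is inflated by the ~1 m sensor resolution and overlapping detection
  ranges.
* **Sensor-sequence (GVFE) baseline**: a binary raster with temporal firing
  order on x and the sensor's ordinal identifier on y; one pixel per firing.
  Height equals the sensor inventory (67 for the default layout) regardless
  of `T_s`; width is a corpus constant (the maximum trajectory length), and
  longer sequences are an error, never truncated.

Images are consumed as binarized (value > 0 → 1) row-major flattened
vectors; the default canvas gives 3·100·130 = 39,000 features per image.
No anti-aliasing is used anywhere, since binarization would destroy it
unpredictably.

### Classifier

The two-branch MLP takes the TRAJ and SPEED feature vectors through
identical branches — dense 32 (ReLU) → batch-norm → dense 32 (ReLU) →
batch-norm → dropout 0.5 — concatenates them, and applies a 3-neuron head
followed by batch-norm and dropout before the softmax.  The softmax is the
standard max-stabilized exponential normalization over the head's outputs.
Batch-norm and dropout after a 3-unit output layer are unusual (the dropout
randomly zeroes logits during training); `head_batchnorm=False` disables
both.

Training: categorical cross-entropy, Adam at learning rate 1e-5, batches of
64, at most 100 epochs, early stopping on a stratified 10 %-per-category
validation split with best-weights restoration.  The early-stopping window
is sized for small validation sets: at the default cohort scale the split
holds only ~58 trajectories, whose epoch-to-epoch loss noise exceeds the
slow per-epoch improvement at this learning rate, so a tight patience
aborts long before convergence.  The default is therefore patience 15 with
a 20-epoch minimum (20 epochs being the lower end of the epoch range the
training procedure is designed around).  Everything
is float32 and fully deterministic under a seed; batch-norm uses running
statistics (momentum 0.99, eps 1e-3) in inference mode, making the frozen
forward pass batch-size invariant.  The engine is a compact numpy
implementation (dense, batch-norm, dropout, im2col convolution, Adam); the
first dense layer of each branch skips its input gradient, which is never
used.

The convolutional baseline follows the architecture used in prior smart-home locomotion-image work:
three zero-padded 5×5 convolutions with 32, 128, 256 filters, each followed
by 2×2 max pooling (halving the feature maps), then dense 512/128/64 and a
3-way softmax.

### Long-term aggregation and evaluation

Per person, the history of per-trajectory classifications is reduced to the
most frequent class.  Ties resolve toward the more impaired class (PwD >
MCI > healthy) — clinically conservative — and set an explicit flag.
Evaluation is leave-one-person-out: each person is the test subject exactly
once and never contributes to that fold's training or validation.  Metrics
are per-class precision/recall/F1 and their unweighted macro means; a class
with no true (no predicted) instances has undefined recall (precision),
reported as n/a and excluded from the macro mean rather than coerced to 0.

## Numeric baseline (NFE)

Per trajectory, locations are discretized to the firing sensor and scanned
left-to-right for non-overlapping maximal episodes: pacing (≥ 3 consecutive
back-and-forth moves between two locations), lapping (≥ 2 consecutive
circuits over ≥ 3 distinct locations), and — among leftover runs — random
(> 4 distinct locations with ≥ 2 heading changes of ≥ 45°).  When a pacing
and a lapping window start at the same record, the longer window wins,
pacing on ties; consumed records cannot seed another episode.  The episode
semantics are validated exhaustively against a brute-force window
enumeration on every sequence of length ≤ 8 over 4 locations.

Low-level indicators per trajectory: per-segment speeds are differentiated
at segment midpoints into per-junction accelerations and then into jerk
(mean absolute value; a trajectory with a single acceleration sample has
constant observed acceleration and reports jerk 0; with none, NaN);
heading-change angles at interior points (straight-ahead 0°, U-turn 180°)
give the sharp-angle count (≥ 90°) and total turning angle (degrees); path
efficiency is start-to-end displacement over path length (0 for a closed
path of positive length); straightness is chord-over-arc at each interior
junction, averaged — the bounded-in-(0,1] reading of an ambiguous verbal
definition; the daily NFE vector sums pattern and sharp-angle counts and
averages jerk and straightness weighted by interior-junction count.
Statistics that need more points than a trajectory has are NaN, never 0.

## Synthetic cohort

The simulator exists so every stage is testable without any external
dataset.  It emulates:

* a 10 m × 13 m six-room apartment with 51 motion sensors on a jittered
  ~1.4 m grid (thinned so that no two removed grid nodes are adjacent,
  keeping nearest-neighbor spacing ≤ 3 m) and 16 door sensors on walls —
  67 sensors, the inventory the pipeline's defaults assume;
* single-occupant activity: per person-day, 20 trajectories, each a chain of
  movement legs whose Martino–Saltzman pattern is drawn from a
  class-conditional mix (healthy 0.85/0.07/0.05/0.03 for
  direct/pacing/lapping/random; MCI 0.55/0.22/0.18/0.05; PwD
  0.25/0.20/0.20/0.35).  Wandering prevalence grows with impairment, and
  its *kind* shifts: early impairment mostly paces and laps, advanced
  dementia adds disproportionately more random travel — which is what lets
  a classifier tell the intermediate class from both neighbors;
* a severity gradient within the wandering patterns: pacing episodes run up
  to 4/8/14 back-and-forth moves and lapping up to 2/3/5 circuits for
  healthy/MCI/PwD, and activity bouts chain 2–4/4–7/6–10 legs — disoriented
  locomotion both repeats more and lasts longer;
* gait slowing: person-level speed drawn from N(1.1, 0.12), N(0.85, 0.12),
  N(0.6, 0.12) m/s for healthy/MCI/PwD, truncated to [0.3, 1.6] m/s
  (indoor gait norms);
* sensor artifacts: *early firings* (20 per 100 events) compress the
  apparent inter-firing time by a factor U(0.15, 0.6), reproducing the
  overlapping-detection-range effect that inflates apparent speeds into the
  upper speed bins — more strongly for faster walkers, which is what makes
  the SPEED encoding class-informative; and *teleport misfires* (2 per 100
  events) that jump > 5 m and must be removed by cleaning (they violate the
  thresholds by construction, so removal is exact);
* inter-trajectory silences U(240, 600) s, longer than any `T_s` in the
  sweep, so ground-truth bout boundaries are exactly recoverable.

Default cohort: 12 healthy, 10 MCI, 8 PwD (30 persons, 600 trajectories) —
class imbalance mirroring prevalence, small enough for a desk-scale
leave-one-person-out run.  Everything is deterministic given the seed
(per-person seed streams are spawned from the cohort seed).

What the simulator does **not** emulate: walls and furniture (paths ignore
room boundaries), activities of daily living that superimpose their own
movement patterns, multi-resident homes, door-usage semantics, sensor
dropout, and day-to-day behavioral drift.  Real deployments confound the
wandering signal with all of these, so passing the synthetic recovery test
demonstrates that the pipeline's machinery is correct and that the method
can recover a class-conditional locomotion structure when present — not
that it attains any particular accuracy on real homes.

## Problem sizes

The default synthetic experiment sizes were chosen to keep a full
leave-one-person-out run of the two-branch MLP practical on a single CPU:
30 persons × 20 trajectories (600 image pairs of 39,000 features each, 30
training runs).  The exhaustive pattern-detector sweep covers all 87,380
location sequences of length ≤ 8 over 4 locations; the cleaning oracle
comparison uses 1,000 random noisy histories.

## Known limitations

* The cleaning scan deletes only the later record of an offending pair; a
  corrupted *first* record therefore anchors the scan and can delete valid
  successors.  The alternative (re-examining earlier records) is noted in
  the design ledger but not implemented.
* Straightness follows one of two defensible readings of its verbal
  definition; the package documents the chord-over-arc reading.
* The intersection-marker radius (0.25 m) is below one pixel at the default
  scale; a 1 px minimum keeps the markers visible, slightly enlarging them
  relative to scale.
* Early stopping on a small validation split (≈ 58 trajectories per fold at
  default sizes) is noisy; fold-to-fold epoch counts vary widely.
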