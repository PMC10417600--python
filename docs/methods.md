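# Methods

## Scope and data model

The package begins where the detector ends. Its unit of input is a
detection stream: one CSV row per bounding box, one row with empty box
fields per frame with no detections, keyed by
`(experiment_id, replicate, day, session, compartment, frame_index)`.
Empty frames are first-class records, not missing data — permanence time is
a sum over *all* frames of a cell, and dropping empty frames would bias it
upward. Timestamps are derived from `frame_index / fps` anchored to the
session's time of day when the source provides none; window membership uses
half-open intervals `[start, end)` so a frame on a boundary is counted
once. Boxes live in continuous pixel coordinates, origin top-left, and the
centroid is the arithmetic midpoint; frames default to 702 × 480 px but are
configurable. Video decoding and detector training/inference are out of
scope by design.

## Unrest index

The per-pair statistic is `k · max(d(A, B), d(B, A))` over centroid sets of
consecutive frames, with `d` the directed Hausdorff distance (max over one
set of the nearest-neighbour distance into the other). Among the candidate
set distances (max-min, mean-min, sum-min) only the max-min reading makes
the outer two-direction max meaningful, and it keeps the index free of
individual identities, which multi-bird detectors cannot provide. The
implementation (vectorised distance matrix) is checked in the tests against
an exhaustive max-min oracle and against an independent directed-Hausdorff
routine.

Parameters:

* `k` (dimensionless, default 1.0) — camera proportionality factor; 1.0
  corresponds to a 90° field of view. No formula mapping field of view to
  `k` is provided upstream, so none is invented; users supply it.
* `empty_frame_policy` (default `missing`) — a pair with an empty side
  yields NaN and is excluded from aggregation, because absence of
  detections is not evidence of stillness; `zero` is available for
  sensitivity analysis.

Pairs are formed only within contiguous segments (same session/window and
compartment, frame indices advancing by the stream's step), never across
window gaps. For statistics the unit is the mean unrest per 2-h observation
window, which gives balanced replicate counts per treatment cell.

## Permanence time and occupancy

`T_L` is the summed per-frame count divided by the *effective* frame rate
of the stream actually summed. With the 2× down-sampled 15 fps streams this
makes `T_L` invariant to down-sampling of a static scene, and on noise-free
data `Σ_L T_L = flock_size × duration` exactly. (The source material's
prose divides by the 30 fps capture rate while analysing 15 fps streams;
this implementation treats that as an inconsistency and always divides by
the effective rate.) A per-bird normalisation (`minutes_per_bird`) is
reported with a configurable denominator — flock size, optionally ×
replicate-days — because no single convention is canonical.

Doorway double-detections (a bird straddling an automatic door seen by two
cameras) are handled by `resolve_duplicates`: boxes within a configurable
margin of a shared door edge on both sides are greedily paired (nearest the
door first) and the smaller-area member removed, one removal per pair — a
proxy for manual head-location adjudication, which pixel data cannot
reproduce. Suppression defaults to **off**, matching the automatic pipeline
whose residual over-count rate is small; door geometry is declared in
configuration (which image edge abuts which neighbour), never inferred from
pixels.

## Detector validation

Count-level validation tallies aligned true/predicted counts into a square
confusion matrix; exact-count accuracy is `100 · trace / total` (reported
to 1 decimal) and the over-count-by-one rate is the superdiagonal share
(2 decimals). Box-level quality is a single-class average precision:
predictions greedily matched in descending confidence to unmatched ground
truth at IoU ≥ 0.5 (default), AP computed with the all-point (continuous)
interpolation — stated explicitly since conventions differ. The manual
sample is sized by the finite-population formula
`n = p(1−p)Z²N / (ε²(N−1) + Z²p(1−p))`, rounded **up**: a sample size must
cover the margin. For the 35 M-frame population at 99% confidence and 4%
margin this yields 1041 with Z = 2.58; the exact 99% quantile 2.576 would
give 1037, and both quantiles are supported (`Z=` or `confidence=`).

## Treatment comparisons

One-way ANOVA uses the standard between/within decomposition; the balanced
two-factor (light × temperature, interaction) model is fitted by OLS via
statsmodels, with unbalanced or incomplete tables rejected outright — in
the balanced case all sums-of-squares types coincide, so no silent type
switching can occur. Tukey HSD computes
`q = |m_i − m_j| / sqrt(MSW/2 · (1/n_i + 1/n_j))` (Tukey–Kramer for unequal
n) with p-values from scipy's studentized range distribution; the tests
verify agreement with statsmodels' `pairwise_tukeyhsd` to 3 decimals.
Compact letter displays use insert-and-absorb: start from one column of all
groups, split on each significant pair, absorb dominated columns; the
sharing relation of the result equals the non-significance relation by
construction (property-tested over all graphs on 4 nodes). Statistical
units are window-level unrest means and per-replicate permanence totals;
degenerate inputs (zero within-group variance) yield flagged NaN/infinite
statistics rather than exceptions.

## Synthetic chamber

Each bird is an independent continuous-time Markov chain on the compartment
graph with jump rate `q(c→d) ∝ w(d)` for adjacent `d`, where `w` maps each
compartment's light (under the experiment's rotation) to a preference
weight. These rates satisfy detailed balance, so the stationary occupancy
is exactly `w / Σw` on a fully connected chamber — an analytic oracle for
parameter-recovery tests — and `stationary_occupancy` solves the global
balance equations of any configured chain. The overall rate is normalised
so the stationary mean number of moves per bird-hour equals `switch_rate`.

Within a compartment the centroid follows a reflected Gaussian walk with
per-frame step SD `within_step_px × activity_scale[thermal]`; on entry
after a crossing the bird appears just inside the door edge. Observation
noise: centroid jitter (SD 2 px), a small per-frame miss probability
(0.002), and — the detector's one systematic failure mode — a stale
double-detection in the vacated compartment at a crossing (probability 0.5
per crossing, persisting 0.5 s), which produces only +1 over-counts, the
error structure seen in manual validation. Boxes are fixed-size rectangles
(80 × 60 px) around detected centroids, since the analysis consumes only
centroids and counts.

Defaults that are genuinely unknown in the field are labelled as choices:
`switch_rate = 12` moves per bird-hour is an order-of-magnitude guess (no
transition counts are published for hens in such chambers); the scenario
presets (`thermoneutral`, `cold`, `hot`) encode the qualitative pattern —
white preferred, green avoided, preference flattened and activity reduced
under heat stress — for demos and power checks, never as ground truth about
hens. What the simulator does **not** emulate: perch/nest attraction,
social cohesion or avoidance between birds, diurnal activity rhythm within
a window, detector confidence scores, and box-shape variation; passing
tests therefore certify the *pipeline arithmetic* on streams with the
assumed statistical structure, not the behavior of real flocks.

## Numerical and test-design choices

* Parameter-recovery acceptance runs use 10⁵ frames and a fast-mixing
  chain (900 moves per bird-hour): the Monte-Carlo error of an occupancy
  fraction is governed by the number of dwell episodes, not frames, and
  ≈10⁴ episodes put 3 standard errors inside the ±0.02 check band. Mixing
  speed does not change the stationary law being verified.
* Simulated test sessions are kept short (tens of seconds to minutes of
  chamber time) except where a check's variance demands more; the full
  54-day design is never simulated wholesale.
* CSV floats are parsed with correctly-rounded conversion so a written
  stream reads back bit-identically; the canonical writer sorts rows by
  (experiment, replicate, day, session, compartment, frame).
* All simulator randomness flows from a single mandatory integer seed;
  pipeline runs derive per-session seeds from the manifest seed, and a
  manifest reproduces byte-identical outputs (SHA-256 checksums recorded in
  `summary.json`).
* Reporting rounds accuracy to 1 decimal and rates to 2 decimals;
  underlying functions return full precision.

## Known limitations

Duplicate suppression is a geometric proxy and cannot recover the true
head-side compartment; factorial ANOVA is balanced-only; no mixed models or
repeated-measures corrections are offered (window means are treated as
exchangeable replicates); the simulator's movement model is not
biomechanical and its noise model omits false positives away from doors.
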