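# Methods

This note documents the models, parameter choices and numerical
conventions behind `ethousv`, and what the synthetic-data tests do and do
not demonstrate about real recordings.

## The analysis problem

Pairs of rats are recorded for 20 minutes spanning a light/dark
transition: 10 minutes before and 10 minutes after the lights switch.
Video (12 fps) is tracked into per-frame keypoints for 12 body parts per
animal; audio (250 kHz) is reduced to a table of detected ultrasonic
calls. The scientific questions are (a) whether the lighting change and
the phase of the experiment (habituation over days) alter the duration of
11 social behaviors and 4 call types, and (b) how strongly behaviors and
call types co-occur on a common 1/12-s frame timeline.

## Pose cleaning

A keypoint observation is trusted when its detection likelihood is at
least the p-cutoff (default 0.6, configurable). Untrusted coordinates are
replaced by the value at the temporally nearest trusted frame; exact ties
between an earlier and a later neighbour resolve to the earlier frame,
which also matches the leading-edge backfill behaviour. A keypoint
trusted in no frame of a session is set to (0, 0) throughout and recorded
in the track's `zero_filled` set so centroid means can exclude it. No
outlier correction beyond this is attempted, and identity swaps are not
repaired. Interpolation is idempotent because likelihoods are kept as
bookkeeping rather than overwritten.

Zero-fill is applied to *coordinates*; derived features then inherit the
convention (a centroid whose constituents are all zero-filled is (0, 0)).

## The 111-feature vector

Two polygon features plus 109 custom features. The custom inventory is
fixed in `features.py` (`feature_manifest()` exports it) and spans every
feature family the classifiers rely on:

| family | count |
|---|---|
| keypoint likelihoods | 24 |
| centroid coordinates (body/head/anogenital × 2 animals × x,y) | 12 |
| 1-s rolling-mean centroid coordinates | 12 |
| convex-hull areas (body, head × 2 animals) | 4 |
| 1-s rolling-mean hull areas | 4 |
| hull-area change ratios (area / its rolling mean) | 2 |
| per-frame centroid movements | 6 |
| 1-s rolling movement sums | 6 |
| summed whole-body movement of both animals | 1 |
| between-animal centroid distances (3 × 3) | 9 |
| rolling means thereof | 9 |
| minimum over the 9 distances | 1 |
| raw cross-part distances (nose–nose, nose–anogenital ×2) | 3 |
| within-animal distances (nose–back, head-cent–anogen-cent, nose–tail end ×2) | 6 |
| body elongation (nose–pelvis ×2) | 2 |
| body-axis angles (nose–head–back, head–back–pelvis ×2) | 4 |
| per-animal mean and min likelihood | 4 |

Conventions: the head centroid uses the four rostral parts (nose, both
eyes, head); the anogenital centroid uses pelvis, anogenital and
tail-middle. Angles are taken at the middle vertex, in degrees in
[0, 180]; degenerate (zero-length) arms give 0. Rolling windows are
trailing, one second (= fps frames) long, truncated at session start;
movements are 0 at frame 0.

Polygon features: body polygons are the convex hulls of each animal's 12
keypoints; `polygon_pct_overlap` = 100 × intersection / min(area_A,
area_B) — the *smaller* hull as denominator deliberately saturates when
one animal sits on top of the other (mounting, crawling) — and
`difference_area` is the absolute (unsigned) area difference. A hull with
fewer than three distinct points has area 0 and overlap 0. Hulls and
intersections are computed with shapely's vectorised geometry kernel.

When polygon and custom tables are merged, rows truncate to the shorter
table, mirroring per-stage exports that can differ by trailing frames.

## Behavior classifiers

One independent binary random forest per behavior (frames may carry
several behaviors, so this is multi-label). Training uses the entropy
split criterion, a stratified 80/20 train/held-out split and no
resampling; 100 trees by default (the forest size is our choice; it is
not critical and is configurable). The stratified split keeps positives
of rare behaviors on both sides. The held-out "20 %" is read as a test
fraction, not a training fraction — training on 20 % of labeled frames
would discard most of the scarce annotation effort for no benefit.

Precision–recall curves are evaluated at every distinct score (plus 0)
under the strict-greater prediction rule; F1 = 2PR/(P+R), defined 0 when
P + R = 0. `select_threshold` returns the arg-max-F1 point, ties toward
the higher threshold (the stricter detector). Because F1 is
piecewise-constant between distinct scores, the *operating* threshold
stored in the classifier bundle is the midpoint of the winning plateau
(halfway to the next distinct score): the literal arg-max point coincides
with the largest held-out negative score and generalises poorly to new
sessions, while any point on the plateau has identical held-out F1. A
config override (`ClassifierBundle.override_thresholds`) replaces the
manual video-inspection tweaking a human operator would do.

Prediction: a behavior is present in a frame iff its forest probability
is strictly above its threshold; a probability exactly at the threshold
is absent. Minimum bout length is 0 — durations are exact to 1/12 s, but
bout *counts* then undercount fragmented episodes, which is why the
aggregation stage reports durations as the primary measure.

## Call typing

Detector paths: `hf` (50-kHz detector) and `lf` (22-kHz detector). An
`lf` detection is ALARM regardless of shape. For `hf` (or unknown-path
records with principal frequency ≥ 32 kHz): duration ≤ 12 ms → SHORT;
else bandwidth ≤ 6 kHz → FLAT; else FM. Both boundaries are inclusive, as
are the band-filter edges (35–95 kHz high path, 10–35 kHz low path). The
low band is stored as the ordered pair [10, 35] although detector
configuration dumps sometimes print the two cutoffs transposed. FM calls
are not sub-typed into trills/steps, and no attempt is made to attribute
a call to one animal of the pair. Spectrogram parameters of the upstream
detector (3.2-ms FFT window, 90 % overlap, contour thresholds) are kept
as provenance metadata only.

## Audio/video alignment

The audio frame grid has `floor(duration × fps)` rows (1,200.005 s at
12 fps → 14,400 rows; 1,202.168 s → 14,426). Floor is chosen over round
because it drops a partial trailing frame rather than inventing one; both
conventions agree on these row counts. A call over [begin, end] marks
frames `floor(begin·fps) … floor(end·fps)` inclusive, so a 12-ms SHORT
call (0.14 frames) still marks one frame; overlapping calls of different
types may mark the same frame.

Trimming: the later-starting stream defines time zero; the earlier
stream's head loses `round(lag × fps)` frames; tails are cut to equal
length. Rows are only dropped, never edited. The session index stores
start timestamps at one-second resolution, so the recovered lag carries
up to ~1 s of quantisation error even with synchronised device clocks —
the residual true misalignment after trimming is therefore bounded by one
second (12 frames) for inter-device offsets up to 2 s, and by half a
frame when exact sub-second lags are supplied. The trim report carries
this residual (measured against the true lag when the synthetic ground
truth knows it, else the rounding residue). Filename matching heuristics
are replaced by explicit index columns.

## Epochs, design collapse and co-occurrence

Epochs are consecutive 60-s blocks from session start (20 per nominal
1,200-s session; epochs 1–10 precede the light change at 600 s). Duration
of a category in an epoch is positive frames / fps (a full epoch is 720
frames = 60 s); bout counts are maximal runs of consecutive positive
frames. A trailing partial epoch is kept in the raw output with its true
length but excluded from the ANOVA cells — only whole minutes are
comparable. For the ANOVA stage, call types contribute *marked-frame
seconds* (total call time), matching the duration analysis of the
behaviors; raw call counts are emitted alongside for the co-occurrence
stage.

The 2×2 cells per box × session type × category are: mean over epochs
1–10 vs 11–20 within each day, then mean over days 1–3 ("early") vs 4–6
("late"). Days missing from the study are simply absent from their mean;
a box missing an entire cell is flagged and excluded from that ANOVA.

Co-occurrence sums per epoch: for two call types, the total number of
calls of either type (1 SHORT + 4 FM → 5); for a behavior and a call
type, the number of calls of that type whose marked frames intersect
frames where the behavior is scored 1. Call counting matches the printed
arithmetic of the worked example; a seconds-of-joint-presence variant is
available behind `unit="frames"`. Call events are recovered as runs of
the marked columns, so abutting same-type calls merge — a documented,
conservative limitation. Event streams (water-spout head entries) are
binned into half-open bins [k·w, (k+1)·w); boundary events go to the
later bin.

## Statistics

Values entering one analysis (one category × session type; 6 boxes × 2
lighting × 2 phase cell means) are screened with four normality tests at
α = 0.05: Anderson–Darling, D'Agostino–Pearson, Shapiro–Wilk and a
Lilliefors-corrected Kolmogorov–Smirnov (parameters are estimated from
the data, so the plain KS null would be wrong). Tests with their own
minimum n are skipped below it (D'Agostino needs 8, Lilliefors 4; cells
under 3 skip the screen entirely) and logged. If any test fails for any
cell — or with `rank=True` — the pooled values are rank-transformed
(ranks 1..n, average ranks at ties) before the ANOVA; the ranking is per
analysis, not global.

The 2×2 within-subject ANOVA tests each effect against its own
subject-by-effect interaction error term: F = SS_eff / (SS_err/(n−1))
with 1 numerator df. Sphericity corrections are moot with 1 df per
effect. Degenerate cases: SS_err = 0 with a positive effect reports
F = +∞, p = 0; an all-constant table reports F = 0, p = 1. Effect size is
partial η² = SS_eff/(SS_eff + SS_err). The battery runs 15 categories ×
2 session types = 30 analyses at α = 0.05 with *no* multiplicity
correction, matching the study design; a Holm option exists behind a
flag, off by default. At α = 0.05 across 11 truly-null categories, up to
about two false-positive lighting effects per battery are expected — the
end-to-end recovery test budgets for exactly that.

The water-spout (lickometer) demo path is a plain one-way ANOVA across
10-minute bins pooled over boxes and days; the published
between-epochs layout is not fully specified, so the demo treats bins as
independent observations and says so.

## The synthetic generator

Arena: 500 × 500 px (a 50 × 50 cm box at a nominal 10 px/cm; the true
pixel scale of the source recordings is unknown, so this is a stand-in),
origin top-left, y down. Rats are keyframed from a fixed 12-part skeleton
along a two-segment body axis (nose at +70 px to tail end at −100 px from
the body anchor). Each behavior poses the animals it constrains with the
geometric signature its classifier needs — e.g. adjacent lying: body
centroids 30 px apart, motionless; mounting: one skeleton at 0.75 scale
inside the other's hull (overlap 100 %); rearing: the subject's hull
shrunk to 0.45 scale (~20 % of nominal area); following: both animals on
a circular path at 6 px/frame, one trailing by 0.6 rad. Unconstrained
animals idle at home positions (optionally wandering slowly). Gaussian
pixel jitter (default 1.5 px) and a configurable fraction of
low-likelihood keypoints (default 5 %, likelihood drawn below the 0.6
cutoff with coordinates retained) corrupt the clean poses.

Two scripted episodes may overlap only if they constrain disjoint
animals; an overlap claiming the same animal (adjacent lying + following)
is rejected as a contradictory posture. `recover_behaviors` applies each
behavior's geometric definition back to the emitted coordinates; at zero
noise the recovered matrix equals the scripted truth exactly (the
generator's self-consistency loop). Movement predicates use the smaller
of the backward/forward frame displacement so episode-boundary teleports
do not leak into neighbouring frames.

Call records are sampled strictly inside the scripted type's defining
region (SHORT: 4–12 ms; FLAT: >12 ms, ≤6 kHz bandwidth; FM: >12 ms,
>6 kHz; ALARM: low path, 18–32 kHz, 0.3–1.5 s), so acoustic re-typing of
clean records is exact by construction. Counts per window are Poisson at
the scripted per-minute rate, or exact when a fixed count is given.

A full study plans 6 boxes × 6 days × 2 session types (72 sessions) of
1,200 s at 12 fps, audio durations differing by up to ±2 s and audio
start offsets within ±2 s, with second-resolution index timestamps.
Default per-phase episode rates (Poisson means per 10 minutes) and call
rates (FLAT 3, FM 4, SHORT 2, ALARM 0.5 per minute) are plausible
laboratory levels chosen once; the programmed lights-off effect
multiplies the fighting episode rate and the ALARM/FLAT/SHORT call rates
by 3 after the light change of light-to-dark sessions — a large, cleanly
interpretable effect for power checks with n = 6 subjects.

### What the synthetic tests do and do not show

They demonstrate that every pipeline stage is numerically correct, that
the stages compose (scripted effects survive classification, typing,
alignment and aggregation to come out of the ANOVA battery), and that
the statistics hold their nominal error rates. They do *not* demonstrate
classifier performance on real video: keyframed skeletons are far more
stereotyped than real posture, identity swaps and occlusions are absent,
and call detectors' false positives are not modelled. Reported F1 values
on synthetic data are therefore upper bounds, not forecasts.

## Problem sizes used in the shipped checks

The test suite trains the bundle on ~6 scripted sessions (≈5,600 labeled
frames), runs the end-to-end recovery on the 36 light-to-dark sessions of
one full-scale study, the statistics battery on a complete 72-session
study via the scripted-truth path, the type-I simulation at 200
replicates, and the alignment property at 50 sessions. The acceptance
script uses one 60-s session for the feature count and 50 sessions for
the alignment bound.
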