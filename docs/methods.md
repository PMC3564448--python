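# Methods

This note documents the models and procedures implemented in
`episodecode`, the defaults and why they were chosen, and what the
synthetic generator does and does not emulate.

## Task and maze model

The maze is a figure-8 track (outer footprint 100 × 140 cm, path width
20 cm) in a coordinate frame with the origin at the lower-left outer
corner, x rightward, y upward, units cm. The centerline runs 10 cm inside
the outer walls. A lap starts at a bottom-corner reward zone, runs along
the bottom arm onto the central stem, climbs the stem to the decision
point, turns left or right, and descends the return rail to that side's
reward zone. Corners are quarter-circle arcs (radius 10 cm — half the path
width) so heading changes continuously; with right-angle corners the
heading would jump within one sample and the angular-velocity-based
turn-onset rule (below) could never classify a sample as "turning".
Idealized paths are polylines densified to ~1 cm vertex spacing; the
central-stem segment is one shared array reused verbatim by all four
journeys, so stem bins align exactly across conditions. All four journeys
have identical arc length (302.8 cm), which lets every lap share one
arc-length bin grid. Laps start and end exactly at the bottom corner-arc
junctions so outbound and return legs never overlap; for same-side
journeys the path is a closed loop whose two endpoints coincide (the one
inherently ambiguous point of the projection).

Zones (axis-aligned rectangles): reward zones at the two bottom corners, a
delay zone on the bottom arm (the DA waiting point sits 20 cm before the
stem entrance), the central stem, and the upper junction containing the
decision point.

### Lap schedule

Blocks follow VD 20, SA 20, VD 10, DA 20, VD 20, SA 20, VD 10, DA 20
(140 laps). VD cue sides are uniform random under the seed; SA/DA laps
alternate sides, and since a lap's origin is physically the previous lap's
destination, correct SA/DA journeys alternate automatically within a
block. To keep the alternation consistent *across* the VD blocks that
separate SA/DA blocks, the final VD lap before an SA/DA block has its cue
forced to the side that continues the alternation; this is the only
schedule satisfying both the alternation rule and origin continuity.
Error laps (probability `error_rate`, default 0) take the wrong side and
are flagged; downstream analysis excludes them.

### Virtual rat

Tracking is sampled at 60 Hz. Along-path speed is the configured mean
(default 30 cm/s) plus Ornstein–Uhlenbeck fluctuations (SD 4 cm/s,
τ = 1 s, clipped at 10% of the mean). Lateral sway is an OU process
(SD 1.5 cm, τ = 0.5 s) low-passed with a 0.4 s Gaussian kernel and
rescaled; without the low-pass the sample-to-sample sway velocity would
rival the running speed and bias measured ground speed upward by several
cm/s. Head direction is the path tangent plus smoothed noise (SD 3°,
τ = 0.25 s); white heading noise at 60 Hz would exceed the 0.12 rev/s
turn-onset threshold everywhere. DA laps hold position for 5 s at the
delay point. A 0.5 s stationary dwell at the reward zone precedes each lap
(and ends the session); lap segmentation keys on these dwells, so the
inter-lap interval — which the task protocol does not pin down — is an
explicit config parameter with this arbitrary but short default.

### Tuning and spikes

Each place cell carries one isotropic Gaussian field per journey (width
8 cm, peak uniform 5–25 Hz), centered on a uniformly drawn arc position of
that journey's path. Remapping is factorized:

* `journey_mode='global'` (default): field locations drawn independently
  per journey — both location and rate change between journeys.
* `demand_mode='rate'` (default): within a journey the fields are shared
  across subtasks and rates are multiplied per cell and subtask by a
  factor drawn from {s, 1/s} with s = `demand_scale` = 0.5 (VD is the
  unit-gain reference). Drawing the direction per cell makes demand
  remapping heterogeneous — as rate remapping is in CA1 — and leaves the
  population's spatial code intact. The implied cross-demand rate
  similarity per cell is 1 − |1 − s|/(1 + s) = 2/3 at the default.
* `journey_key='origin'` ties fields to the origin side only, with centers
  restricted to the origin arm + stem; combined with `prospective_gain`
  (destination-dependent rate multiplier applied only before the lap's
  entry into the upper junction) it creates a controlled prospective-coding
  substrate whose spatial code is destination-blind.

Untuned control cells fire spatially uniformly at 4 Hz. The rate is
deliberately not lower: the plug-in Skaggs information estimator is biased
upward at small spike counts, and at ~1 Hz an untuned cell can spuriously
cross the 1 bit/spike place-cell threshold on a ~150 s trial type.
Putative interneurons (narrow spikes, ~15 Hz) exercise the unit screen.

Spikes are drawn by thinning an inhomogeneous Poisson process: the rate is
evaluated at every tracking sample from the lap's journey/subtask tuning
(zero between laps), a homogeneous stream at the session peak rate is
drawn, and candidates are accepted with probability λ(t)/λ_max (λ linearly
interpolated between samples).

Every stochastic stage draws from `default_rng([master_seed, offset])`
with a fixed per-component offset, so a session is reproducible from one
integer and components can be varied independently.

## Behavioral preprocessing

* **Segmentation** detects stationary reward-zone dwells (speed < 2 cm/s
  inside a reward zone for ≥ 0.2 s); laps are the intervals between
  consecutive dwells and must match the schedule length.
* **Linearization** projects each sample to the exact foot on the
  densified polyline (nearest vertex via KD-tree, then the adjacent
  segments), yielding arc length and signed lateral offset (positive to
  the rat's right; in the stem this equals the x offset up to sign).
  Samples > 5 cm off the path are unvisited. Covariates are binned at
  pitch L/round(L/0.35 cm) ≈ 0.35 cm: occupancy, mean speed, circular-mean
  head direction, mean lateral offset.
* **Turn onset** is the last sample inside the stem or upper junction
  whose absolute angular head velocity (central difference of unwrapped
  heading, boxcar-smoothed over 5 samples ≈ 83 ms) is below 0.12 rev/s.
  The smoothing window is a config parameter since the threshold's
  reference signal (raw vs smoothed) is a free choice.
* **Immobility filtering** removes spikes whose interpolated tracking
  speed is below 5 cm/s (configurable); this excises the DA delay period
  and reward dwells from all rate estimates. Rate-map occupancy is
  restricted to the same moving samples so numerator and denominator
  describe the same epochs.

## Place-field analysis

Rate maps evaluate the kernel ratio f(x) (Gaussian, h = 5 cm) at 5 cm bin
centers, with the denominator integrated as a 60 Hz Riemann sum; a bin is
visited if its center lies within 5 cm of a tracked sample. The mean rate
is R = Σ Pᵢ Rᵢ with occupancy probabilities Pᵢ over visited bins; the
Skaggs information treats Rᵢ = 0 terms as 0 (the x log x limit) and is
undefined at R = 0. Unit classification: excluded below 0.1 Hz; pyramidal
iff spike width ≥ 0.4 ms and mean rate ≤ 5 Hz; otherwise interneuron.

Similarity uses the central stem as ROI. Spatial similarity is Spearman by
default (Pearson optional) over bins visited in both maps (≥ 3 required;
degenerate variance is signalled, and such pairs are skipped in batch
summaries). Rate similarity compares occupancy-weighted stem mean rates
(peak-rate option available). "Within" comparisons split a trial type's
correct laps into first and second halves, which for SA/DA coincides with
the two block exposures. Maps pooled over repeated exposures are
occupancy-weighted by construction (all samples enter one kernel sum).

### ANCOVA screen

For each cell and comparison (journeys within a subtask; demands within a
journey), an OLS model rate ~ condition + speed + head direction + lateral
position is fit and the type-II F test of the condition factor reported.
Observations are **per-lap stem means** (one row per traversal): per-bin
observations within a lap share the lap's spike-count noise while the
condition is constant within the lap, so treating bins as independent
replicates makes the F test strongly anti-conservative. The per-bin mode
is retained (`observations="bin"`) for comparison but is not the default.
Head direction enters in degrees as a linear covariate; a circular
regressor would be preferable if headings spanned the circle, but stem
headings concentrate near 90°.

## Ensemble trajectory analysis

Per lap, each cell's spikes are binned on the shared ~0.35 cm arc grid and
convolved with a Gaussian of SD 5 cm (truncated at the track ends), giving
the laps × bins × cells array. Distances are Euclidean across cells at
matched bins, on raw smoothed counts (no z-scoring; an option exists but
is off). LOOCV means are exact: excluding the test lap rescales its
own-class distance by n/(n−1), an identity the tests verify against
explicit recomputation. Per-bin labels are the distance argmin with ties
broken toward the lexicographically first label (deterministic; tie counts
are reported); the lap label is the majority over central-stem bins, with
split votes flagged ambiguous and scored incorrect. Per-location binomial
p-values are one-sided (greater than chance). Shuffle controls permute the
label sequence and re-run the entire procedure, templates included.
Generalization computes reference-subtask R-L/L-R templates (no exclusion
needed, reference and target laps are disjoint; the degenerate
reference-equals-target case falls back to LOOCV) and classifies the other
subtasks' laps; its shuffle permutes the journey labels of all involved
laps. The binary suite covers the R-L vs L-R trial-type groups
(VD1, SA1, DA1 vs VD3, SA2, DA2), the three subtask pairs, and all 28
trial-type pairs; classes reduced below 2 laps are skipped with a warning.
PCA projection is provided for visualization only and never feeds
classification.

## Statistics

Binomial tests are exact, one-sided greater by default (the question is
always "better than chance"). The rank-sum Z uses the tie-corrected normal
approximation without continuity correction (cross-checked against the
asymptotic Mann–Whitney implementation). Kruskal–Wallis uses the
chi-square approximation; the post hoc is Tukey HSD on rank-transformed
pooled data, with Dunn's Bonferroni-corrected z tests as an alternative.

## Problem sizes and numerical choices

The standard analysis session is the full eight-block, 140-lap schedule
with 50 place cells (128 for generalization, matching the roster size that
analysis targets); shuffle nulls use 1000 permutations. Null means under
LOOCV sit slightly below nominal chance (the excluded test lap repels its
own-class mean — a known leave-one-out artifact of order 1/n_laps),
comfortably within the binomial null spread. Distance computations run in
float64 on float32-stored trajectories; d² is clipped at 0 before the
argmin.

## What the generator does and does not emulate

It emulates: the block schedule with cross-block alternation and optional
error laps; 60 Hz tracking with realistic speed, sway and heading noise;
the 5 s DA delay; global/rate/prospective remapping structure;
Poisson spiking; untuned and interneuron control units. It does not
emulate theta phase precession or any spike-timing structure beyond the
rate function, LFP or sharp-wave events, slow representational drift,
learning across sessions, behavioral idiosyncrasies (head scanning,
hesitation), or overdispersed firing. Passing tests therefore show that
the analysis recovers the remapping and episodic structure that generated
the data, and that its null calibrations are correct — not that real CA1
data would yield these effect sizes.

## Known limitations

* The projection arc is ambiguous at the closed-loop endpoint of
  same-side journeys; a jittered sample near the start can bin at the far
  end of the lap. Stem-based analyses are unaffected.
* Rate similarity of near-silent stem cells is undefined and those pairs
  are skipped, which conditions the similarity summaries on stem activity.
* The ANCOVA default deliberately trades the finest spatial granularity
  for calibrated inference (see above); per-bin mode is exploratory.
* The binomial test treats laps as exchangeable; serial dependence across
  laps (present in alternation subtasks by design) is ignored, as in the
  procedure it reproduces.
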