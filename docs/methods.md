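# Methods

This document records what each component computes, the model behind the
synthetic generators, all user-facing parameters with units and defaults, the
numerical choices that deviate from the most common library defaults, and the
known limitations.

## 1. Imaging arm

### 1.1 Synthetic vesicle fields (`imaging_sim`)

The generator emulates a confocal field of giant unilamellar vesicles at the
coarsest level that still exercises the full analysis chain:

- **Geometry.** `n_guvs` circles with radii uniform in `radius_range`
  (default 10–40 px) are placed by rejection sampling so that rings never
  overlap (centre distance ≥ r₁ + r₂ + 2 px) and never cross the frame edge;
  placement fails loudly (`PlacementError`) after 500·n attempts.
- **Lipid channel.** Each vesicle contributes an additive annulus with a
  radial Gaussian profile, σ = `ring_width`/2 (default width 3 px), peak
  `ring_intensity` (default 800), truncated at 3σ. Background is
  `background_level` (default 100) plus an optional linear
  `background_gradient`.
- **Protein channels.** Each vesicle receives puncta on its annulus: an
  isotropic Gaussian spot, σ = `punctum_radius`/2 (default radius 3 px), peak
  `punctum_intensity` (default 1200). The per-vesicle count is Poisson with
  mean `puncta_per_guv`, or exactly that number when
  `fixed_puncta_count=True`. With two protein channels, a planted fraction
  `coloc_fraction` of channel-B puncta is placed at the centre of a distinct
  channel-A punctum of the same vesicle (running-balance rounding keeps the
  realised count within one of the requested fraction); the remainder is
  placed independently on the annulus.
- **Noise.** Optional Poisson shot noise (on the noiseless intensity) and
  additive Gaussian read noise of SD `noise.gaussian_sd`.
- **Ground truth.** Every planted vesicle and punctum (centre, radius,
  channel, colocalization partner) is returned and can be written as CSV.
  Identical configs produce bit-identical images.

What it does **not** emulate: point-spread-function blur beyond the Gaussian
spot model, depth sectioning, photobleaching, uneven membrane labelling,
vesicle aggregation or deformation.

### 1.2 Vesicle detection (`detection`)

Classical circular Hough transform: the lipid channel is min–max normalised,
edges are found with a Canny filter (`canny_sigma`, default 2.0), and
`skimage.transform.hough_circle` is evaluated at every integer radius in
[`min_radius`, `max_radius`]. Peaks with normalised accumulator score ≥
`sensitivity` (default 0.45) survive; non-maximum suppression keeps peaks at
centre distance ≥ max(radius)/2. The reported radius is then refined by an
intensity-weighted mean of the radial profile within ±4 px of the Hough
radius, because Canny marks both flanks of the ridge and the raw Hough radius
is biased by up to ~3 px. Each detection carries a padded crop box
(`pad = max(3, 0.2·r)`) and a `border` flag when the box is clipped by the
frame; border vesicles are excluded from experiment-level statistics.

### 1.3 Puncta chain (`puncta`)

Per vesicle crop and per protein channel, in order:

1. **Background level** = minimum-cross-entropy (Li) threshold of the crop.
   The package implements the threshold by **exhaustive scan** over candidate
   cuts (exact over unique grey values when ≤ 512 of them, else a 512-bin
   quantization) because the common fixed-point iteration demonstrably settles
   in local minima of the cross-entropy objective on random images, and the
   test suite requires equality with a brute-force minimizer. Crops with
   negative values (possible under the Gaussian read-noise model) are shifted
   by their minimum before thresholding and the threshold shifted back.
2. **Subtraction**, clamped at zero, in float.
3. **Denoising**: non-local means (`skimage.restoration.denoise_nl_means`,
   patch size 7, search window 21, strength h = 0.8·σ̂ with σ̂ the
   wavelet-based noise estimate, unless `denoise_strength` is set), followed
   by a Gaussian blur (`blur_sigma`, default 1.0).
4. **Contrast equalisation**: the standard uint8 CDF histogram-equalisation
   transfer function on a min–max rescaled 8-bit copy (hand-written;
   equivalent to OpenCV's `equalizeHist`). Constant crops stay constant.
5. **Otsu binarisation** (`skimage.filters.threshold_otsu`, strict `>`).
6. **Connected components**: components **larger than 5 pixels**
   (`min_punctum_area = 6`) are puncta; connectivity is 8 by default
   (configurable to 4). Components are ordered deterministically by their
   lexicographically smallest pixel; bounding boxes use closed intervals in
   image-frame coordinates.

**Signal gate (package design choice).** Equalisation stretches a noise-only
crop to full dynamic range, and Otsu then produces spurious foreground. The
chain therefore skips puncta calling when the denoised crop's maximum rises
less than `min_signal_snr` (default 3) robust noise SDs above its median.
This keeps the false-positive rate on empty vesicles ≤ 5% at moderate noise
while leaving genuine puncta (≥ ~5× background) untouched.

**Colocalization.** A punctum is colocalized when its bounding box overlaps
(closed intervals; corner touch counts) at least one box in the other
channel. The reported fraction is the colocalized count in the
**higher-count channel** divided by that channel's total; on a tie the larger
of the two per-channel colocalized counts is used, which makes the value
symmetric in its arguments. Both per-channel counts are available via
`details=True`. With no puncta in either channel the fraction is `None`
(undefined), never 0.

### 1.4 Replicate statistics (`recruit_stats`)

The statistical unit is the replicate (imaging chamber). Per replicate the
proportion of recognised vesicles with ≥ 1 punctum is kept as an exact
`Fraction`. Conditions are summarised as mean ± sample SD (ddof = 1; a single
replicate reports SD `None`, never 0) and compared by pooled-variance
Student's t (two conditions, two-tailed), Welch's t, a one-tailed t
(alternative: second group lower), or one-way ANOVA (more than two). When
both groups have zero variance and equal means, the t statistic is defined as
0 with p = 1 (two-tailed) or 0.5 (one-tailed); with different means scipy's
±∞ / p = 0 limit is kept. `cell_positive_area` implements the live-cell
metric: pixels strictly above a per-cell threshold, with an optional minimum
particle size.

## 2. Trajectory arm

### 2.1 Synthetic trajectories (`trajectory_sim`)

The generator emulates, per frame, a protein hovering above a planar bilayer
patch:

- **Lipids**: an `nx × ny` jittered grid (default 8×8 over a 14×14 nm box),
  one headgroup particle at z = 2.0 nm and one acyl particle at z = 1.0 nm
  per lipid, static over time. Exactly `round(ps_fraction · n_lipids)` lipids
  are PS (default fraction 0.30, i.e. 70/30 PC/PS), the rest PC.
- **Residues**: one particle each. Per sampled frame, residue *i* is in
  contact with probability `contact_prob[i]`: it is placed at distance
  d ∈ [0.25, cutoff − 0.02] nm above a lipid headgroup (uniform over lipids,
  or PS-biased via `ps_contact_prob`). Otherwise
  d ∈ [max(cutoff + 0.3, 1.02), 3.0] nm, so every frame is unambiguous at the
  cutoff and a zero-probability residue never has any lipid within 1 nm.
- **Ions**: uniform in the solvent band z ∈ [6, 8] nm, except during planted
  `PlantedEvent`s, when the specified ion is held 0.30 nm from its partner PS
  headgroup (partners are forced into the PS set). Events are specified in ns
  and validated (in range, non-overlapping per ion).
- Coordinates are wrapped into the box when `periodic=True`. Ground truth
  (per-residue probabilities, event frame spans and species, expected PS
  contact share) is returned exactly; identical configs are bit-identical.

Not emulated: real dynamics (no diffusion or autocorrelation — frames are
independent draws), multi-atom residues and lipids, membrane undulations,
ion–protein coordination, water.

The native on-disk dialect (`trajio`) is deliberately plain text: `meta.json`
(box, periodicity, shapes), `particles.csv` (annotation table) and
`coords.csv` (one row per frame: time, then x/y/z per particle, 6 decimal
places, nm/ns).

### 2.2 Contact statistics (`contacts`)

- **Windowing.** Analyses use the trailing `analysis_window` fraction of the
  trajectory (default 0.5 — the final half), sampled every `sample_stride`
  (default 2 ns): the first frame at or after the window start, then every
  round(stride/dt)-th frame, endpoint included.
- **Contacts.** A residue is in contact in a frame iff any of its particles
  lies **strictly** within `contact_cutoff` (default 0.4 nm) of any selected
  lipid particle, with minimum-image distances when periodic. Frequencies are
  percent of analysed frames, decomposed by species (PS/PC) and atom class
  (headgroup/acyl); a species absent from the patch contributes zeros. The
  default neighbour search is a `scipy.spatial.cKDTree` (with `boxsize` on
  wrapped coordinates when periodic) whose inclusive-radius candidates are
  refiltered with the exact strict-< min-image distance, so it equals the
  all-pairs brute-force oracle exactly; `method="bruteforce"` runs the oracle.
- **Residues-in-contact series.** Per-frame counts per replicate; replicates
  must share residue count and time grid. The pointwise SE uses
  n = replicates; the scalar summary is the mean ± SD across replicates of
  each replicate's time average over the analysis window.
- **Coordination events.** For every (ion, PS/PC headgroup) pair, contiguous
  runs of frames with min-image distance strictly below
  `coordination_cutoff` (default 0.35 nm) are events with duration =
  run length × dt. Durations < `short_event_max` (default 2 ns) are 'short',
  others 'persistent'. `gap_bridge` (default 0) optionally bridges short
  excursions above the cutoff. `min_ion_lipid_distance` reports each ion's
  nearest-lipid distance per frame and the fraction of frames beyond
  `encage_report_distance` (default 0.5 nm), the encaged-ion criterion.
- **Group comparison.** One-tailed pooled-variance t test (alternative: the
  second group binds less) on replicate window means.

## 3. Experiment orchestration (`pipeline`)

`run_guv_experiment` maps a design (condition → replicates → images) through
detection (border vesicles excluded) and the puncta chain, aggregates exact
per-replicate proportions, summarises per condition, and compares conditions
(two → Student's t, more → ANOVA). Per-image failures are recorded in the
result, not fatal. `run_contact_experiment` does profiles, series, events and
the one-tailed comparison of the first two groups. Both write CSVs plus a
`manifest.json` (tool version, config snapshot, SHA-256 input digests,
per-stage counts); all seeded outputs are byte-reproducible.

## 4. Validation strategy and problem sizes

All problem sizes in the test and acceptance suites are the package's own
choices, set so each property is sharp at desk scale:

- Component labeling and both thresholds are checked against brute-force
  oracles (flood fill; exhaustive objective minimisation).
- Binding-proportion recovery uses 30 vesicles × 3 replicates per condition
  at moderate noise (Gaussian SD = 10% of ring intensity plus shot noise);
  a planted proportion of 0.9 is realised as Poisson puncta counts with mean
  ln 10, and estimates are compared both to the per-replicate realised truth
  and to 0.9.
- Colocalization recovery is evaluated on the planted truth of sparse fields
  (10 large vesicles per 2000² field, one punctum per channel each, 400
  puncta total): dense fields have an irreducible chance-overlap floor of
  bounding-box colocalization that no correct implementation can beat, so the
  geometry is chosen to keep that floor below the ±0.05 tolerance.
- Contact-probability recovery uses 8 planted residues over 1000 frames
  (250 analysed) with a binomial 3σ criterion per residue; at this size the
  joint per-run coverage is ~0.98, so ≥19 of 20 seeded runs passing is the
  correct expectation rather than a tuned one.
- Event segmentation plants a 1.5 ns and a 350 ns event in a 400 ns
  trajectory and requires duration errors ≤ dt with correct classes.

## 5. Limitations

- The vesicle detector assumes bright rings on darker background and roughly
  circular vesicles; strongly deformed or nested vesicles are out of scope.
- Crop-based puncta counting attributes any punctum inside a vesicle's padded
  crop to that vesicle; on crowded fields a neighbour's punctum can leak into
  the crop. Keep fields sparse or shrink `pad_fraction` if this matters.
- Closely spaced puncta merge after blurring and are counted once; the
  exact-recovery guarantee holds for puncta separated by ≥ 4 px edge-to-edge.
- Bounding-box colocalization has a density-dependent chance-overlap floor;
  it is a counting criterion, not a subpixel correlation measure.
- The trajectory generator draws frames independently; observables that
  depend on temporal autocorrelation (e.g. residence-time distributions of
  residue contacts) are not meaningfully testable against it, which is why
  event durations are planted explicitly for ions instead.
- Statistical tests assume replicate-level independence and (for the pooled
  t) equal variances; Welch's t is available where that is doubtful.
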