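# Methods

This note documents the models, conventions and numerical choices behind
`wormstate`, and what the synthetic-data generators do and do not
emulate.

## Behavioral-state decoding

### Model

A plate-assay track gives only the centroid path of a crawling worm; the
direction of locomotion relative to the body (forward vs backward) is
not observable frame by frame. The decoder treats it as a discrete
labeling problem:

1. **Speed** — instantaneous centroid displacement between successive
   frames times the frame rate (μm/s). Frame 0 carries no displacement
   and inherits its successor's speed for classification.
2. **Omega turns** — fixed per frame by silhouette shape (below);
   runs separated by fewer than 2 frames are merged (raster flicker).
3. **Stationary frames** — speed below 10 μm/s; they carry no heading
   and break direction runs.
4. **Sharp turns** — heading is the direction of the inter-frame
   displacement, undefined below a 1 px-equivalent displacement (the
   direction of a near-zero vector is noise); an absolute heading change
   greater than 60° (strict) within a mobile span is a turn event.
   Headings are never compared across omega or stationary runs.
5. **Segments** — maximal mobile spans split at turn events. Candidate
   patterns assign {forward, backward} per segment; omega frames are
   fixed.

### Penalty and tie-break

The score of a candidate labeling counts, with unit weights (the rules
count occurrences, so no term is privileged; weights are configurable):

* maximal backward runs lasting more than 7.5 s (strict);
* omega runs whose next mobile segment is not forward (an omega at the
  end of a track, with nothing after it, is not penalized — the
  direction after the recording ends is unobserved);
* one point if total forward time does not exceed total backward time.

The three penalty terms never *force* a short reversal to be labeled
backward: relabeling a 3 s backward segment as forward violates none of
them, so the true pattern and the all-forward pattern often tie at
penalty zero. Equal-penalty candidates are therefore ordered by a
deterministic tie-break with a kinematic rationale: a worm crawling
forward cannot change its travel direction by more than 60° between two
frames without an omega, so a sharp turn is itself evidence of a
forward/backward switch. The full ordering is

1. total penalty;
2. number of sharp-turn boundaries *not* accompanied by a label flip
   (fewer is better);
3. total forward time (more is better);
4. number of backward runs (fewer is better);
5. residual ties: first pattern in enumeration order, forward before
   backward per segment.

### Optimization

Up to 20 segments the decoder scores all 2^k patterns with vectorized
penalty evaluation. Beyond that an exact dynamic program runs over
(segment, label, current-backward-run duration, forward-minus-backward
time) with time discretized in 0.5 s bins — exact whenever segment
durations are bin multiples, which always holds at the native 2
frames/s. Residual ties beyond the four-level key may order labels
differently between the two paths; the optimum of the key is identical.

## Silhouette shape descriptors

* **Eccentricity** — second-moment ellipse eccentricity (focal distance
  over major axis), in [0, 1). The alternative axis-ratio convention is
  available (`eccentricity_mode="axis_ratio"`); the default is the
  standard convention because the `< 0.8` branch must select *curled*
  postures, which the axis ratio would not.
* **Compactness** — perimeter²/area; **solidity** — area/convex-hull
  area, both from the binary mask.
* **Perimeter estimator** — 4-direction Crofton formula by default: on a
  dyadic refinement of a rasterized disk its compactness error falls
  monotonically (2.3% at radius 16 px to < 0.1% at 128 px), i.e. it
  converges to the continuous boundary length. The classical weighted
  boundary-step estimator (diagonal √2) is available
  (`perimeter_method="weighted_steps"`); it is exact on axis-aligned
  rectangles but overestimates smooth boundaries by ~8–10% without
  converging, so it is not the default. Declared raster tolerances:
  5% for compactness of smooth shapes at ≥ 256 px resolution, 12% under
  arbitrary-angle rotation (the Crofton estimator carries a direction
  bias on near-axis-aligned boundaries).
* **Omega rule** — `(ecc < 0.8 OR compactness < 30) AND solidity >
  0.575`, strict inequalities; the solidity clause binds the
  disjunction. A fully conjunctive variant is available behind
  `rule="conjunctive"`.

## Synthetic worm movies

The generator renders a constant-length, constant-width tube around a
midline: a one-wave sinusoid for crawling frames and a 300° circular arc
for omega frames. Defaults (body length 60 μm, width 8 μm, crawl
amplitude 6 μm, 1 μm/px, 2 frames/s) put the two posture families on
opposite sides of all three shape thresholds with margin: crawl frames
measure eccentricity ≈ 0.96–0.98 and compactness ≈ 44–56; omega frames
measure eccentricity ≈ 0.42 and solidity ≈ 0.69. The worm is miniature
relative to a real adult (~1 mm); only dimensionless shape and the
μm-scale thresholds matter downstream, and the small raster keeps mask
rendering cheap.

Kinematics: forward 30 μm/s along a heading with 6°/frame drift;
backward 25 μm/s opposite the heading (so forward↔backward transitions
flip the travel direction by ~180°, well past the 60° detection
threshold); stationary jitter ≈ 0.6 μm/s; omega centroid drift 2 μm/s
with a 80–160° reorientation at omega end. `noise_sd` sets both mask
boundary roughness (px) and isotropic per-frame path jitter (μm);
masks keep their largest connected component with holes filled. Crops
carry float-valued origins, so the mask centroid equals the stored
centroid exactly by construction.

Random schedules default to forward runs of 6–18 s, reversals of 1–4 s
(60% of run ends), omegas of 1–2.5 s after half the reversals, and
occasional 2–6 s pauses — short spontaneous reversals embedded in
forward-dominated locomotion, the regime the penalty heuristic assumes.
What the generator does **not** emulate: posture kinematics beyond the
threshold-relevant shape families, worm–worm contact, lawn borders, or
head/tail asymmetry; passing tests therefore validates the decoding
logic, not segmentation of real video.

## Neuron tracking

All peak finding, candidate segmentation and intensity matching run on
a lightly Gaussian-filtered copy of each frame (σ = 1 px, configurable):
without it, single-pixel noise fragments candidate regions at low SNR
and the candidate count explodes. Extraction of the ratio signal always
uses the raw images.

* **Brightest mode** — global maximum; ties resolve to the lowest
  raster-order pixel and flag the frame; the reported position is the
  intensity-weighted centroid of the connected region above 50% of the
  peak, with the region's own intensity floor subtracted so the
  background pedestal does not pull the estimate.
* **Heuristic mode** — candidates are connected regions above 50% of
  the previous ROI intensity inside a 20×20 px window, with region
  intensity the mean of pixels above the window's Otsu threshold;
  candidates must differ in intensity by < 1/3 (strict) and lie within
  10 px. One candidate is accepted; among several, only a candidate
  strictly better in *both* match-quality scores (relative intensity
  difference, distance/radius) wins; otherwise a resolver callback — the
  reproducible stand-in for interactive input — is consulted, and by
  default the frame is unresolved. Accepted candidates are refined with
  the peak-region centroid, which is much tighter than the candidate
  segmentation (whose threshold sits close to the background).
* **Reseeding** — after an unresolved frame the tracker follows the
  per-frame brightest point provisionally and resumes automatically at
  the first frame where the candidate search around the provisional ROI
  returns exactly one candidate coinciding with the brightest point
  (within 2 px).
* **Supervised mode** — brightest point within a time-indexed region;
  frames without an entry inherit the last region; a robust z-score of
  the in-region peak below 5 flags low SNR.

The synthetic stack renders the neuron as a 2-D Gaussian spot (σ = 2 px)
in both channels over a uniform background, with acceptor amplitude =
programmed ratio × donor amplitude plus a crosstalk fraction (0.6) of
the donor, independent additive Gaussian noise per channel, optional
distractor spots, and a stage log consistent with the world path under
`world = stage + pixel_size × (frame − center)`. It does not emulate
shot noise, photobleaching, body autofluorescence or defocus.

## Ratio extraction

Per channel and frame: mean of the 20 brightest pixels within a
10-pixel radius of the ROI centroid minus the frame-wide median (the
background; computed over the full frame, not ROI-locally —
configurable). Ratio = acceptor/donor − 0.6; frames with non-positive
donor signal are flagged, not errors. Border-clipped disks with fewer
than 20 pixels use all pixels and flag the frame. No temporal smoothing
is applied to traces.

**Known estimator bias.** The top-20 mean is an order statistic: under
per-pixel noise the selected pixels are noise-favored, inflating each
channel's signal by ≈ 0.3–0.45 of the per-pixel noise SD. The inflation
is equal in absolute terms in both channels, so it cancels only when the
channel amplitudes are equal; for acceptor/donor ratios above 1 the
recovered corrected ratio is biased low by roughly
0.36 × (acceptor/donor − 1) / SNR (peak-signal-to-noise). At the
defaults (corrected ratios 0.45–0.9, i.e. acceptor/donor 1.05–1.5) the
recovery error is ≈ 3–9% at peak SNR 5 and falls within 2% from peak
SNR ≈ 10. This is a property of the published estimator itself, not of
its implementation; the extraction is kept faithful rather than
bias-corrected, and the acceptance suite reports the sweep honestly.
Median-background subtraction exactly cancels uniform per-channel
offsets, and common scaling of both channels leaves the ratio unchanged.

## Trajectory reconstruction

`world = stage + pixel_size × R(roi − center)` with `R` one of the eight
axis orientations (default identity). Smoothing is a centered moving
average, default 5 frames, shrinking at edges and around missing frames
(output length always equals input length). Gap handling reads "shorter
than 30 frames" strictly: interior NaN gaps of ≤ 29 frames are filled
with a natural cubic spline through 3 valid points on each side; gaps of
≥ 30 frames, and gaps touching either end of the sequence (where
interpolation would be extrapolation), are excluded. A cubic spline
reproduces collinear flanking data exactly, so uniform motion is filled
on the line.

Motion classes: central-difference speed (one-sided at the ends);
< 10 μm/s (strict) ⇒ stationary; maximal runs of successive heading
changes ≤ 7.5° (inclusive, with a 1e-9° guard against floating-point
equality) ⇒ consistent movement; consistent runs > 90 s (strict) ⇒
forward; shorter consistent runs need a direction label, supplied as a
run-id → label mapping (the file-based stand-in for interactive input).
Reversals are maximal backward runs; the offset is the first forward
frame after the run.

## Statistics

* **Event alignment** — rows are trace snippets on a common relative
  -time grid, n = number of events (an animal may contribute several
  events but is imaged once). Default normalization subtracts the
  per-event pre-window baseline mean and scales by the per-event window
  range; both steps toggle off for physical-unit panels (amplitude
  recovery uses baseline subtraction only). Mean and SEM are computed
  across events per time point.
* **Validity filtering** — an animal contributes one mean per interval,
  over its valid frames, only if it has a continuously-valid run of at
  least 10 s within the interval; no animal id can appear twice in an
  interval's sample.
* **Mann–Whitney U** — two-sided throughout. For combined n ≤ 16 the p
  value is exact: all C(n1+n2, n1) assignments of the pooled midranks
  are enumerated and P(|U − n1n2/2| ≥ |U_obs − n1n2/2|) computed, which
  handles ties without approximation. Larger samples use the
  tie-corrected normal approximation with continuity correction. Fully
  tied data gives p = 1. Significance tiers: *** < 0.001, ** < 0.01,
  * < 0.05.
* **Steady-state intervals** — each stimulus segment's comparison
  interval starts a configurable lag (default 120 s) after its onset
  transition and ends at the next transition; a lag exceeding the
  segment flags the interval empty.

## DE intersection

Significance is q < 0.05, strict, also for the exclusion comparison
(configurable separately). Tables must share a gene universe; with
`allow_missing=True` absent genes are treated as q = 1 with a warning
(conservative). Orientation of each table is explicit (+1/−1 sign
applied to log2fc) so "same direction" concordance is well defined. The
synthetic tables draw q values uniformly on [0, 0.049] for significant
genes and [0.06, 1] otherwise, keeping every gene away from the cutoff;
the concordant subset of each shared Venn region has a deterministic
size, round(concordance × region size), so exact designs reproduce
exactly.

## Problem sizes in the verification suite

The test suite and acceptance script use: 500 random tracks (≤ 12
segments) for decoder–enumeration agreement; 100 ninety-second movies
for state recovery; 100 random gap placements for the 29/30 boundary;
1000 null simulations (12 animals, two 60 s intervals) for the
false-positive rate; 200 events for transient recovery; three 150-frame
stacks plus a distractor scenario for tracking; five 10-minute sessions
for reversal recovery; a 5000-gene universe for the intersection.
These sizes give stable estimates while keeping a full run on a single
CPU in a few minutes.
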