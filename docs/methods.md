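# Methods

This note documents the models, conventions, numerical choices and known
limitations of `zygoquant`. It is written for users who want to know what the
package computes and what its validation on synthetic data does — and does
not — establish about real microscope data.

## Problem setting

After fertilisation of a *C. elegans* oocyte, the sperm contents (paternal
DNA, paternal mitochondria, and membranous organelles) form a cohesive unit
near one pole of the ~50 µm × 25 µm ellipsoid zygote while oocyte meiosis
completes at the opposite pole. Cytoplasmic streaming can move the sperm
contents long distances; if they come close enough to the meiotic spindle the
sperm DNA can be captured by spindle microtubules. The package quantifies
three readouts of this system from imaging data:

1. **Movement** — phase-segmented trajectory metrics of the sperm contents,
   tracked as the centre of the maternal ER ring that envelops the sperm DNA
   in 5-s-interval time-lapse video.
2. **Scatter** — the dispersion of paternal mitochondria around the sperm
   DNA in fixed-embryo z-stacks, as an intensity-weighted distribution of
   punctum-to-DNA distances.
3. **Capture** — classification of sperm/spindle approach events from paired
   trajectories using a centre-to-centre distance threshold.

## Coordinate and calibration conventions

All physical quantities are in µm and seconds. The canonical embryo frame
has its origin at the embryo centre, x along the long axis and y along the
short axis; videos are oriented so the spindle-containing pole is at negative
x on the first frame (`geometry.normalize_orientation`, a rigid transform
that preserves all pairwise distances). Pixel and frame indices are 0-based.
Default calibration: 65 nm pixels (46 nm supported via the same parameter),
1 µm z-steps, 5 s frame interval. Embryos measuring ≤ 35 µm along the long
axis are rejected for tracking (`qc_embryo_length`, strict inequality):
short apparent length indicates a tilted embryo.

The cross-species volume comparison uses the ellipsoid volume
V = (4/3)·π·a·b·c. With the worm zygote as a 25 × 12.5 × 12.5 µm semi-axis
ellipsoid, an 80 µm sphere (mouse zygote) is 16.4× its volume and a 120 µm
sphere (human zygote) 55.3×; ratios are reported raw and rounded half-up.

## Intensity measurement

ROI means are arithmetic means over pixels whose centres fall strictly
within the disk radius (or inside a polygon). The reference ROI is a
1.17 µm-diameter circle — 18 pixels at 65 nm — sized to cover one
mitochondrial punctum; it is configured in µm and converted per image
calibration. Background correction subtracts the mean of a signal-free ROI;
negative corrected values are retained for ratios and statistics but clipped
to zero before multiplicity rounding, where a negative count would be
meaningless. Chromosome/cytoplasm fluorescence ratios use the same ROI for
both compartments and are invariant to global intensity scaling.

## Scatter statistic

Each embryo yields a weighted list of 3-D Euclidean distances from
mitochondrial foci to the sperm-DNA centroid (in-plane distance combined
with z-step × plane offset for out-of-plane foci). Distinct puncta
contribute their distance once. Amorphous masses — connected regions whose
in-plane footprint exceeds 3 ROI areas — are tiled with non-overlapping
ROIs; each tile's background-corrected mean is divided by the embryo average
of the distinct-punctum corrected means, and the ratio, rounded half-up with
a floor of 1, is the number of times that tile's distance enters the list.
Half-up rounding is a documented choice (the convention is not otherwise
pinned down); the floor of 1 reflects that a measured fluorescent region
represents at least one mitochondrion.

Summaries are the weighted mean and the sample standard deviation (n−1
denominator, the default of common analysis tools); a single-observation
profile is flagged degenerate with SD 0. Quantification is restricted to
anaphase I through anaphase II; metaphase I is excluded because it
immediately follows fertilisation, before scattering can manifest.
Detections outside the embryo mask (e.g. sperm stuck to the eggshell
exterior) are discarded.

Automated detection (replacing manual clicking): Gaussian smoothing, local
maxima above an absolute floor, and brighter-first merging of maxima closer
than one ROI diameter. The background ROI is auto-placed at the in-plane
location with minimal local mitochondrial signal.

## Track metrics

Per phase (windows inclusive of both endpoint frames; a boundary frame
belongs to the earlier phase):

* max x/y displacement: per-axis max − min coordinate;
* displacement: first-to-last point Euclidean distance;
* distance traveled: summed consecutive point-to-point distances;
* maximum average velocity: frame-to-frame scalar speeds (gaps divide by the
  actual time elapsed), trailing 3-point moving averages, maximum taken —
  trailing rather than centred windows, a documented choice that differs
  only at window edges; the metric is omitted (None) for phases with fewer
  than 4 points;
* duration: (last − first frame) × frame interval.

Incompletely filmed phases and phases in which cell-cycle arrest occurred
are excluded from quantification (the former automatically via the
complete/incomplete flag, the latter by the caller's annotation).

## Capture classification

The distance series is the per-frame 2-D centre-to-centre distance on the
frames shared by the sperm and spindle tracks (live capture calls come from
single-focal-plane imaging, so no z). An approach is a capture when the
distance falls below 5.5 µm and the sperm "stops moving relative to the
spindle": operationalised as some run of 6 consecutive frames (30 s) with
cumulative relative displacement < 1 µm. No numeric stuck criterion is
standard, so both parameters live in `CaptureConfig` and are echoed into
every output. Below-threshold episodes separated by tracking gaps longer
than 3 frames are split. The final episode is *stable* if it persists to the
end of the series and contains a stuck run; earlier episodes that end with
the distance rising back above threshold are *transient*; the overall label
is none / stable / transient / transient_then_stable, and captured means
stable or transient_then_stable. Reported threshold crossings are counted
before the final episode begins.

## Statistics layer

Shapiro-Wilk tests (α = 0.05, a documented choice) gate each comparison:
the parametric branch is taken only when *every* group passes; groups with
n < 3 or zero spread force the nonparametric branch. Two groups compare with
Welch's t-test or Mann-Whitney; three or more with Welch's ANOVA or
Kruskal-Wallis. Welch's ANOVA (rather than classical one-way ANOVA) keeps
the ≥3-group branch consistent with the unequal-variance assumption of the
two-group branch; it is implemented from the Welch (1951) formula and
cross-checked against an independent implementation in the test suite.
Mann-Whitney is exact (full enumeration) when both n ≤ 8 without ties,
otherwise the tie-corrected normal approximation with continuity correction;
the two-sided exact p doubles the one-sided tail with a cap at 1.
Kruskal-Wallis uses the tie-corrected chi-square approximation. Fisher's
exact test reports the probability-mass two-sided p and the smaller
directional p. Variance comparisons use Brown-Forsythe (ANOVA on absolute
deviations from group medians). P-values are raw — no multiple-testing
correction is applied, matching the protocol the pipeline mirrors — with
stars *, **, ***, **** at p < 0.05, 0.01, 0.001, 0.0001. Pairwise post-hoc
tests after Kruskal-Wallis are available but off by default.

## Synthetic-zygote generator

The generator exists so that every stage has ground-truthed inputs.

**Cloud model.** Punctum positions are isotropic 3-D Gaussian displacements
(sd `cloud_sigma_um`, default 1 µm) from the DNA centroid, rejection-sampled
into the embryo (bounded at 10,000 attempts per point). For this model the
expected punctum-DNA distance is 2σ√(2/π), which the tests use for
parameter recovery. Masses carry integer multiplicity k ≥ 2 (Poisson with
mean `mass_intensity_factor`, default 3) and are rendered as k overlapping
sub-Gaussians, so multiplicity is integer ground truth for the rounding
rule.

**Rendering.** Each focus is a peak-normalised anisotropic 3-D Gaussian of
physical width `psf_sigma_um` on the voxel grid, plus additive background
and Gaussian noise; channels are mitochondria, DNA (blob at the DNA
centroid) and tubulin (blob at the spindle pole). Rendering is patch-local
(±4σ). At the full default calibration (65 nm pixels over a 50 µm embryo) a
stack is large; tests and the bundled demo configurations use coarser
calibrations (0.2 µm pixels, 6–8 µm semi-axis embryos), which exercise the
identical code paths at tractable sizes.

**Streaming kinematics.** Streaming is phenomenological, not hydrodynamic —
the pipeline needs trajectories with controllable displacement statistics,
nothing more. Jostling is a fixed-step random walk (step length =
amplitude × frame interval, random direction, directions resampled near the
boundary so the configured step length is exact); short-axis rotation is a
y-oscillation (the 2-D projection of rotation about the long axis);
long-axis rotation is an x–y orbit producing long x excursions. The control
amplitude default is 0.15 µm/s — a free parameter chosen once as realistic,
not a measured value. Per-phase factors (MI 0.3, AI 1.0, MII 0.4, AII 0.3)
encode that movement is limited while the ER is sheet-like and peaks when it
disperses; the kinesin-13-like mode keeps MII at 1.0 (elevated streaming
persisting into meiosis II). Depletion multipliers: control (1, 1);
katanin-like and kinesin-13-like (3, 1) on streaming; ataxin-2-like (1, 3)
on cloud σ; the double mode (3, 3). The spindle is nearly stationary at
x = −0.8a. Default phase durations (MI 300 s, AI 150 s, MII 300 s,
AII 150 s) are plausible round numbers, not measurements.

**Capture scenarios.** Programmed distance profiles: *stable* descends to
4 µm and holds with sub-tolerance jitter; *transient* dips below 5.5 µm,
rises, then re-approaches and holds (exactly two downward crossings);
*none* runs the streaming model with an enforced ≥ 8 µm exclusion zone
around the spindle. The recorded capture frame is the first frame of the
final below-threshold episode of the rendered (jittered) series.

**What passing on synthetic data shows.** The generator draws from the same
model families the estimators assume (Gaussian clouds, Gaussian foci,
programmed kinematics). Validation therefore establishes correctness of the
computations and their calibration — not robustness to real-data features
the generator omits: optical aberrations and depth-dependent attenuation,
mitochondrial network topology, autofluorescence, focus drift, tracking
errors, or ER-morphology phase-calling ambiguity. Phase windows are inputs
everywhere; the package never calls phases from images.

## Numerical choices and degenerate inputs

* Rounding is half-up throughout (volume-ratio integers, multiplicities).
* ROI membership is strict (< radius), so results are deterministic under
  exact arithmetic; ROIs extending past the image border are errors, not
  silently truncated.
* Zero-variance groups in the parametric branch fall back to nonparametric
  with a note; identical constant groups give Brown-Forsythe statistic 0,
  p 1.
* Empty sub-tracks from windows outside the filmed span are flagged
  incomplete rather than raised.
* Seeds: every stochastic component takes a `numpy` Generator seed;
  per-embryo seeds in the pipeline derive from the run seed by hashing, so
  cohorts are reproducible and order-independent.

## Problem sizes

The test suite and the acceptance script use: 1000 random tracks for oracle
equivalence; 50 embryos per cohort (30 puncta each) for scatter recovery and
direction checks; 15 embryos per group for displacement direction; 100
programmed scenarios for the capture classifier; 1000 null simulations for
Kruskal-Wallis calibration; 400–500 for Brown-Forsythe. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bounds.

## Known limitations

* The scatter detector is tuned for well-separated diffraction-limited foci;
  dense clouds (σ ≲ the ROI diameter) merge detections, biasing counts low
  (the multiplicity rule partially compensates through brighter merged
  regions).
* Mass/punctum separation by footprint area (> 3 ROI areas) is a heuristic
  with a configurable threshold; no intensity-based sub-ROI segmentation is
  attempted.
* The capture classifier sees only 2-D projected distances; genuinely 3-D
  approaches can be under- or over-estimated by projection.
* `read_mtrackj_points` covers the common plain-text point-list export, not
  every variant of the format.
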