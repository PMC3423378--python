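# Methods

This note documents the models, estimators and design choices behind
`fibrinet`, and what the synthetic validation does and does not establish.

## Image model and preprocessing

Images are single-channel intensity rasters in arbitrary units (au),
calibrated by a physical pixel size (default 57.6 nm/px, i.e. a 59×59 µm²
field at 1024² pixels, matching common multiphoton acquisition geometry).
All images pass through the same chain: background subtraction, rescaling to
a fixed 0–255 au range, and global thresholding.

* **Background.** The default estimator is the modal intensity of the image:
  fibrin fields are mostly dark void, so the histogram mode is the detector
  offset. A rolling-percentile surface (10th percentile over a 64 px window)
  is available for uneven illumination. The subtraction is clipped at zero.
* **Normalization.** The image maximum is rescaled to 255 au so the single
  global threshold is meaningful across acquisitions with different gains.
  A consequence worth knowing: the rescaling is driven by the brightest
  structure in the field (often a fiber crossing, where intensities add), so
  absolute per-fiber intensities are comparable within an image, not across
  images. FWHM diameters are scale-invariant and unaffected.
* **Threshold.** 27 au, inclusive (a pixel exactly at threshold is fiber).
  The comparison sense is a package convention; nothing downstream is
  sensitive to the measure-zero boundary case.

Degenerate inputs (uniform images) are rejected rather than silently
normalized.

## Test-line stereology

Fiber density is estimated by sampling the image along *n* equally spaced
horizontal lines (rows ⌊H·k/(n+1)⌋, k = 1..n; five lines by default).
Because fiber orientation in a clot is random, line sampling is an unbiased
sample of the network, and density is reported per 100 µm of test line. A
fiber crossing several lines counts once per line — the unit is crossings
per line length, not a per-object census.

Peaks are found on a 3 px moving-average–smoothed profile: a fiber is a
local maximum ≥ 27 au (equivalently, a +→− sign change of the first
derivative), with peaks closer than 5 px merged to the higher one and a
5 au prominence floor to reject plateau noise. Peaks within 5 px of the
profile ends are dropped: a truncated half-peak at the field border is not a
measurable crossing. The reported peak position is refined to the raw-profile
maximum within ±2 px.

Editing is a machine-readable batch list (confirm/reject/add), not a GUI.
Untouched automatic detections count as implicitly confirmed true positives;
rejections are false positives of the automatic pass; additions are its
false negatives. PPV = 100·TP/(TP+FP), undefined (None) when there are no
positives.

## Diameter measurement

The diameter is the FWHM of the intensity profile taken perpendicular to the
local fiber axis through the fiber's local intensity maximum (search window
±4 px around the test-line crossing; ties break toward the crossing). FWHM
was chosen as the width measure because fiber fluorescence is proportional
to laterally aggregated protofibril content, making the half-maximum a
landmark that is stable under intensity rescaling.

* Orientation comes from the intensity-weighted structure tensor of a
  15×15 px window; the fiber axis is the minor eigenvector.
* The profile is sampled at 1/4 px steps over ±20 px with bilinear
  interpolation; crossings of the half level are located by linear
  interpolation (sub-pixel).
* The local background is the 5th percentile of the profile. A mean- or
  median-of-the-ends estimator is biased high in dense networks, where
  neighbouring fibers cross the measurement window; the low percentile is
  robust to such intrusions. On isolated noise-free fibers both estimators
  agree.
* Failure modes are explicit: a profile that never falls to half maximum is
  flagged `unresolved`; a profile with two prominent peaks above the half
  level (two fibers closer than the optical width) is flagged `merged`.
  Flagged fibers keep their detection (they count for density) but are
  excluded from diameter statistics.

Residual accuracy: on noise-free isolated fibers spanning 400–1000 nm the
mean absolute error is ~10–40 nm (well under one pixel). In dense networks
the residual error is ~50 nm MAE, dominated by fibers that cross other
structures at the measurement site. Thick fibers (≥ 1 µm) read ~3% low
because the ±20 px window clips their far tails slightly.

## Diameter distribution, thin/thick threshold, TTR

A diameter sample is tested for normality (Shapiro–Wilk, α = 0.05). If
normality is not rejected, a single normal is fitted by maximum likelihood
and the summary statistic is the mean. Otherwise a two-component Gaussian
mixture is fitted by EM (k-means initialization, 10 restarts, tolerance
1e-8, seeded) and the summary is the median; the interior local minimum of
the fitted density between the component means — located by 0.1 nm grid
search — is the data-derived thin/thick threshold. If the fitted mixture has
no interior minimum the sample is reported as normal. Bimodal fitting
requires n ≥ 30.

The default thin/thick cut is 761.9 nm, the control-derived value used
across treatment doses in the study this package operationalizes; it can be
re-derived per dataset. TTR = n_thin/n_thick with thin strictly below the
cut; TTR is scale-free and non-decreasing in the threshold, and is flagged
infinite when no thick fibers exist. Percent changes are computed from
unrounded values and rounded only at display time.

## Topology rules

* **Branch junction** (trifunctional): three segments meet and the widest
  width conserves the sum of the other two. The classifier is
  `|max − (sum of others)|/max ≤ 0.15`, permutation-invariant. The 15%
  tolerance operationalizes "approximately equal" and absorbs measurement
  error of ±30 nm per arm on ~800 nm trunks.
* **Crossing contact**: both fibers' intensities rise strictly more than
  40% at the meeting point relative to their own baselines (median along
  the fiber, excluding a 7 px window around the meeting). The threshold is
  read as 40% with the "±15%" of the source phenotype describing observed
  spread, not a tolerance band; the rule is proportional, hence invariant
  to rescaling either profile. One-sided increases are pass-overs. Meetings
  of more than three segments are treated as crossings, not branches.
* Candidate meetings are generated by tracing each fiber's ridge from its
  test-line crossing (1 px steps along the local structure-tensor axis,
  re-centring ±2 px, up to 200 steps per direction) and emitting positions
  where the traced intensity exceeds the fiber's own baseline by > 40%,
  paired with any other trace within 3 px. Unpaired bright anomalies (e.g.
  a cluster core on the fiber) are emitted for downstream classification.

Per-area rates default to the acquisition field (59×59 µm²) with per-mm²
variants; per-fiber rates and the density/branch and density/crossing ratios
are null when their denominators are zero.

## Voids and abnormal structures

Void area is the black-pixel fraction of the binarized image; projected void
is the void fraction of the pixelwise OR of (by default) three slice masks;
void volume is the unweighted mean of per-slice void fractions — an
equal-slab model for evenly spaced slices. The complement identity
(void + fiber = 100) and projection containment (projected void ≤ every
slice void) are exact.

**Clusters.** A fibrin cluster is an irregular high-intensity core with more
than 8 thin fibers protruding from its periphery. Cores are connected
components above the image's 99th intensity percentile with area ≥ 0.5 µm²,
solidity < 0.9, and long axis ≤ 8 µm (a whole bright fiber ridge is not a
core). Protrusions are counted by casting radial rays just outside the core
boundary (120 angular bins): a direction is protrusion-bearing when the ray
stays ≥ 27 au along its whole 20 px length — a genuine radial ridge does, a
passing fiber lights a ray only briefly. Contiguous hot runs are single
protrusions (single-bin gaps closed, single-bin splinters dropped), and only
runs with arc width below the thin-fiber threshold count. The strict > 8
count separates clusters from ordinary multi-fiber nexuses, which present at
most ~8 thick radial arms.

**Agglomerates.** When no fibrin component spans two of the standard
test-line rows — an extended fiber does, an ≤ 8 µm particle cannot at this
geometry — the field is particle-mode plasma: connected components with
equivalent diameter ≥ 0.3 µm are agglomerates, measured by their major-axis
length (sanity-bounded at 20 µm), classed spherical below aspect ratio 1.3.
Calling agglomerate morphometry on a network image raises a mode error
directing the caller to the network pipeline.

## Synthetic generator

The generator renders the image phenotypes the measurement chain must
handle, with exact bookkeeping:

* Fibers are straight chords with Gaussian perpendicular profile
  (FWHM = diameter), peak intensity strictly linear in diameter
  (0.12 au/nm), additive where objects overlap, plus additive Gaussian
  detector noise (default sd 3 au) and clipping to 0–255.
* Orientations are stratified over [10°, 170°]: isotropic in expectation,
  with low sampling variance, and excluding fibers nearly parallel to the
  horizontal test lines, for which line stereology is degenerate. Chords
  shorter than 0.7 of the field edge are rejected (network fibers span the
  field), relaxing only if the field is crowded.
* Placement keeps test-line crossings resolvable: crossings stay ≥ 24 px
  apart *and* clear of each other's along-line footprints (a shallow
  fiber's footprint on a row is FWHM/sin θ), ≥ 20 px from the column
  borders; fiber–fiber intersections are kept ≥ 12 px away from the test
  lines, because summed intensity at an intersection bridges two peaks into
  one. Infeasible requests raise a packing error rather than degrading.
* Branches are three co-terminal 2.5 µm segments with widths F2, F3 ~
  U(350, 550) nm and F1 = F2 + F3 exactly; crossings are two segments
  through one point (≥ 40° apart), additive by construction, so an
  equal-fiber crossing shows a ~100% local increase; structures keep ≥ 50 px
  clear of the test-line rows (so stereological counts stay interpretable)
  and far enough from each other that arms cannot touch.
* Clusters are spiky star-polygon cores (~1 µm radius, 235 au) with 10–13
  radial thin fibers (400–500 nm, ~2.2 µm long); cores are placed ≥ 55 px
  from network fiber paths so the bright core stays one component.
* Agglomerates are isolated ellipses with long axes drawn log-normally
  (median 2.24 µm, σ_log 0.67 — mean ≈ 2.8 µm with ~11% above 5 µm),
  truncated to the observed 0.5–8 µm range, aspect ratio U(1.05, 2.5).
* Ground truth records every object once, all fiber–line crossing columns,
  and the noise-free ≥ 27 au footprint fraction (the void oracle). A fixed
  seed reproduces a scene bit-exactly.

**The virtual dose series** emulates a dose-dependent polymerization
inhibitor: across 7 doses the fiber count falls 24 → 11 → 0 while the mean
diameter rises 670 → 850 nm at an interior dose and then falls; diameters
are calibrated so the binarized footprint stays approximately constant
before cluster onset — falling density spatially offset by thickening
fibers — keeping void volume flat (~67%) until clusters appear (dose 6 of
7), after which void rises sharply and the final dose contains only
agglomerates. Replicates (3 in tests, 4 in the acceptance script) mirror a
triplicate imaging protocol and stabilize the monotonicity checks.

## What the synthetic validation shows — and what it does not

The suites certify the operators: detection recovers per-line counts within
±1 and density within a few percent on resolvable networks; FWHM recovery is
sub-pixel on isolated fibers; the mixture fit recovers a known density
minimum within 25 nm in ≥ 18/20 runs at n = 300; the topology rules are
≥ 90% accurate on labeled events (labeled-event suites render structures
without a background network, so each measured width is attributable to its
event); void arithmetic is exact.

The generator does not emulate fiber curvature, out-of-focus haze, photon
shot noise, photobleaching, depth attenuation, or unresolved sub-threshold
fibers. Passing these suites therefore demonstrates correctness of the
measurement chain under the stated image model, not performance bounds on
arbitrary real acquisitions — on real data, detection edits and the width
flags exist precisely because those artifacts occur.

## Numerical conventions

Row-major 0-based pixel indices, pixel centres at integer coordinates,
physical position = index × pixel size. Angles measured from the +column
axis with (row, col) direction (sin θ, cos θ). All RNG is
`numpy.random.default_rng` with explicit seeds; EM restarts are seeded.
Ties in the local-max search break toward the window centre. Degenerate
denominators (zero thick fibers, zero junctions, empty profiles) are flagged
or raised, never silently zero.

## Known limitations

* Diameters in crowded fields carry ~50 nm MAE from overlapping structures;
  the per-fiber `merged`/`unresolved` flags bound, but do not eliminate,
  this.
* Per-image normalization anchors on the brightest structure, so absolute
  intensities are not comparable across images (CVs and the
  diameter–intensity regression, which are within-image, are unaffected).
* Ridge tracing is greedy and can leave a fiber at a bright junction; the
  candidate-meeting generator is deliberately recall-oriented, with the
  proportional-increase classifier doing the discrimination.
* Topology is classified in 2D images; structures overlapping in z but
  separated laterally are handled (pass-over rule), but no 3D linking
  across slices is attempted.
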