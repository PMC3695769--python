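# Methods

This note documents the models, conventions and numerical choices behind
`cmrpost`, and what the synthetic phantoms do and do not establish about
behaviour on clinical data.

## Coordinate and contour conventions

Contours are simple planar polygons with vertices in millimetres; image
coordinates are 0-based, pixel centers sit on the integer grid scaled by
the pixel spacing, and slice 0 is the most basal slice of a short-axis
stack. Polygon areas use the shoelace formula (orientation-free);
rasterization uses a pixel-center-in-polygon test. These conventions are
fixed here because acquisition standards leave them open; they must match
whatever produced the contours.

The AHA segment model places the angular origin at the anterior RV
insertion point and counts segments counterclockwise viewed from the
apex: basal 1–6 and mid 7–12 at 60° each, apical 13–16 at 90°, optional
apical-cap segment 17. Angular spans are half-open, so a pixel exactly on
a boundary belongs to the counterclockwise-following segment — a pure
determinism tie-break. Usable slices are split base→apex into thirds;
remainder slices go to the basal, then the mid ring, since the governing
documents give no slice-to-ring rule. The RV insertion angle is an input
per slice, never inferred.

Transmural chords are cast at equal angular increments (default 100 per
slice, giving < 1 % angular quantization on synthetic annuli) from the
endocardial centroid; each chord runs from the endocardial to the
epicardial boundary crossing and is sampled at quarter-pixel steps
against the enhancement mask. Endo/epi layers split each myocardial
pixel at 50 % transmural depth, defined by the ratio of distances to the
two boundaries.

## Volumetry

Volumes are slice summations: area × (thickness + gap), applied
uniformly including the stack ends (whether the step should be halved at
the ends is not specified anywhere; the uniform rule is used and stated
here). ED and ES are single global phases maximizing/minimizing the
summed blood volume; ties resolve to the earlier phase. Aortic-valve
closure as an ES definition is not computable from contours, so a caller
override is accepted and logged in the result notes.

The basal "less than 50 % of blood surrounded by myocardium" criterion
is operationalized as the fraction of the endocardial perimeter lying
within 3 mm of the epicardial-minus-endocardial region (threshold and
distance configurable); combined with systolic cavity expansion it
excludes the slice as atrium at ES. An epicardial contour without a
blood pool contributes wall (mass) only.

Mass uses the specific density of myocardium, 1.05 g/ml. Papillary
polygons move between blood and myocardium according to the declared
papillary mode; blood volume and mass change by exactly equal-and-
opposite tissue volumes times density, which the tests assert. The
stroke-volume consistency check defaults to a 10 % relative tolerance —
"nearly equal" has no published number, so the tolerance is explicit
and configurable.

## Perfusion

Curve features: baseline is the mean of the first n ≥ 1 baseline frames
(default 4). Contrast arrival is the first frame exceeding
baseline + 2·SD(baseline) that stays above threshold on the following
frame; requiring two consecutive frames rejects single-frame noise
crossings. The maximal upslope is the steepest least-squares line over
any window (default 5 frames, minimum 3, exhaustive search) between the
last pre-contrast frame (arrival − 1) and the peak; anchoring at
arrival − 1 keeps the estimate insensitive to one-frame jitter in
arrival detection, since the rise begins inside that interval. The
upslope integral runs from arrival to peak (the unbounded "area under
the curve" needs limits; these are configurable). MPRI is the
stress/rest ratio of blood-pool-normalized upslopes.

The defect/artifact classifier evaluates the standard criteria vectors
per segment and reports them for audit. Hypoenhancement is a peak
enhancement below 0.75 × the per-frame median reference curve of all
segments; the deficit-onset and persistence measurements use a 5 %-of-
reference-peak detection level; "several RR intervals (usually > 4)"
is encoded as strictly > 4 RR and "less than approximately 6" as
< 6 RR (all configurable; temporal resolution defaults to 1 frame per
RR). The width of the hypoenhanced band is measured radially: along each
transmural chord, the longest contiguous run of samples below 0.75 × the
myocardial median, converted to pixels, maximized per segment. A radial
(transmural) width is used because the defining criteria — "more than
one pixel wide" versus "approximately one pixel wide" — describe the
depth of the band, which a mid-myocardial circumferential profile cannot
see for a one-pixel subendocardial rim. Since defects are most prominent
subendocardially, classification operates on endocardial-layer curves.
A stress-only transient dip never qualifies as a defect on its own;
matched stress/rest deficits over known scar are reported as normal for
ischemia with a scar-match note. No motion registration is performed;
inputs are assumed registered.

## LGE

The n-SD threshold is remote mean + n·SD with strict `>`; FWHM is half
the scar-core maximum with `≥`, so the maximum pixel always belongs to
its own mask. An optional FWHM variant using (core max + remote mean)/2
exists but is off by default — the literal half-maximum is the primary
reading, and the method's bright-core assumption is surfaced as a
warning when the mask covers the whole myocardium. Remote statistics are
per-slice (a pooled option exists); no-reflow filling is 2-D per slice,
idempotent and mask-growing only. Transmurality per segment is the mean
enhanced chord fraction, binned into the five categories with "0 %"
reserved for exactly zero. Visual-assessment guidance (windowing, TI
selection, pattern reading) is out of computational scope.

## T2-weighted edema

Global/regional ratios divide mean myocardial SI by the mean of a
skeletal-muscle ROI (≥ 20 pixels). The classification cutoff (default
1.9, dark-blood triple-IR) and the pixel-map cutoff (default 2.0) are
deliberately separate parameters because they serve different displays;
both treat the boundary as positive ("2 or higher"). Surface-coil
inhomogeneity correction is an acquisition-side responsibility; a
sequence tag mentioning a surface coil produces a warning field only.

## T2*

SI(TE) = S0·exp(−TE/T2*) is fitted by bounded nonlinear least squares
(T2* ∈ (0, 1000] ms) initialized from the log-linear regression; fixed
optimizer tolerances make the fit deterministic, and no constant offset
term is included — truncation is the plateau remedy. The truncation
method drops the latest echo while R² < 0.995 and more than 3 points
remain (both configurable); the reported fit is the first meeting the
rule, with the truncation count recorded. Iron classification applies
the 1.5 T cutoffs (< 10 ms high risk, < 20 ms overload, 40 ms normal
reference); any other field strength is refused rather than
extrapolated. Black-blood acquisitions can disable truncation via their
metadata flag.

## Flow

Window shifting re-expresses each velocity as v + 2·VENC·k inside the
new [lower, upper) range — a bijection modulo 2·VENC, idempotent for
in-window values. Background correction fits a first-order plane per
frame to ≥ 100 stationary-tissue pixels (exact for planar offsets) or
subtracts a static phantom's per-pixel temporal mean. Flux integrates
pixel velocity × pixel area over the lumen ROI; volumes use a
trapezoidal rule over trigger-time intervals with the last interval
closing the RR cycle, and sign crossings are split exactly within
intervals so that net = antegrade − retrograde holds identically. The
antegrade direction is a declared input. Peak velocity supports the
single-pixel and n×n-neighborhood-mean (default 3×3, ROI-clipped)
conventions, and the mode is carried into the result because the two
are not interchangeable. QC flags: TE > 3.5 ms, ≥ 3 ROI pixels within
2 % of a window edge (aliasing), peak < 40 % of VENC (poor contrast).

## MRA

Subtraction and MIP are exact voxel operations. The "widest inner
diameter" is the maximal caliper width of the cross-section (convex hull
+ farthest pair); the outer diameter projects lumen + wall onto the same
direction. The aorta report fixes the nine anatomic levels; sinus and
sinotubular-junction rows are suppressed without ECG gating, and all
three sinus-commissure dimensions are carried when provided.

## Phantoms: what they emulate and what they do not

The ellipsoidal ventricle gives closed-form volumes (4/3·π·abc), a
cosine volume curve with ED at phase 0 and ES mid-cycle, and a
constant-thickness wall; the in-plane axes contract while the long axis
is held, so every phase covers the same slices. Slice midpoints sample
the long axis, so measured volumes converge to truth as O(h²) in slice
thickness — the 30 mm sphere is ~1.3 % off at 10 mm slices. The
perfusion phantom builds pixelwise gamma-variate first-pass curves
(blood leading the myocardium by 4 frames), injects reduced-amplitude
subendocardial defect bands at stress only and one-pixel sub-baseline
dark bands at blood-pool arrival, and scales rest myocardial amplitude
by the generating flow ratio so the true MPRI is known. The T2* series
is √((S0·e^(−TE/T2*))² + floor²) plus Gaussian noise; the default
10-echo TE grid (2–25 ms) represents a protocol able to capture both
normal and heavy-overload decay, where the late echoes of a 5 ms T2*
sit on the noise floor — exactly the regime the truncation method
addresses. Curve-level noise in the Monte-Carlo experiments uses
SD = 2 SI units, the ROI-mean noise of a ~100-pixel septal ROI at
per-pixel SNR 50. The flow phantom provides plug or Poiseuille profiles
(spatial mean = peak/2), optional planar offsets and VENC wrapping, with
truth volumes integrated analytically before corruption.

None of the phantoms model coil sensitivity, motion, partial volume at
oblique boundaries, arrhythmia, or realistic anatomy; passing tests
demonstrate correctness of the measurement rules and numerical
implementations on ideal geometry, not robustness to those confounds.
Truth manifests are computed from closed forms only and never call the
analysis code.

## Reported problem sizes

The test suite and acceptance script use a 9-slice, 20-phase ventricle;
80×80 perfusion frames over 50 dynamics with 100 classification seeds;
96×96 LGE slices; 200 T2* Monte-Carlo replicates; and 64×64×20-frame
flow series. These sizes keep every quantization error well inside the
stated tolerances while the whole pipeline runs in seconds on one CPU.

## Known limitations

- Quantitative myocardial blood flow (deconvolution), peri-infarct grey
  zone, T1/T2 mapping, strain, 4-D flow and volume rendering are out of
  scope by design.
- The contour-exchange format carries single-plane polygons only;
  long-axis cross-referencing for basal descent is not implemented (the
  basal rules operate on short-axis evidence).
- DICOM support covers single-frame files with standard spacing tags;
  exotic vendor dialects are not parsed.
- 3 T T2* and RV mass are deliberately refused/not computed rather than
  approximated.
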