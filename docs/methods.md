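# Methods

## The measurement problem

Amyloid-binding PET tracers bind white-matter myelin; demyelinated tissue
binds less. Quantifying that signal without arterial blood sampling needs a
reference-tissue chain: find a reference region whose kinetics are free of
specific binding, fit each voxel's time-activity curve (TAC) against the
reference, and read off the distribution volume ratio (DVR). This package
implements that chain plus the simpler static alternative (SUV), the
lesion-centred spatial analyses that consume the maps, perfusion (CBF)
quantification, and the statistics that compare DVR and SUV as classifiers
of demyelinated tissue.

## Kinetic simulation (phantom)

The phantom drives a one-tissue compartment with an analytic tri-exponential
bolus input Cp(t) = (A₁t − A₂ − A₃)e^(−λ₁t) + A₂e^(−λ₂t) + A₃e^(−λ₃t)
(classic bolus-shape coefficients, rescaled so the peak is ≈100 kBq/ml). No
blood data constrain this choice: DVR estimation is input-independent, so
any smooth early-peaking input serves parameter-recovery tests. Grey matter
(the reference tissue) follows dC/dt = k1·Cp − k2·C with k1 = 0.30,
k2 = 0.15 min⁻¹. White matter and lesions follow the simplified reference
tissue relation

    C_t = R1·C_ref + (k2 − R1·k2a)·[C_ref ⊗ e^(−k2a·t)],  k2a = k2/(1+BP_nd)

so the true DVR = 1 + BP_nd is known exactly. Defaults: white matter
R1 = 0.8, k2 = 0.12, BP_nd = 0.44 (DVR 1.44, a healthy-white-matter-like
value); the default lesions sit at DVR 1.28 (typical T2 lesion) and 1.10
(severe). Curves are evaluated on a fixed 1-s internal grid — the
exponential convolution uses a recurrence exact for piecewise-linear
inputs — and frame values are trapezoidal means over each frame interval.
This bounds the discretization error that all recovery tolerances (±0.02 on
DVR) are budgeted against.

Geometry is deliberately simple: a spherical brain (radius 0.45 of the
grid extent) with a grey-matter shell and white-matter core (0.62 of the
brain radius); lesions are spheres voxelized by a centre-inside test, with
no fractional partial-volume mixing, keeping the ground truth piecewise
constant and assertions unambiguous. Optional per-lesion gradients emulate
graded demyelination: `core_bp_nd` ramps binding linearly from the centre
to the boundary, `rim_width_mm` ramps it back to the white-matter value
outside the boundary. Thirty blood-pool voxels (configurable) carry the
input curve itself, planted at seeded random grey-matter locations.

Frame noise is zero-mean Gaussian with SD = noise_scale·√(C/Δt_min) — the
first-order counting-noise approximation in which variance scales with
activity and inversely with frame duration. With Δt in minutes,
noise_scale 0.3 yields ≈8 % relative noise on the 15-s frames and ≈2 % on
the 10-min frames, a realistic dynamic-PET profile. The phantom emits
decay-uncorrected frames by default (multiplied by e^(−λ·t_mid),
λ = ln2/109.77 min) so the decay-correction stage is exercised; correction
at frame midpoints inverts this exactly.

What the phantom does **not** model: scanner resolution/PSF, attenuation
and scatter, head motion, partial-volume mixing at boundaries, realistic
anatomy, or physically simulated diffusion (the DTI-like maps are linear
functions of true DVR plus noise, making the DVR–FA/MD correlations a
recoverable synthetic property rather than physics). Passing tests
therefore demonstrate algorithmic correctness of the quantification chain,
not robustness to those real-data effects.

## Frame handling

Frame schemes are compact strings ("8x15,3x60,5x120,5x300,5x600") expanded
into contiguous frames starting at injection. The printed 90-min
acquisition expands to 26 frames totalling exactly 5400 s. Window
membership (e.g. the 70–90-min SUV window) is decided by frame midpoint on
a half-open interval [t0, t1) so adjacent windows never double-count a
frame; on the default scheme this selects the last two 10-min frames
(midpoints 75 and 85 min). Decay correction carries an idempotence flag and
refuses to run twice.

## SVCA reference extraction

Each frame is z-scored over the brain (subtract the brain-mean, divide by
the brain-SD), putting frames on a common scale. Three classes come from
control scans: class 1/3 are grand means of normalized grey-/white-matter
TACs; class 2 is the mean normalized TAC of, per control scan, the 30
voxels with the highest summed raw activity over frames wholly inside the
first 60 s (the large vessels) — selection is per scan, then averaged,
and rank ties break by lexicographic voxel index for determinism. Candidate
voxels (grey matter by default) are regressed on the three classes with
non-negative least squares; NNLS keeps the class-1 weight ratio
w₁/(w₁+w₂+w₃) inside [0, 1] and well-defined (ratio 0 when all weights
vanish). Voxels with ratio > 0.9 form the reference region; the reference
TAC is the mean of their raw (non-normalized) curves. An OLS solver mode
exists for comparison. The whole stage is invariant to global rescaling of
the activity (z-scores are), which tests assert.

## Logan reference DVR

For frames with midpoint ≥ t* the transformed coordinates
Y = ∫₀ᵗC_t/C_t and X = ∫₀ᵗC_ref/C_t are fitted by ordinary least squares;
the slope is DVR. Integrals are trapezoidal over the frame midpoints with a
C(0) = 0 anchor. t* defaults to 30 min (7 late frames on the default
scheme) and is recorded in provenance; noiseless estimates at t* = 30 and
40 min agree within the discretization budget, so the exact choice is not
critical on reference-tissue-model data. The k2′ correction term
(X += C_ref/(k2′·C_t)) is available but off by default. Voxels with
non-positive activity in the fit window cannot be transformed; they are
returned as NaN and counted. Known property, verified by test: under frame
noise the estimator's median falls at or below the noiseless value (the
classic Logan noise-induced underestimation), so noisy DVR maps are biased
low, not high. Recovery assertions exclude the planted blood-pool voxels:
their TAC is the plasma input, for which a reference-tissue DVR is
undefined.

## SUV and SUVR

SUV = C/(ID/BW) with C in kBq/ml, ID in MBq, BW in kg; the implicit
1 g/ml tissue density makes the units cancel. The static image is the
duration-weighted 70–90-min window mean of decay-corrected frames. SUVR
(SUV normalized to a reference region's mean) is provided but its
provenance carries a warning: it is only meaningful when reference uptake
does not differ between the groups being compared, which must be checked
first.

## Lesion geometry

Distances are exact Euclidean distance transforms with physical voxel
spacing; "distance from the lesion" is distance to the nearest lesion voxel
centre. Perilesional rings (0–4 mm, 4–8 mm by default) are computed
in-plane per axial slice by default — matching how such ROIs are drawn on
2-D slices — with a 3-D mode available and flagged in provenance. Rings
are clipped to white matter, never enter any lesion, and voxels claimed by
two lesions' same-band rings are conservatively excluded from both.
Intralesional layers split each lesion into n equal-depth bands (default
2, outer/inner; the count is a parameter since two- and three-layer
conventions both exist); a lesion too small to split degenerates to the
outer layer with a warning. Lesions smaller than the scanner resolution
(equivalent-sphere diameter < 4.3 mm; the metric is the package's choice)
are excluded before analysis. The impaired-white-matter mask thresholds WM
at mean − 1.96·SD of a reference white-matter DVR distribution (the lower
normal tail); impaired and unaffected masks partition WM exactly.

## Perfusion

CBF = 6000·λ·ΔM·e^(PLD/T1b) / (2·α·T1b·M0·(1 − e^(−τ/T1b))) in
ml/100 g/min, with ΔM the mean pairwise control−label difference. Defaults
λ = 0.9 ml/g, T1b = 1.65 s, α = 0.85 (3-T pCASL consensus constants) and
τ = 1.5 s, PLD = 1.8 s (the emulated acquisition). Pairs are subtracted
then averaged — equivalent in expectation to averaging first, but keeps
per-pair QC possible. The phantom inverts the same equation to encode its
flow field, so the round trip is exact to numerical precision at zero
noise; the test budget of 0.1 ml/100 g/min leaves room for regridding in
real pipelines.

## Discrimination statistics

ROC analysis treats lesion voxels as the positive class scoring *low*
(orientation configurable and logged). AUC is the trapezoidal area of the
empirical curve, identical to the Mann–Whitney concordance probability with
half credit for ties — tested by exhaustive pair counting. Two AUCs
measured on the same voxels are compared with the DeLong correlated-curves
test implemented from midranks; its p-values agree with a paired-bootstrap
oracle and hold the nominal 5 % size over null simulations where both
scores carry identical signal. Group-level modelling (mixed-effects,
hierarchical regressions) is deliberately not reimplemented: the package
exports one tidy row per ROI × quantity (mean, SD, voxel count, volume)
for off-the-shelf statistics.

## Pipeline, determinism and problem sizes

The driver chains phantom → decay correction → SVCA (classes from
lesion-free control phantoms with seeds derived from the global seed) →
Logan + SUV → geometry → CBF → ROC, writing every intermediate as
uncompressed NIfTI-1 with a JSON provenance sidecar (stage, parameters);
re-running a config reproduces every output byte-for-byte. When no external
reference statistics are supplied, the impaired-WM cutoff uses the
subject's own NAWM mean/SD — with real cohorts, healthy-control statistics
should be passed explicitly.

Default problem sizes were chosen as the smallest grids on which every
geometric feature (two supra-resolution lesions, 8-mm rings, a grey-matter
shell hosting 30 blood voxels) is well resolved: 24³ voxels at 2 mm for the
standard phantom, 16³ at 3 mm for kinetic-recovery studies, 32³ at 2 mm for
the layer-gradient demonstration, which needs enough normal white matter
around an 8-mm perilesional rim for "normal-appearing" to mean something.

## Known limitations

- The centre-inside voxelization means no partial-volume effects; real
  perilesional gradients are confounded by scanner PSF, which the phantom
  does not model.
- SVCA here uses three classes; pathology-specific classes (e.g. a lesion
  class) are not modelled.
- The Logan fit is unweighted OLS on transformed coordinates;
  perpendicular-distance and multilinear variants are out of scope.
- Registration is out of scope throughout: phantoms are generated
  pre-aligned, and real inputs are assumed co-registered on one grid.
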