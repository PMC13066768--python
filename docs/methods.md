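# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what the synthetic phantom does and does not show
about real data.

## Signal model and frequency separation

The measured proton signal of a lung voxel under free breathing is
modeled as a slow multiplicative density term (parenchyma compresses at
expiration, signal up; expands at inspiration, signal down), a fast
additive cardiac term (blood inflow), a global monoexponential approach
to magnetization steady state, and noise.  Respiratory rates sit well
below and cardiac rates well above 0.7 Hz, so a single cutoff separates
the two mechanisms; with Δt = 288 ms the Nyquist rate is 1.74 Hz, which
accommodates heart rates up to ~104 bpm without aliasing.  The split uses
a zero-phase (forward–backward) Butterworth low-pass of order 4 with
symmetric reflection padding; the filter order is a package choice — what
matters downstream is zero phase, since any phase distortion would shift
respiratory extrema and corrupt phase sorting.  The perfusion branch is
computed as the exact complement (series − low-pass), so the two branches
reconstruct the input to floating-point precision and DC stays in the
ventilation branch.

## Registration

The engine estimates displacement from local quadratic (polynomial)
expansions of fixed and moving image computed under a Gaussian
applicability window (σ = 2 px, separable moment correlations).  The
pointwise relation A d = −(b_m − b_f)/2 is ill-posed wherever local
structure is weak, so the engine averages the normal equations (AᵀA,
Aᵀrhs) under a Gaussian of σ = 3 px — the fluid regularization — before
solving; pixels whose averaged structure tensor is near-singular, or
whose absolute strength is below 10⁻⁶ of the image maximum, contribute
nothing.  Estimation runs coarse-to-fine from a 8× downsampled level
(start scale 3) with six warp/estimate iterations per level; each
incremental update is bounded to ±2 px (larger motions belong to coarser
levels), composed with the accumulated field, and the accumulated field
is smoothed with a certainty-weighted Gaussian of σ = 3 px — the elastic
regularization — so that textureless lung interior adopts the consensus
of the surrounding structured regions over the iterations.

Warping uses cubic B-spline interpolation.  This was a considered
decision: bilinear warping blurs the warped moving image relative to the
fixed one, and on thoracic anatomy — asymmetric in the cranio-caudal
direction (dark lungs above a bright abdomen) — that blur mismatch turns
into a systematic sub-pixel displacement bias along the asymmetry (about
0.2–0.7 px vertically on the phantom, independent of the true motion).
Cubic interpolation removes the bias; on the phantom a 3-px translation
is recovered to < 0.05 px and a smooth 4-px sinusoidal deformation with a
mean endpoint error of ~0.35 px inside the lung.

Two series schedules exist: *direct* (each frame to the mean image of the
reference respiratory group, group 5 of 10) and *GOREG* (frames to their
own group mean, group means to the reference, fields composed).  There is
no randomness anywhere; repeated runs are bitwise identical, which is the
property the repeat-analysis experiment measures.

The estimated field is the backward map of the applied deformation, so
accuracy is assessed either against the analytic inverse (which the
phantom provides exactly) or as the endpoint error of the composition
with the generating field.

## Phantom

Frames are rendered by evaluating a continuous scene — soft-edged
(1.5 px smootherstep) ellipses for body, lungs, vessel disks, defect
circles — at analytically deformed coordinates.  No image is ever
resampled during generation, so the series carries no rendering
interpolation error, and the piecewise-linear vertical deformation
(maximal at the diaphragm, zero at the apex, rigid below the diaphragm)
has an exact closed-form inverse that is returned as the per-frame
ground-truth registration field.

Defaults are chosen to emulate the target acquisition: 128×128 grid, 200
frames at Δt = 0.288 s, respiratory period 4 s (0.25 Hz), cardiac period
0.9 s (1.11 Hz), 8 px diaphragm excursion, fractional ventilation 0.15
with a ±15 % gravity-style cranio-caudal gradient, parenchymal cardiac
amplitude 1.2 % of the parenchymal signal (vessels 6× stronger relative
to their own brighter baseline — together these put quantified perfusion
near 80 mL·min⁻¹·100 mL⁻¹ at 67 bpm), steady-state envelope starting at
3× equilibrium with τ = 1.5 s, two circular defect lesions multiplying
the local truth value by 0.2, and Gaussian noise σ = 0.01 (SNR ≈ 35 in
parenchyma).  The respiratory waveform is an asymmetric raised cosine
whose phase warp is smooth (`p = φ + 0.9 sin(2πφ)/2π`, shorter
inspiration); smoothness matters because a kinked waveform sheds
harmonics above 0.7 Hz that leak coherently into the perfusion branch
over the whole lung.  Parenchymal pulsation lags the vessels by 90 ms
(pulse transit).  The quantification ROI contains only pure-parenchyma
voxels: partial-volume voxels on pleural, vessel and defect boundaries
carry mixed signal by construction and are excluded, as a segmented
parenchymal ROI excludes pleura and central vessels.

What the phantom does *not* emulate: through-plane motion, coil/B1
inhomogeneity, Rician noise statistics, cardiac- and breath-to-breath
variability, lateral chest-wall motion, and realistic parenchymal
texture.  Passing recovery tests therefore demonstrates the correctness
of the pipeline's numerics and phase logic, not robustness to every
in-vivo confounder; in particular the textureless phantom interior makes
registration *harder* than real parenchyma, while perfectly periodic
waveforms make phase sorting easier.

## Phase estimation and cycle reconstruction

Respiratory grouping uses equal-count amplitude bins of the 0.7-Hz
low-passed lung-area signal (per-frame masks when available, otherwise a
threshold fallback counting dark pixels inside the body outline of the
temporal mean).  The continuous respiratory phase comes from the
diaphragm signal: sub-pixel edge position (parabolic refinement of the
maximal vertical gradient averaged over a column band), outlier exclusion
outside the 5th–97th percentiles (linear-interpolation percentiles,
flags only), and a per-breath cosine model — the signal is normalized to
[−1, 1] between parabolic-refined extrema and acos-inverted with the
branch chosen by the local slope, giving phase 0 at end-expiration and
0.5 at end-inspiration.

Both the 60-phase ventilation and the 15-phase perfusion cycles use
Nadaraya–Watson regression with a circular Gaussian kernel; the default
bandwidth is 1.5 phase spacings (≈ ±3 neighbours), a compromise between
amplitude attenuation (≈1 % at 60 phases) and variance at the ~30 usable
frames of a 15-s series; phases further than three bandwidths from any
sample are flagged.

Cardiac phases come from piecewise sinusoidal regression of the
vessel-ROI mean: beats are segmented at parabolic-refined signal peaks
(phase 0 at each peak), each beat gets its own period and linear
amplitude/offset fit.  At 288 ms there are only ~3 samples per beat, so
two guards matter: the sinusoid-fit frequency is refined off the FFT grid
(a fraction of a bin of mismatch destroys the fit over a 49-s record),
and inter-peak intervals spanning k dominant periods are subdivided
evenly (missed peaks at the sampling limit).

The vessel-ROI growth maximizes the R² of a single-frequency sinusoid
fit to the ROI-mean signal.  Because averaging in any voxel whose
pulsation is coherent with the ROI keeps R² creeping upward
monotonically, growth stops when R² fails to improve by 10⁻⁴ for three
consecutive steps (or at 200 px); a plateau, not only a drop, must
terminate.  Seeds are the top-percentile variance voxels inside the lung
mask — restricting the search matters, since warp artifacts at the image
border otherwise win the variance ranking.

## Parameter maps

RVent is the full-cycle fractional change (S_EE − S_EI)/S_EI read from
the reconstructed cycle (phases 0 and 0.5), reported in percent; reading
anchors from the cycle rather than raw extreme frames keeps the estimate
stable under truncation.  An alternative mid-respiration construction
(sum of the two half-cycle fractional changes through phase 0.25/0.75) is
kept behind the same isolated function.  FVL-CM correlates each voxel's
flow loop (circular central difference of the cycle) at zero lag with the
mean loop of the largest 8-connected component of voxels with RVent in
the 80th–90th percentile band (ties broken by larger mean RVent).
Perfusion amplitude is the cycle value at the parenchymal phase (the
phase whose 32-bin histogram mode over the parenchyma is largest;
switchable to the mean-based phase) minus the per-voxel cycle minimum.
QQ divides that amplitude by the equilibrium blood-pool signal — the
asymptote of a monoexponential fit S(t) = S_ss + (S₀ − S_ss)e^(−t/τ) to
the vessel-mask mean over the full transient-inclusive series — and
multiplies by heart rate (bpm) and 100.  The published method's
parenchymal blood and exchange-fraction corrections are reduced to a
single configurable scale factor (default 1) because their full form
requires calibration data this package does not model.

Defect thresholds (0.4×P90 for RVent, 0.15×P90 for QQ, 0.90 for FVL-CM)
are evaluated with percentiles over the parenchymal ROI only.  The
FVL-CM threshold is interpreted as the raw correlation value 0.90.
Regional overlap between two classifications aligns the two parenchymal
masks with a closed-form moment-matching affine transform (centroid,
principal axes with deterministic sign fixing, per-axis scale) and counts
identical labels over the aligned intersection; the Dice coefficient of
defect voxels is available alongside.

## Statistics

Paired Wilcoxon signed-rank tests drop zero differences and use the exact
null distribution (dynamic programming over signed midranks, valid with
ties) up to 25 non-zero differences, the tie-corrected normal
approximation beyond.  Pearson and Spearman correlations delegate to
scipy.  ICC(A,1) — single-measure absolute agreement — is computed from
the two-way ANOVA mean squares with the standard F-based 95 % interval
(Satterthwaite degrees of freedom); the implementation is cross-checked
in the tests against an independent ANOVA oracle and against
pingouin's `intraclass_corr`.  No multiple-testing correction is applied
(α = 0.05 throughout).

## Study harness and problem sizes

The truncation study analyzes each scan at 55/45/30/15 s (191/156/104/52
frames; frame count = round(duration/Δt), which reproduces all four
printed counts simultaneously where floor would not), analyzes the 55-s
reference twice with the first run as ground truth, and the steady-state
skip is applied after truncation, so the 15-s analysis rests on 32
dynamic frames.  Anything shorter errors out in the steady-state stage
with the minimum usable duration in the message.  Validation studies in
this repository run cohorts on 64×64 phantoms (the agreement and trend
statistics are resolution-independent) and single-subject checks at the
full 128×128; a full-resolution 191-frame analysis takes roughly half a
minute on one CPU core.

## Known limitations

* 2D only; no through-plane motion model or 3D extension.
* The registration engine is one-directional and non-diffeomorphic by
  design (single expansion model, no symmetric mode); an adapter
  interface accepts fields from external engines instead.
* QQ is quantitative only up to the configurable normalization scale; no
  landmark-based (pulmonary-artery) calibration.
* The cosine phase model assumes diaphragm-dominated, roughly sinusoidal
  breathing; irregular breathing degrades per-breath normalization.
* Lung/vessel segmentation is out of scope: masks come from the phantom
  truth (or any external segmentation), with only an Otsu-style
  threshold fallback for the lung-area signal.
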