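# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the methodology was genuinely
open.

## Synthetic data model

The generator produces a *known-answer* recording: every downstream test
measures recovery of quantities the generator planted.

**Atlas.** Regions are Voronoi cells of random seed points inside an
ellipsoidal brain mask, which keeps each region connected (verified, with
re-seeding on the rare fragmented draw). Landmarks are region centroids
plus four brain poles, in physical micrometres, so at least four
non-coplanar named points exist even for a two-region atlas.

**Sources and traces.** Each source is a truncated Gaussian blob
(σ = 2.5 voxels by default) placed inside exactly one region, biased toward
the region interior. Its time series is a drive — spontaneous events
(Poisson, lognormal amplitudes), a behavior-state indicator, ball optic
flow, or a stimulus boxcar — convolved with the indicator impulse response
and scaled so the **peak excursion equals `amplitude`** (default 25 a.u.
over a baseline of 100, i.e. tens-of-percent ΔF/F at the map peak). The
peak normalization matters: a sustained drive convolved with the kernel
otherwise integrates to many times the single-event response, producing
fluorescence swings of several hundred percent that no real indicator
shows. ArcLight traces are negated, because that voltage indicator dims
with depolarization.

**Indicator kernel.** Double exponential
`h(t) = (1 − e^(−t/τ_r)) · e^(−t/τ_d)`, peak-normalized, truncated below
10⁻³ of peak. The rise constant τ_r is solved numerically so the peak falls
at the indicator's rise-to-peak time: 0.15 s for GCaMP6f, 0.10 s for
ArcLight (0.55 s for GCaMP6s). Decay constants are not established for
these preparations; defaults are τ_d = 0.6 s (GCaMP6f), 0.3 s (ArcLight),
1.8 s (GCaMP6s), configurable. All recovery tests are insensitive to the
exact decay because they compare against traces built with the same kernel.

**Photobleaching.** Multiplicative exponential decay parameterized by the
fractional intensity loss over 30 s — 13% for GCaMP6/GFP, 20% for ArcLight
by default — i.e. τ = −30 s / ln(1 − f).

**Baseline anatomy.** By default the scalar baseline is modulated by an
anatomical field: per-region intensity levels (uniform in [0.7, 1.0])
over a 5% out-of-brain floor, smoothed with a σ = 1.5 voxel Gaussian. This
bright-brain/dark-background structure is what rigid registration locks
onto in real data, and its internal intensity boundaries are where
movement shadows form. `structured_baseline=False` gives the flat baseline
used by the algebraic rendering contracts.

**Behavior.** A semi-Markov process over rest/walk/groom with exponential
bout durations (means 8/5/3 s, floored at 0.3 s); walk bouts contain
turn sub-bouts (~1.5 s) of random direction whose flow magnitude is a
half-sine, so turns are one-sided and start/end at zero flow. Stimuli
alternate light and odor pulses (1 s) every 6 s with ±10% onset jitter.

**Motion and noise.** The motion path is a smoothed (σ = 10 frames)
Gaussian random walk normalized to unit per-axis amplitude (z halved —
volumes are thin in z); the renderer scales it by `motion_amp_voxels`, so
ground-truth shifts are `amp × path`. Noise is Gaussian read noise
(default SD 2 on a baseline of 100) plus optional scaled-Poisson shot
noise. Rendering is a deterministic function of the ground truth and seed.

**What the generator does not emulate:** optical blur and depth-dependent
resolution loss in the rendered movies (that physics lives in the light
field module and is tested there), non-rigid tissue deformation,
indicator saturation and nonlinearity, correlated (structured) noise, and
slow state drift. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not performance on any particular real
recording.

## Light field model

The forward operator is a deliberate geometric-optics stand-in for a
wave-optics light field PSF. Each depth layer is blurred with a normalized
Gaussian whose lateral σ grows linearly with distance from the focal plane
(σ(d) = σ₀(1 + w·|d|); defaults σ₀ = 1.5 µm, w = 0.02 µm⁻¹, axial width
twice lateral), pooled over each lenslet block, and deposited on one
subaperture pixel per depth: the signed depth index is mapped
proportionally onto the flattened pitch² subaperture index and rounded to
the nearest pixel. The default reconstruction geometry is 40 layers at
6 µm spacing. With pitch p and n ≤ p² layers every depth receives a
distinct subaperture, and lateral blur spreading across lenslet blocks
carries sub-lenslet position information, so the volume is recoverable.

The operator is linear and nonnegative with an *exact* adjoint
(block-pool/placement is a 0/1 matrix; the symmetric Gaussian convolution
under zero padding is self-adjoint), which is the correctness core of
Richardson–Lucy deconvolution: the multiplicative iteration
`v ← v · Aᵀ(y / max(Av, ε)) / Aᵀ1` with ε = 10⁻¹² then provably does not
increase the Poisson negative log-likelihood and preserves nonnegativity.
The iteration count is configurable (default 30; the round-trip tests use
50); no convergence claim is attached to any particular count.

FWHM measurement takes 1D profiles along x, y, z through each bead center
and locates half-maximum crossings by linear interpolation; lateral FWHM is
the mean of x and y. Profiles that never fall below half maximum inside
the volume are flagged rather than silently truncated.

## Preprocessing conventions

* **Motion correction** maximizes the circular cross-correlation between
  each mean-subtracted frame and the reference (first frame or temporal
  mean) over integer shifts within ±8 voxels, then refines each axis with
  a three-point parabolic fit. Translation-only: the rigid-registration
  contract is filled without reproducing any external tool's internals.
  With realistic activity amplitudes the residual bias from activity
  fluctuating against the reference is well under a tenth of a voxel.
* **Box averages** (detrending, high-pass) use centered windows of
  `round(window·rate)` frames with shrinking (truncated) windows at the
  edges — no data are fabricated beyond the recording. Whether the
  historical pipeline centered its window is unknowable; centered is
  chosen and stated. With an odd window length the average of a linear
  ramp equals the ramp, so detrending is exact on linear trends away from
  the edges.
* **Kalman-style denoising** is the first-order causal recursion
  `est_t = (1−g)·est_{t−1} + g·obs_t`, `est_0 = obs_0`, with the published
  gain of 0.5 as default; the referenced implementation's internals are
  not reproduced — the recursion with the stated gain *is* the contract.
* **ΔF/F** supports mean, low-percentile, and moving-window baselines.
  The moving baseline (box average over 15–30 s) folds slow-trend removal
  into F0 and is the right choice before condition statistics: a global
  mean baseline leaves the bleaching trend in the trace, and a circular
  permutation null is then inflated by trend alignment.
* **Clock alignment**: behavior timestamps are scaled by
  `1 − drift/60000` (30 ms/min default), then states are resampled by
  nearest neighbor (exact midpoints break toward the earlier sample) and
  flows by linear interpolation. Drifts above 10% are rejected as sensor
  errors.
* **SVD movement removal** subtracts chosen rank-1 terms of the centered
  voxel×time matrix. Auto mode flags components whose spatial energy
  concentrates (> 50%) on the top-decile spatial-gradient voxels — the
  shadow signature movement leaves around intensity boundaries. The rule
  is a heuristic formalization of a qualitative criterion and is exposed
  in config.
* **Z-slab reduction** partitions layers greedily from the focal plane
  outward, each slab sized `max(1, round(FWHM_axial(depth)/dz))`, and
  averages within slabs; boundaries are recorded in provenance.

## Source extraction

The chain is melodic-style spatial PCA/ICA. A pre-SVD (default 2
components) is removed before computing the per-voxel temporal variance so
the variance estimates noise, not signal; the *original* data are divided
by the square root of that variance (ε-floored). After a thin SVD of the
voxels×time matrix, the number of retained modes is **twice the shoulder
index** of the singular spectrum, clamped to the available rank.

**Shoulder convention.** "The point with a 45° tangent" is only
well-defined once both axes are normalized: the mode index and the log
singular value are each scaled to [0, 1]. The shoulder is the first index
at which the centered finite-difference slope of the normalized curve
crosses −1 — in either direction. Realistic spectra cross upward (a steep
signal decay flattening into the noise floor); a shallow plateau breaking
downward also qualifies. A flat spectrum, or one whose slope never crosses
−1, raises an error and callers may fall back to a fixed count
(`extract_sources` uses 20).

**ICA.** FastICA (logcosh contrast, tol 10⁻⁴, max 500 iterations, seed
mandatory) runs on the orthonormal spatial modes — spatial ICA, because
independence is claimed for the maps, not the time series. Component time
series are the least-squares projection of the data onto the unmixed maps
(equivalently, the inverse unmixing applied in mode space), variance
normalized with the amplitude folded into the maps, ordered by explained
temporal variance. Convergence failures are flagged, never silent. Signs
follow the positive-side rule: a map/trace pair is flipped iff the mean of
the map's positive part is smaller than the absolute mean of its negative
part.

**ROI masks** zero voxels below k·SD (k = 3) where the SD is computed
about zero — ICA maps are mean-free by construction — with `center="mean"`
available. Only the positive side of a map enters masks and region
sorting; the meaning of negative map lobes is left open.

## Annotation and artifact rules

Landmark registration solves the least-squares affine on ≥ 4 shared,
non-coplanar named landmarks and reports the residual RMS; resampling is
pull-back, nearest-neighbor for label fields and trilinear for continuous
ones. A component's region is the one with the highest mean of its
positive map inside the region mask (ties: larger overlap, then lower
label). "Present in a region" — undefined in qualitative descriptions of
this procedure — is made concrete as: more than 0.5% of the region's
voxels exceed the map's 3σ threshold. A component is auto-flagged when
present in more than 5 regions **or** fragmenting into more than 200
connected objects (26-connectivity default); the literal conjunction
("and") is also implemented because the prose is ambiguous, but "or" is
the default since movement shadows and noise speckle each violate one rule
strongly. Manual overrides are recorded as `manual:<label>` and never
silently dropped.

## Map statistics

Condition-difference maps are voxelwise mean ΔF/F differences between two
disjoint frame sets, antisymmetric under swapping, with the two-color
display convention recorded alongside (default green = positive). Stimulus
response maps average 1 s post-onset minus 1 s pre-onset over all onsets
with full windows. Cross-correlation peak lags use normalized correlation
at integer lags with parabolic sub-frame refinement; positive lag means
the second series follows the first.

The optional permutation test for map significance uses circular shifts of
the condition labels, computed for *all* shifts at once via FFT
cross-correlation with the condition-contrast indicator (deterministic;
`n_perm` optionally samples a seeded subset). Shifts shorter than the
condition signal's correlation time (bout length plus indicator decay)
produce surrogates still aligned with the behavior and are not valid null
draws; `min_shift_s` excludes them, and the default of 0 (keep all) is
therefore conservative. Statistical resolution is set by the number of
independent behavior bouts, so condition-map significance tests use
recordings of a few hundred seconds.

## Problem sizes and tolerances

The reference source-recovery problem is a 64×32×16-voxel movie with 2000
frames at 100 Hz and 8 planted sources at the default SNR; behavior-
coupling checks use 32×16×8 × 60 s at 100 Hz; condition-map statistics use
32×16×8 × 300 s at 25 Hz, sizes at which each measurement has comfortable
statistical resolution on a single CPU in minutes. Light field round trips
run on a 24×24 sensor, 9 layers, lenslet pitch 4, chosen so every depth
has a distinct subaperture and kernels span several lenslets. Numerical
tolerances: kernel normalization 10⁻⁹; adjoint identity 10⁻⁶ relative;
SVD reconstruction 10⁻⁶ relative; RL epsilon floor 10⁻¹²; variance floor
10⁻¹²; registration search ±8 voxels.

## Known limitations

* The geometric light field model shares only the *structure* of the real
  inverse problem; no claim of numerical agreement with wave-optics
  reconstructions is made, and aliasing artifacts are not modeled.
* Motion is rigid translation only; rotation and non-rigid deformation are
  out of scope.
* The shoulder convention, the region-presence rule and the SVD
  shadow-component heuristic are this package's own formalizations of
  qualitative descriptions; all three are exposed as configuration.
* FastICA on near-degenerate mixtures can converge to different local
  optima across seeds; the seed is therefore mandatory and recorded in
  every run log.
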