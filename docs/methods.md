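# Methods

## Damage model

The model treats radiation damage as a first-order decay of the
spectral SNR with accumulated exposure N (e⁻/Å²):

    SNR(k, N) = SNR(k, 0) · exp(−N / Ne(k)),

so Fourier amplitudes decay with the square root of that rate,
q(k, N) = exp(−N / (2·Ne(k))).  The critical exposure Ne is modeled as

    Ne(k) = a·k^b + c,

with defaults a = 0.245, b = −1.665, c = 2.81 (units such that Ne is in
e⁻/Å² with k in Å⁻¹), referenced to 300 kV.

Two points deserve emphasis:

* **The independent variable is spatial frequency in Å⁻¹, not
  resolution in Å.**  Only this reading produces the strongly
  resolution-dependent curve the model describes (Ne ≈ 45 e⁻/Å² near
  1/22 Å⁻¹ falling to ≈ 5 e⁻/Å² near 1/4 Å⁻¹); feeding resolutions in
  Å gives a nearly flat curve and silently wrong filter weights.
* **Voltage handling.**  The critical exposure is multiplied by 0.75 at
  200 kV.  Other voltages are rejected rather than interpolated — the
  25% figure is an empirical point value, and pretending to a scaling
  law between voltages would be false precision.

The DC term (k = 0) is undefined by the power law; all grid-level
weight evaluations substitute the smallest nonzero shell frequency so
the image mean is never amplified relative to its neighbors.

The optimal exposure, `optimal_ratio · Ne(k)` with ratio 2.5 by
default, is the exposure that maximizes accumulated SNR at frequency k;
it is exposed for planning acquisitions but plays no role in filtering.

## Exposure filter

For frames with Fourier transforms Fᵢ and accumulated exposures Nᵢ, the
per-shell-SNR-maximizing weights are the matched-filter weights
wᵢ ∝ qᵢ = q(k, Nᵢ) (Cauchy–Schwarz).  The filtered sum is

    F̃(k) = Σᵢ qᵢ(k)·Fᵢ(k) / sqrt(Σᵢ qᵢ(k)²).

The square root in the denominator is deliberate: with unit-variance
independent frame noise, the output noise variance is exactly that of a
single frame at every frequency, so the filter alters only the signal
content, never the noise floor.  A `nosqrt` variant (denominator
Σ qᵢ²) is provided for comparison.  Weights are evaluated per Fourier
voxel at the voxel's exact radial frequency; per-shell tables are
available for diagnostics.  A pre-summed input (e.g. a 3-frame sub-sum)
should carry the sub-sum's mean accumulated exposure.

When a per-shell estimate of the unattenuated single-frame SNR (PSSNR)
exists, the Wiener form Σ qᵢFᵢ / (Σ qᵢ² + 1/SNR(k)) is available, and a
CTF-aware generalization Σ CTFᵢ*·qᵢ·Fᵢ / (Σ (|CTFᵢ|·qᵢ)² + 1/SNR) for
per-frame reconstruction weighting (a per-voxel combine on 2D or 3D
grids; CTF values are supplied externally — CTF estimation is out of
scope).  Zero SNR is evaluated through the algebraically equivalent
form SNR·num / (SNR·den + 1), which realizes the low-SNR limit without
division by zero.  The filter deliberately ignores specimen movement;
early frames blurred by fast motion are not down-weighted beyond their
damage weight.

The model-predicted SNR of an unweighted n-frame sum relative to the
matched filter, (Σqᵢ)² / (n·Σqᵢ²), quantifies what plain summation
wastes: for a 38-frame, 53 e⁻/Å² schedule at 1/3 Å⁻¹ it is ≈ 0.33.

## Frame alignment

Each iteration loops over frames, cross-correlating the current frame
against the sum of all *other* currently-shifted frames (leave-one-out,
so a frame cannot lock onto its own noise), then fits a least-squares
cubic spline to X(t) and Y(t) over frame index and re-centers the mean
shift to zero (only relative motion is observable).  Iteration stops
when no frame's shift changes by more than 0.1 px (default) or after 20
iterations; non-convergence is flagged, never silent.

Numerical choices:

* Correlations are band-passed to 1/200–1/8 Å⁻¹ and damped with a
  Gaussian B-factor of 1500 Å² by default — values in line with common
  practice for this algorithm family, fully configurable.
* Sub-pixel peaks use parabolic interpolation over the 3×3
  neighborhood; ≤ 0.1 px on noiseless data, verified in tests.
* Ties between equal correlation maxima resolve to the peak nearest
  the previous iteration's shift (zero at the first iteration).
* Leave-one-out sums are maintained incrementally (total minus current
  frame), identical to explicit recomputation within float tolerance.
* Spline complexity is expressed as effective degrees of freedom,
  default n_frames/4 (min 4); fewer than 4 frames fall back to a
  polynomial.  Smoothing is applied after each full pass over frames.
* Initial shifts are zero.
* Aligning boxed particles or sub-sums is the same operation on a
  different stack; there is no separate code path.

## Critical-exposure estimation

Half-map pairs at increasing exposure yield FSC curves; per shell,
SNR = 2·FSC/(1−FSC), and ln SNR is regressed on N (OLS by default) over
points with N ≥ start_exposure (excluding the motion-dominated early
exposure range) and SNR above a censoring floor.  The floor is the
FSC-noise argument: pure-noise FSC in a shell of n independent voxels
has standard deviation ≈ 1/√(n/2), reduced by the symmetry factor when
maps were symmetrized; points below `noise_sigma_mult` (default 3)
times that are indistinguishable from noise.  Ne = −1/slope, with the
standard error propagated by the delta method (se(Ne) = se(slope)/slope²).
Shells with a non-negative slope or fewer than 3 usable points are
dropped with a recorded reason.  A weighted regression variant (weights
∝ SNR², the propagated inverse variance of ln SNR) is available behind
a flag.

The power-law fit is bounded nonlinear least squares (a > 0, b < 0,
c > 0), initialized from the data (c₀ = 0.9·min Ne, b₀ = −1.5, a₀ from
the highest-frequency point), with R² reported on the Ne values
directly.  Two stabilizing choices matter in practice:

* **Inverse-variance weighting by the per-shell se(Ne).**  The three
  parameters are strongly correlated along the fitted curve; without
  weighting, a handful of noisy shells can trade a against c by tens of
  percent while barely changing the curve itself.
* **Shells entering the law fit need ≥ 6 regression points** (all
  shells with ≥ 3 are still reported).  Slope standard errors from 3–4
  point regressions are unreliable, and shells censored down to a few
  points carry a selection bias: points that fluctuate upward survive
  the noise floor preferentially, flattening the apparent slope and
  inflating Ne.
* A fit whose power-law term barely varies over the fitted range is
  flagged degenerate (a and c are then unidentifiable separately).

Very-low-frequency shells should be excluded via `freq_range`: their
FSC sits so close to 1 that tiny errors explode in SNR, and on small
grids they contain very few voxels.  On a 128² grid the usable band in
our synthetic validations is roughly 1/22–1/3.8 Å⁻¹ at 1 Å/px, mirroring
where exposure-series regressions are well conditioned in general.

Resolution is reported at an FSC threshold (0.143 for half-map curves,
0.5 against an independent model), linearly interpolating the crossing
frequency between shells; a curve that never crosses reports Nyquist
with a warning.

## Synthetic data

The generator realizes exactly the measurement model above, so ground
truth is known in closed form:

* **Reference object**: a seeded mixture of Gaussian blobs (widths from
  sub-pixel to ~6 px) and ring features, with the radial amplitude
  spectrum then shaped to 1/(1 + k/k₀), k₀ = 0.05 cycles/px.  The
  shaping reflects that real particle images retain measurable
  structure across the whole band: an unshaped blob mixture is so
  spectrally red that the upper shells would carry no signal to damage
  or protect.  Every shell up to Nyquist has nonzero power.
* **Motion**: per-frame step lengths decay exponentially from
  `initial_rate_ang` (2.0 Å/frame) to `plateau_rate_ang` (0.2 Å/frame)
  with an 8-frame constant, in a slowly wandering direction; positions
  are mean-centered so a perfectly corrected sum coincides with the
  reference.  The returned ground-truth trajectory is the centered
  correction trajectory, directly comparable to the aligner's output.
* **Damage** is deterministic per-voxel amplitude attenuation
  q(k, Nᵢ) applied in Fourier space — the measurement model the
  analysis assumes, not a stochastic bond-breaking simulation.
* **Noise** is additive Gaussian, constant per frame (σ = 1.0 per
  pixel against a unit-variance reference), realizing the assumption
  that added noise is exposure-independent.  Poisson statistics,
  detector MTF/DQE, CTF and gain artifacts are deliberately absent;
  passing tests validate the estimators under their own model, not
  robustness to those effects.
* **Half-map pairs** use a separate noise scale (σ = 0.01) chosen so
  the low-frequency FSC sits above 0.999, as it does for reconstructions
  averaged over many particles; per-shell FSC precision then emulates
  study-scale 3D reconstructions on a desk-scale 2D grid, whose shells
  hold ~50× fewer voxels.

Default acquisition geometry is 130 frames at 0.769 e⁻/Å² (100 e⁻/Å²
total) on a 128² box at 1 Å/px — a desk-scale stand-in for a long
high-exposure movie.  All outputs are bit-reproducible for a fixed
seed.

## Validation problem sizes

The test suite validates end to end at sizes chosen for second-scale
runtimes: the damage-law recovery uses three independent 128² half-map
series of 40 exposure windows each (per-shell Ne agreement is asserted
as RMS over the mid-band, and the fitted constants as the median over
the three series — single-series constants scatter by several percent
because of the a/b/c correlation); alignment recovery uses 32-frame
128² movies totalling 100 e⁻/Å², with frame noise σ = 1.5 so that the
unfiltered sum's resolution falls measurably inside the band rather
than saturating at Nyquist.

## Known limitations

* Rigid, global, translational motion only: no rotations, no
  local/patch deformation, no tilt-series geometry.
* The filter does not model motion-dependent signal loss; early-frame
  weighting is therefore optimistic when motion is fast.
* MRC I/O covers the classic 1024-byte-header dialect (modes 0/1/2/6
  read, mode 2 write, no extended headers); compressed formats (TIFF,
  EER) and gain/defect correction are out of scope.
* Shell indexing requires square/cubic grids.
* Fractional-pixel shifts on even-sized grids are ambiguous at the
  Nyquist row; composition identities hold exactly on odd grids or
  band-limited content, and Fourier resampling folds/splits the Nyquist
  row to keep crop–pad round trips exact.
* Estimation assumes a single-exponential decay; multi-phase damage
  would bias Ne toward the dominant phase in the fitted exposure range.
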