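# Methods

## Forward model

The measurement of a back-illuminated transmittance mask `s(x, y)`
behind a scattering slab of thickness `L` is modelled as
`m(x, y, t) = α f_T(t) (W(·,·|t) * s)(x, y)`: a convolution whose
kernel changes with arrival time. `W(x, y | t)` is a centered
isotropic Gaussian with per-axis variance `2 D (t − t0)`; each
discretized frame is renormalized to unit mass on its grid, absorbing
every constant (including the pixel-area factor) into `f_T`, exactly
as the conditional-density factorization demands. `t0 = L n / c` is
the ballistic transit time; the frame containing it is represented by
the zero-variance limit (a discrete delta, split over the tied center
pixels on even grids). `D` is the photon diffusion coefficient in
mm²/ps; in the diffusive limit `D = c / (3 μs′)` with `μs′` the
reduced scattering coefficient, `≈ 0.1 mm²/ps` for the default
15 mm / μs′ = 10 cm⁻¹ phantom.

Assumptions: the medium is laterally homogeneous (a spatially
invariant kernel per frame — layered media are fine, lateral
heterogeneity is not), index-matched (no boundary refraction), and the
scene is dark outside the field of view (zero-padded convolutions).

The linear operator is applied implicitly: per-frame kernels are
FFT-cached once, a forward application is one batched FFT multiply,
and the adjoint is the exact transpose of pad–convolve–crop (verified
by dot-product tests to 1e-8 and against the dense matrix to 1e-10 on
small instances). Scene pixels may be an integer multiple of the
measurement pitch; pixel replication upsamples, block summation is its
adjoint. The dense matrix (one column per scene pixel, frames raveled
outermost) is available below a configurable entry cap for
pseudoinverse baselines and oracle tests.

## Monte Carlo transport

Photons random-walk through the layered slab with exponential free
paths (mean `1/μs` per layer), Henyey–Greenstein polar angles (analytic
inverse CDF), uniform azimuths, and continuous absorption attenuation.
There is no Russian roulette, so the weight ledger is exact:
transmitted + backscattered + absorbed + truncated weight equals the
number launched to machine precision. Photons exceeding a scatter-count
or time cap are recorded as truncated, never dropped silently. One seed
drives the whole batch (numba-compiled loop, bit-reproducible).
Validation: the sampled HG mean cosine matches quadrature of the HG
density, a clear slab transmits exactly at `L/c`, identical two-layer
stacks reduce to the single slab trajectory-for-trajectory, and the
lateral exit variance of transmitted photons grows linearly in time
with slope within 15 % of the diffusion-theory value `2c/(3μs′)`
(10⁶ photons, μs = 200 cm⁻¹, g = 0.85, 15 mm).

## Blind calibration

* `f_T`: the strongest pixel's trace (peak temporal amplitude; total
  energy available as an option). For extended scenes this trace
  carries an extra decaying factor — the kernel spreads past any one
  pixel — so the trace is used for normalization, while the model's
  arrival profile is taken from the per-frame signal mass above the
  noise floor, which is proportional to `f_T` for any scene. With the
  mass profile, `α f_T (W * s)` reproduces a noiseless synthetic
  measurement to ~3 % relative L2.
* Noise floor and `t0`: mean + 5 σ of the first 5 % of frames (the
  sweep starts dark), never below 3·10⁻⁴ of the cube peak (~70 dB, a
  12-bit sensor's dynamic range — without this floor a noise-free
  synthetic cube would "detect" physically meaningless 10⁻⁷-level
  residue). `t0` is the first frame above the floor, placed at that
  bin's leading edge so the first kernel is a half-bin Gaussian rather
  than a delta (an 8 ps bin integrates the earliest diffuse arrivals).
* Normalization: frames with `f_T` below 10⁻³ of its peak are zeroed
  and masked (division there only amplifies noise); the rest are
  divided by `f_T` and then rescaled to the median frame mass. Every
  normalized frame should be the scene convolved with a unit-mass
  kernel, so equal masses are a model identity; the rescaling removes
  the pixel-trace bias described above (it raised the letter
  round-trip SSIM from 0.30 to 0.77 and cleared a 0.2-level background
  haze). Plain division is available via `equalize_mass=False`.
* `D`: line search on the frame-ratio relation, 50-point log grid over
  [10⁻⁵, 1] mm²/ps with one 21-point refinement pass (resolution
  ~2.5 %). The discrepancy per frame pair is the L2 distance between
  *unit-normalized* frame shapes — amplitude-free, hence insensitive
  to per-frame gain error — summed over three pairs spanning
  early/mid/late diffusive frames. The relation contains no `t0`, and
  the estimate is invariant under time-origin shifts and time
  rebinning (tested). Recovery: within ~1 % noiselessly and ~2 % at
  50 dB across a decade of ground-truth D.

## Inversion

FISTA on `½‖As − m̄‖² + λ‖s‖₁` with projection to `s ≥ 0` (scenes are
transmittance masks; a flag disables it). The operator is the
normalized one (kernels only, masked to the valid frames); the data
are the normalized measurement. Step size 0.95 / L with L from power
iteration (deterministic all-ones start); standard adaptive
(gradient-scheme) momentum restart, which changes iteration count but
not the minimizer; the forward application at each iterate is reused
for the momentum point by linearity, so an iteration costs one forward
and one adjoint. Initialization: the noisy first-signal frame,
block-averaged to scene pitch, clipped and scaled to unit max. The
default configuration is λ = 0.004 and 10000 iterations with no early
stop; the studies here run a few hundred iterations with a relative
objective tolerance of 1e-7–1e-9, which is converged for these sizes.
Divergence (objective above 10× initial) raises a step-size error.

Baselines: time-average (sum over frames, unit-max), the raw frame at
the ballistic transit time (no denoising — through ~100 optical depths
it is noise, which is the point), and the Moore–Penrose pseudoinverse
on explicit small instances (singular-value cutoff `1e-10 · s_max`).

## Synthetic data generator

The emulator defines the study conditions. Defaults mirror the
reference acquisition scaled for desk-size runs: a 15 mm slab with
μs′ = 10 cm⁻¹ (g = 0.85), a 71 × 71 × 128 cube at 1 mm × 1 mm × 8 ps —
the same 1 ns window as the physical streak measurement, which records
305 × 305 × 512 at 0.3 mm / 2 ps — and measurement PSNR 61.7 dB
(seeded Gaussian sensor noise scaled to the cube peak, returned
unclipped so the realized PSNR is exact).

The ground-truth arrival profile is a delta spike at `t0` carrying
10⁻⁷ of the total mass plus a diffuse tail of the slab-transmission
form `t^(−5/2) exp(−L²/(4Dt))`, further suppressed near the front by
`exp(−t_c/(t − t0))` with `t_c` five transport-scattering times: the
raw diffusion Green's function is acausal at the ballistic front, and
without the suppression the earliest bins hold far more diffuse signal
than a physical slab delivers. The 10⁻⁷ ballistic fraction encodes
that through μsL ≈ 100 optical depths the unscattered component
(~e⁻¹⁰⁰) is unmeasurable: the frame at `t0` holds noise, which is the
regime in which early-photon gating fails and the all-photons
inversion is needed. An MC mode instead convolves the scene per frame
with an empirical random-walk PSF (real model mismatch, shot noise,
and no ballistic photons at all).

What the generator does *not* emulate: the 1D streak aperture and
mirror scan (the cube is taken as given), pile-up and gain
nonuniformity of a real sensor, lateral heterogeneity of the medium,
and sub-bin jitter. Passing tests therefore demonstrate the method's
behavior under its own model class plus sensor noise and (in MC mode)
transport-level mismatch — not robustness to arbitrary real-world
systematics.

## Evaluation

PSNR and SSIM after min-max scaling both images to [0, 1], the
reference defining the peak; SSIM is single-scale with Gaussian
window σ = 1.5, K1 = 0.01, K2 = 0.03 (window shrunk only for images
under 11 px). Slit resolvability is Rayleigh-style: project onto the
slit axis, smooth at one scene pixel, find local maxima above 25 % of
the profile peak, and merge adjacent peaks whose valley dips less than
20 % of the lower peak. `count_resolved_peaks` reports how many
features survive; `match_slit_peaks` counts how many *true* slit
positions are matched by a resolved peak within one scene pixel — the
right score for "recovering the correct locations", since a pure-noise
image yields several spurious resolved peaks but almost never three at
the right places. The slit-experiment harness gates the early-photon
baseline at the known ballistic time `L/c` (the slab thickness is
known in the physical setup); the inversion itself uses only its own
detected `t0`.

Recoverable resolution: slit pairs at decreasing separation, full
calibrate-and-invert per cube, smallest separation still showing two
resolved peaks; sensor time resolution is emulated by integer
rebinning of the native cube (a slower sensor integrating the same
photon stream), with trailing partial groups dropped.

## Problem sizes and numerical choices

The studies run at the 71 × 71 × 128 scaled grid with reconstructions
of 200–700 FISTA iterations under a 1e-7–1e-9 relative-objective
tolerance; Monte Carlo checks use 4·10⁵–10⁶ photons. Two consequences
of the scaling are documented rather than hidden: the scaled cube
averages sensor noise over ~130 measurements per scene pixel versus
~9800 at full acquisition size, so 61.7 dB noise costs ~0.03 SSIM here
where the full system loses none; and with 8 ps bins the sharpest
usable kernel has σ ≈ 0.9–1.4 mm, bounding the noiseless letter
round-trip near SSIM ~0.77 where the full 2 ps acquisition supports
>0.9. Ties, degenerate inputs, and error conditions (all-zero cubes,
f_T ≡ 0, non-integer pitch ratios, oversized dense matrices, diverging
steps) raise typed exceptions rather than propagating NaNs.

## Known limitations

Spatially varying (x, y) heterogeneity is out of scope (the kernel is
laterally invariant per frame); no polarization, coherence,
fluorescence, or refractive-index mismatch; general-basis sparsity and
TV solvers are not implemented (plain ℓ1 only); absolute
recoverable-resolution maps depend on the operational dip criterion
and on photon budget, so only their trends are asserted.
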