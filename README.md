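# allphotons

Imaging through thick, highly scattering media — slabs many mean free
paths deep, where almost no photon arrives unscattered — by using *all*
of the transmitted light instead of gating on the rare early photons.
The package is aimed at researchers in diffuse optical imaging and
computational imaging who want to simulate, calibrate, and invert
time-resolved transmission measurements of hidden scenes (masks behind
tissue phantoms, and their in-silico counterparts).

## The model

A pulsed source back-illuminates a hidden scene `s(x, y)` pressed
against a scattering slab; an ultrafast camera records the space-time
measurement `m(x, y, t)` on the far side. The forward model is a
time-variant convolution

```
m(x, y, t) = α · f_T(t) · ( W(·, · | t) * s )(x, y)
```

where `f_T(t)` is the photon arrival-time density (a weak ballistic
spike at the transit time `t0 = L/c` followed by the broad diffuse
tail) and `W(x, y | t)` is the spatial arrival density conditioned on
the arrival time: a centered isotropic Gaussian with per-axis variance
`2 D (t − t0)`, `D` being the photon diffusion coefficient of the
medium (`D = c / 3μs′` in the diffusive limit). Early frames are
nearly sharp and weak; late frames are bright and blurred — together
they are many *different* blurred views of the same scene.

Everything is estimated from the measurement itself (no calibration
arm): `f_T` from the strongest pixel's time trace, the noise floor and
`t0` from dark-frame statistics and first-signal detection, and `D` by
a line search on the frame-ratio relation — frame `t2` must equal
frame `t1` re-blurred by the incremental Gaussian of variance
`2 D (t2 − t1)`, a relation independent of `t0`. The scene is then
recovered by FISTA on the ℓ1-regularized least-squares problem

```
min_s  ½ ‖A s − m̄‖²  +  λ ‖s‖₁ ,      λ = 0.004, s ≥ 0
```

with `m̄` the f_T-normalized measurement and `A` the per-frame
convolution operator (implicit, FFT-based, with its exact adjoint; a
dense matrix is available for small instances). Baselines for
comparison: the time-averaged image, the raw early-photon frame, and
the Moore–Penrose pseudoinverse.

The package also contains a Henyey–Greenstein Monte Carlo photon
random walk through layered slabs (numba-compiled), used both to
generate empirical space-time PSFs and to validate the diffusion
kernel, plus an end-to-end measurement emulator, image-quality metrics
(PSNR, SSIM, slit resolvability), and recoverable-resolution sweeps
over sensor time resolution and slab thickness.

## Worked example

```python
from allphotons import (EmulatorConfig, SceneSpec, SolverConfig,
                        emulate_measurement, make_scene, psnr, ssim)
from allphotons.pipeline import reconstruct_api

scene = make_scene(SceneSpec(kind="slits", separation=10.0))  # 3 slits
cube, truth_model = emulate_measurement(scene, EmulatorConfig(seed=1))
api = reconstruct_api(cube, config=SolverConfig(max_iters=250, tol=1e-7))

print(f"D   = {api.calibration.model.D:.4f} mm^2/ps "
      f"(truth {truth_model.D:.4f})")
print(f"t0  frame {api.calibration.t0_frame} "
      f"(ballistic bin {cube.frame_index(truth_model.t0)})")
print(f"PSNR {psnr(scene, api.scene_hat):.1f} dB, "
      f"SSIM {ssim(scene, api.scene_hat):.2f}")
```

prints

```
D   = 0.1000 mm^2/ps (truth 0.0999)
t0  frame 7 (ballistic bin 6)
PSNR 17.3 dB, SSIM 0.73
```

The blind calibration recovers the diffusion coefficient of the 15 mm
slab to three digits and locates the first-signal frame one bin after
the ballistic transit (the true ballistic photons sit below the
sensor noise); the inversion then resolves all three slits at 10 mm
separation, which neither the time-averaged image (one merged blob)
nor the early-photon frame (noise) can do.

The same pipeline is scriptable from the shell:

```
allphotons emulate --scene slits10 --seed 1 --out m.tif
allphotons calibrate --cube m.tif --out model.json
allphotons reconstruct --cube m.tif --method api --out scene.tif
```

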