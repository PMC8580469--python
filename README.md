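# symscan

Quantification of **approximate symmetry** in 2-D biological images and
patterns, for plant morphometrics and pattern-formation studies:
rosette-forming flowers, bilaterally symmetric leaves and unicellular
algae, self-similar leaf whorls, and reaction–diffusion (Turing)
patterns.

Biological symmetry is almost never exact.  Rather than testing
invariance, `symscan` measures *how far* an image is from being invariant
under a candidate transformation T, using a divergence of
Kullback–Leibler type on the pixel intensity function μ > 0:

```
TI(μ, T) = (1/|D̃|) ∫_D̃ μ(x) ln[ μ(x) / Tμ(x) ] dA
```

where Tμ(x) = μ(T⁻¹x) and D̃ is the overlap of the image with its
transform.  TI = 0 exactly when T is a symmetry; local minima of TI over
a transformation family — rotations, reflections, periodic translations,
or rotation combined with rescaling — are the approximate symmetries of
the object, ranked by depth.  The same machinery estimates symmetry
centres and axes automatically, so no manual landmarking is needed.

The package contains:

* intensity extraction from raster images (luminance or the
  relative-greenness channel 2g − r − b + 1), with positivity flooring,
  masking and block-mean downsampling;
* geometric transforms with explicit overlap-domain handling (undefined
  samples are excluded, never zero-filled);
* TI evaluation, parameter scans, FFT-accelerated periodic translation
  maps, and signed difference maps;
* automatic symmetry detection (prominence-filtered minima) and three
  centre estimators (rotational ‖dTI/dθ‖, reflection TI, area balance);
* two classical baselines for comparison: the Simple Indicator (SI) for
  bilateral symmetry and the landmark-distance measure (ZI) for
  rotations;
* a spectral (ETDRK4) two-species reaction–diffusion simulator that
  generates Turing test patterns, with linear-stability and spectral
  diagnostics;
* a synthetic fixture generator with exact ground-truth symmetries, so
  everything is testable without image downloads;
* a `symscan` command-line interface over all of the above.

## Worked example

Detect the rotational symmetries of a noisy fivefold rosette:

```python
import numpy as np
from symscan import (FixtureSpec, make_fixture, ti_scan, find_symmetries,
                     RDParams, fastest_mode)

field, truth = make_fixture(
    FixtureSpec("rosette", n_fold=5, noise_amplitude=0.05, size=128, seed=1))
curve = ti_scan(field, "rotation", np.arange(0.0, 360.0, 1.0))
for c in find_symmetries(curve):
    print(f"rank {c.rank}: rotation by {c.spec.angle:.0f} deg  "
          f"TI={c.ti_value:.4f}  prominence={c.prominence:.3f}")

fm = fastest_mode(RDParams())
print(f"fastest mode: k={fm.k_max:.3f}  wavelength={fm.lambda_max:.3f}")
```

prints

```
rank 1: rotation by 216 deg  TI=1.6342  prominence=39.560
rank 2: rotation by 144 deg  TI=1.6575  prominence=35.591
rank 3: rotation by 288 deg  TI=1.6966  prominence=37.500
rank 4: rotation by 72 deg  TI=1.7136  prominence=37.418
fastest mode: k=6.966  wavelength=0.902
```

Exactly the four non-trivial fivefold rotations are found, all with
small TI (the pattern is nearly symmetric there — the 5% pixel noise
sets the residual) and large prominence (the minima are deep relative to
the ~39 TI reached at the least-symmetric angles).  The last line is a
diagnostic of the reaction–diffusion module: the wavenumber of the
fastest-growing linear mode at the default stripe-regime parameters,
which sets the emergent pattern scale.

The same flow from the shell:

```sh
symscan fixture --kind rosette --n-fold 5 --noise 0.05 --seed 1 rosette.png
symscan simulate --c 0 --seed 1 --t 100 state.npz
symscan ti --family translation state.field.npz ti_map.csv
```

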