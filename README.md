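# refblochi

Single-TI 3D post-contrast cardiac T1 mapping from late gadolinium
enhancement (LGE) volumes.

## The problem

Post-contrast myocardial T1 (and the extracellular volume fraction derived
from it) is a biomarker for diffuse fibrosis, but conventional T1 mapping
needs several differently T1-weighted acquisitions, which makes
high-resolution 3D mapping of thin-walled structures (left atrium, right
ventricle) prohibitively slow.  A 3D LGE scan — an inversion-recovery FLASH
acquisition at a single inversion time — is acquired routinely anyway.  This
package turns that *single* volume into a voxel-wise T1 map, given the
sequence parameters and one reference T1 (typically blood, from a quick 2D
breath-hold scan).

## The method

The steady-state longitudinal magnetization just before the readout train of
an inversion-recovery FLASH sequence (inversion efficiency β, inversion time
TI, N readout pulses of flip angle α spaced TR apart, inversion-to-inversion
interval RR) is

```
S = M0 · f(T1),    f(T1) = (1 − 2 e^(−TI/T1) + p e^(−RR/T1))
                           / (1 + cos(α)^N e^(−RR/T1))
```

where the perturbation coefficient `p ≥ 1` accounts for the saturation by
the α-pulse train.  With `E = exp(−TR/T1)` and `Q = cos(α)·E`,

```
p = [1 − (1 − E)(1 − Q^N)/(1 − Q)] / E^N
```

(validated against a discrete Bloch recursion to < 1e−9).  For TI ≈ 300 ms,
f is strictly decreasing over the post-contrast range, so signal and T1 are
in one-to-one correspondence.  M0 — the combined proton-density, T2* and
gain weighting — is nearly uniform across heart tissues once coil
sensitivity is removed, so a single-point calibration on blood
(`M0 = S_ref / f(T1_ref)`) fixes it, and every voxel is inverted by a grid
search over 100–800 ms in 2.5 ms steps.  The package also provides:

- **coil detrending** — trivariate cubic polynomial fitted over a
  non-contiguous blood-pool VOI, extrapolated over the heart and divided out;
- **multi-TI joint fitting** — the comparison method: bounded nonlinear
  least squares of three inversion-prepared signals plus one
  inversion-disabled signal for per-voxel (T1, M0), yielding the M0 maps
  that test the uniformity assumption;
- **error analysis** — first-order bias propagation for miscalibrated M0
  and for model errors (wrong effective RR, imperfect inversion), direct
  noiseless bias simulation, and Monte-Carlo precision curves;
- **ECV approximation** — `ECVa = (1/T1_m − 1/T1_m0)(1 − HCT)/(1/T1_b − 1/T1_b0)`
  with assumed native T1s;
- **digital phantoms** — seeded tube-array and cardiac-like volumes with
  per-compartment T1, near-unity M0 heterogeneity, a smooth multiplicative
  coil field, and Gaussian or Rician noise at a stated blood SNR.

## Worked example

```python
import numpy as np
from refblochi import (SequenceParams, PhantomSpec, CalibrationPoint, Volume,
                       generate_phantom, fit_trend, apply_detrend, map_volume,
                       ecva, EcvParams)

# swine-like protocol: TR/alpha/TI/RR/N = 3.9 ms/15 deg/300 ms/1000 ms/37
protocol = SequenceParams(tr_ms=3.9, flip_deg=15, ti_ms=300, rr_ms=1000, n_views=37)

# cardiac-like phantom: blood pool (T1 280), myocardium (450), scar (230),
# heart-like M0 heterogeneity, smooth coil shading, Gaussian noise at blood SNR 20
spec = PhantomSpec(geometry="cardiac", protocol=protocol, noise_model="gaussian",
                   snr=20, coil_amplitude=0.15, seed=7)
image, truth = generate_phantom(spec)
labels = np.asarray(truth["labels"].data)

# 1) coil detrending from a blood-pool VOI
voi = Volume((labels == 1).astype(float))
heart = Volume((labels > 0).astype(float))
flat = apply_detrend(image, fit_trend(image, voi), region=heart)

# 2) single-point calibration on blood (T1 known from a separate 2D scan)
ref_signal = float(np.mean(np.asarray(flat.data)[labels == 1]))
result = map_volume(flat, heart, CalibrationPoint(280.0, ref_signal), protocol)

for name, label in [("blood", 1), ("myocardium", 2), ("scar", 3)]:
    t1 = np.asarray(result.t1_volume.data)[labels == label]
    true = {1: 280, 2: 450, 3: 230}[label]
    print(f"{name:10s} true T1 = {true:3d} ms   mapped = {np.nanmean(t1):5.1f} "
          f"+/- {np.nanstd(t1):4.1f} ms")

# 3) approximate extracellular volume of a myocardial voxel
print(f"ECVa(T1_m = 450 ms, T1_b = 280 ms) = "
      f"{ecva(450.0, 280.0, EcvParams()):.3f}")
```

prints

```
blood      true T1 = 280 ms   mapped = 280.2 +/-  7.9 ms
myocardium true T1 = 450 ms   mapped = 448.4 +/- 18.3 ms
scar       true T1 = 230 ms   mapped = 242.8 +/-  6.7 ms
ECVa(T1_m = 450 ms, T1_b = 280 ms) = 0.256
```

Blood and myocardium are recovered within a few ms; the scar offset
(+13 ms) is the M0-heterogeneity bias at work — the phantom gives scar ~7%
lower proton-density/T2* weighting than the blood used for calibration, and
the error analysis bounds exactly this effect at ~20 ms for a ±10%
weighting change.  The spread grows with T1 because |f′(T1)| shrinks.

A command-line interface mirrors the library
(`refblochi simulate | detrend | map | multiti | ecv | bias | precision`;
see `refblochi --help`).  All times are milliseconds, angles degrees;
volumes are NIfTI-1.

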