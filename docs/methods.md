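# Methods

## Signal model

The LGE acquisition is modeled as a strictly periodic pulse sequence with
period RR: an inversion (Mz → −β·Mz, β ∈ (0, 1], β = 1 perfect), free
recovery over TI, then N cycles of (α pulse: Mz → Mz·cos α, free recovery
over TR), then free recovery over RR − TI − N·TR.  The signal is the
longitudinal magnetization in the periodic steady state *just before the
first α pulse*, matching centric phase-encode ordering, where the k-space
center — and hence image contrast — is acquired at the start of the train;
the sin α receive factor is absorbed into the global gain inside M0.

Solving the steady state gives, with `E = exp(−TR/T1)` and `Q = cos(α)·E`:

    f(T1)   = (1 − 2 e^(−TI/T1) + p e^(−RR/T1)) / (1 + cos^N(α) e^(−RR/T1))
    p       = [1 − (1 − E)(1 − Q^N)/(1 − Q)] / E^N          (p ≥ 1)
    f_β(T1) = (1 − (1+β) e^(−TI/T1) + p β e^(−RR/T1))
              / (1 + β cos^N(α) e^(−RR/T1))
    g(T1)   = (1 − p e^(−RR/T1)) / (1 − cos^N(α) e^(−RR/T1))   (no inversion)

`p` was derived from the recursion above (the geometric sum
`(1−Q^N)/(1−Q)` degenerates to N as Q → 1, which the code guards).  Every
closed form is validated against `bloch_recursion_oracle`, an independent
period-by-period simulation of the same sequence, to |Δ| < 1e−9 over
randomized valid protocols; the hypothesis-based equivalence tests are the
load-bearing correctness argument for the whole package, since everything
downstream consumes f.

Numerical notes:

- The product `p · e^(−RR/T1)` is evaluated as
  `e^(−(RR−N·TR)/T1) · [1 − (1−E)·S]`, which stays bounded as T1 → 0
  while `p` alone overflows.
- `f` is strictly decreasing on [100, 800] ms for all TI ≈ 300 ms
  protocols used here — that monotonicity is what makes the signal-to-T1
  inversion one-to-one.  The *signed* signal crosses zero above the
  post-contrast range (near T1 ≈ 780 ms for RR = 900 ms); it is positive
  throughout the 200–600 ms range where tissues live.
- `f′` is a central finite difference with h = 1 ms.  `p` depends on T1, so
  a symbolic derivative is error-prone; h = 1 ms is well below the 2.5 ms
  grid step, and the difference of the oracle-validated f inherits its
  accuracy.
- Angles are degrees at every public interface and converted to radians
  once; all times are milliseconds.

## Single-TI mapping

`M0` is estimated once per volume from a reference tissue of known T1
(blood: homogeneous, easily delineated, T1 intermediate between myocardium
and scar): `M0 = S_ref / f(T1_ref)`, with `S_ref` the *mean* detrended
signal over the reference ROI.  A calibration whose reference sits near the
signal null (f ≈ 0) is refused rather than amplified.

Each voxel is inverted by brute-force grid search: `argmin_T1 |S − M0·f(T1)|`
over 100–800 ms in 2.5 ms steps.  The f-lookup over the grid is precomputed
once per protocol and shared across voxels (bit-identical to per-voxel
evaluation).  Exact residual ties resolve to the smaller T1 — deterministic,
and conservative for scar detection.  Estimates that land on a grid endpoint
are kept but flagged in a boundary mask, leaving the accept/reject decision
to downstream QC.  Non-finite input voxels become NaN, never exceptions.

The ECV approximation
`ECVa = (1/T1_m − 1/T1_m0)·(1 − HCT)/(1/T1_b − 1/T1_b0)` uses assumed
native T1s (myocardium 1150 ms, blood 1500 ms, HCT 0.45 by default, all
configurable).  It is deliberately unclamped — dense fibrosis can exceed
1 − HCT — and only a vanishing blood-R1-change denominator raises.  Raising
the assumed native myocardial T1 by 100 ms (edema-like) shifts ECVa by
0.0175 (~0.02) independently of the post-contrast myocardial T1, which
bounds the cost of assuming a population native T1.

## Coil detrending

Coil shading is modeled as a multiplicative full trivariate cubic (all 20
monomials x^i y^j z^k, i+j+k ≤ 3) fitted by ordinary least squares to the
intensities of a non-contiguous blood-pool VOI, then evaluated over the
target region and divided out.  Choices:

- Coordinates are normalized to [−1, 1] per axis over the volume bounding
  box before fitting; the raw-index design matrix of a 20-term cubic is
  badly conditioned otherwise.
- Unweighted least squares (no noise model for the VOI is assumed).
- The fit requires ≥ 5 × 20 VOI voxels and a full-rank design; coplanar VOIs
  (e.g. a single slice) are rejected with guidance rather than silently
  producing an unconstrained z-dependence.
- Cubic extrapolation far from the VOI can go negative; `apply_detrend`
  refuses to divide if the trend is non-positive anywhere in the target
  region.  In practice the region should be a heart mask, and the VOI
  should span the slices of that region — a VOI confined to a small blob
  cannot constrain a 20-term cubic over a whole volume.
- Fitting is fully 3D (a single trend for the volume), not per-slice.

## Multi-TI comparison fit

Per voxel, (T1, M0) minimize the sum of squared residuals of `M0·f_TI(T1)`
for each inversion-prepared signal and `M0·g(T1)` for the inversion-disabled
one, via scipy's bounded trust-region-reflective least squares (T1 ∈
[50, 2000] ms, M0 ≥ 0).  Starts: T1 ∈ {200, 400, 700} ms with M0 seeded
from the no-inversion signal (g ≈ 1 near full recovery, so S₀ ≈ M0); the
best converged start wins, with an early exit once a start reaches an
essentially zero-residual optimum.  All-zero voxels are flagged degenerate
(M0 → 0 leaves T1 unidentifiable).  No inter-volume registration is
attempted.

Magnitude data are fitted against the signed model without de-rectification.
At TI = 100 ms the true Mz of long-T1 voxels is negative while magnitude
images are positive; voxels whose best fit pairs a negative model value with
a non-negative observation are flagged in the QC map (code 3) instead of
being silently trusted.

The M0 map, normalized to the blood-ROI mean (`m0_ratio_map`), measures the
proton-density/T2* heterogeneity that the single-TI method assumes small.

## Error analysis

Two bias categories propagate to first order through the calibrated
inversion, with δ = (estimated M0)/(true tissue M0):

- Category 1 (wrong M0, right model): ΔT1 ≈ (1 − δ) f / (δ f′).
  A reference-T1 error of ±Δ gives δ = f(T1_ref)/f(T1_ref ± Δ); tissue
  carrying k× the reference weighting gives δ = 1/k (the calibration is
  anchored on the reference, so the tissue's M0 is *under*-estimated by k).
- Category 2 (wrong model f vs true law f_true): ΔT1 ≈ (f_true − δ f)/(δ f′),
  with δ = f_true(T1_ref)/f(T1_ref) induced by calibrating through the wrong
  model.  Covers a wrong effective RR and an imperfect inversion assumed
  perfect.

`simulate_bias` checks both formulas against the ground truth: generate
noiseless signals under the scenario's true law, calibrate and grid-invert
exactly as the mapper would, and difference against the true T1.  The
formulas track the simulation to ~2–3.5 ms for reference-T1 bias, M0
heterogeneity and RR error.  For the imperfect inversion (β = 0.92) the
bias magnitude reaches ~50 ms at T1 = 600 ms and the first-order
linearization overshoots by up to ~7 ms there (−56.4 predicted vs −49.9
exact, verified by continuous root-finding independent of the grid); below
T1 = 500 ms agreement is within 5 ms.  This is an inherent property of a
first-order expansion at large ΔT1, not an implementation artifact, and the
test suite documents it as such.

Monte-Carlo precision: for each true T1, `n_reps` realizations of
signal + white Gaussian noise (σ = blood signal/SNR, blood T1 280 ms) are
grid-inverted and the sample SD reported.  Calibration uses the *noiseless*
reference signal — a noisy reference would conflate calibration error with
per-voxel noise and destroy the clean SD-vs-T1 shape; the spread then
follows σ/|f′(T1)|, growing with T1 and shrinking with SNR.  Estimates
clipped at the grid bounds are included in the SD (the conservative choice;
it is what the mapper returns).  Noise is real Gaussian on the signed model
signal; a Rician magnitude mode exists in the phantom generator for realism
studies but is deliberately absent from the precision path.  Default
experiment: 10,000 replicates, T1 200–500 ms, SNR {10, 15}, RR
{750, 950} ms, single recorded seed.

## Synthetic data

The phantom generator emulates what the method sees, not anatomy: voxel
intensity composes exactly as `C(x,y,z) · A · PD · exp(−TE/T2*) · f(T1)`
plus noise, with every factor returned as a truth volume.

- Geometries are schematic — a tube array (six T1s, default evenly spaced
  200–560 ms, spanning the post-contrast range; the exact values are
  configurable) and a cardiac-like blood-disc/myocardial-annulus/scar-sector
  arrangement on a 40×40×12 grid at 1.2×1.2×3 mm.  The method is voxel-wise;
  geometry exists to exercise detrending, masking and ROI statistics.
- Default M0 composition uses tissue-like values (PD 0.80/0.84/0.77,
  T2* 180/45/40 ms for blood/myocardium/scar, TE 1.9 ms), giving
  myocardium/blood and scar/blood weighting ratios within ~7% of unity —
  the near-uniformity the single-point calibration relies on.  Whole-blood
  water content follows its plasma/erythrocyte partition
  (0.55·0.93 + 0.45·0.64 ≈ 0.80), matching myocardium's ~80%.
- The coil field is the exponential of a seeded random quadratic in
  normalized coordinates (positive by construction); amplitude 0 disables
  it.
- Noise: Gaussian at a stated blood SNR (reference compartment's model
  signal over σ), or Rician via two quadrature Gaussian channels.  Every
  realization is reproducible from the spec's seed; multi-TI series share
  the coil field and truth but draw independent noise per volume.
- A seven-member protocol family (base TR/α/N/RR/TI =
  3.8 ms/15°/37/800 ms/300 ms; single-knob variants α→10°, RR→700, RR→900,
  N→51, TR→5.4 ms, and a ¼-SNR tag) supports sensitivity sweeps.

What passing phantom tests do **not** show: robustness to motion,
partial-volume and point-spread effects, flow, magnetization transfer,
off-resonance, or k-space artifacts — none are simulated.  Noise-wise, at
blood SNR 20 the grid-search estimator already carries a noise-induced
*skew* bias of ~+10 ms at T1 = 560 ms (|f′| shrinks with T1, so symmetric
signal noise maps to a right-skewed T1 distribution); phantom accuracy
assertions therefore bound per-tube bias for T1 ≤ 500 ms and the pooled
bias across the suite.

## Known limitations

- Pre-contrast (native) T1 mapping is out of scope: at native T1s the
  single-TI signal is weak and the calibration ill-conditioned.
- The single-TI method's precision degrades at long T1 and low SNR, with
  the skew bias noted above; the multi-TI fit dominates it at matched SNR.
- Bias formulas are first-order; expect ~10–15% overshoot where |ΔT1|
  approaches 50 ms.
- Automatic segmentation (blood pool, heart mask) is not provided; masks
  and ROIs are caller-supplied NIfTI volumes.
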