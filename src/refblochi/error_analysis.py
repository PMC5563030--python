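"""Accuracy (bias) and precision (Monte-Carlo) analysis of the single-TI mapper.

Four error sources confound the single-TI method, in two categories.

Category 1 — the calibrated M0 is wrong by a factor delta (a biased reference
T1, or spatial heterogeneity of the proton-density/T2* weighting), while the
signal model itself is right.  The first-order T1 bias is

    dT1 ~ (1 - delta) f(T1) / (delta f'(T1)).

Category 2 — the signal model used for calibration and inversion deviates
from the true signal law f_true (a wrong effective RR, or an imperfect
inversion assumed perfect):

    dT1 ~ (f_true(T1) - delta f(T1)) / (delta f'(T1)),

where delta is the M0 miscalibration induced at the reference tissue.  Both
approximations are validated here against direct noiseless simulation of the
full calibrate-and-invert pipeline.

Precision is characterized by Monte-Carlo simulation: Gaussian noise scaled
to a stated blood SNR is added to the model signal, each realization is
inverted by the grid search, and the spread of the estimates is reported.
Since the grid inversion is a single-parameter fit, the noise SD maps to a
T1 SD of roughly sigma/|f'(T1)|, worsening at long T1 where |f'| is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapper import CalibrationPoint, GridSpec, _GridInverter, estimate_m0
from .signal_model import SequenceParams, f_imperfect, f_prime, f_weight

__all__ = [
    "ACCURACY_PROTOCOL",
    "BiasScenario",
    "PrecisionSpec",
    "bias_category1",
    "bias_category2",
    "simulate_bias",
    "predict_bias",
    "monte_carlo_precision",
]

# default simulation protocol: TR/alpha/TI/RR/N = 5 ms/15 deg/300 ms/900 ms/33,
# blood-like reference T1 of 280 ms
ACCURACY_PROTOCOL = SequenceParams(tr_ms=5.0, flip_deg=15.0, ti_ms=300.0,
                                   rr_ms=900.0, n_views=33)
DEFAULT_REF_T1_MS = 280.0

_KINDS = ("ref_t1_bias", "m0_heterogeneity", "rr_error", "imperfect_inversion")


@dataclass(frozen=True)
class BiasScenario:
    """One systematic-error experiment.

    ``magnitude`` is interpreted per ``kind``: a reference-T1 offset in ms
    (ref_t1_bias, e.g. +-30), an M0 factor (m0_heterogeneity, e.g. 0.9/1.1),
    an RR offset in ms applied to the *nominal* model (rr_error, e.g. +-30),
    or the true inversion factor beta (imperfect_inversion, e.g. 0.92).
    """

    kind: str
    magnitude: float
    params: SequenceParams = ACCURACY_PROTOCOL
    ref_t1_ms: float = DEFAULT_REF_T1_MS
    t1_range_ms: tuple[float, float] = (200.0, 600.0)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "m0_heterogeneity" and self.magnitude <= 0:
            raise ValueError("M0 factor must be > 0")
        if self.kind == "imperfect_inversion" and not (0 < self.magnitude <= 1):
            raise ValueError("inversion factor must lie in (0, 1]")

    def true_f(self):
        """The signal law actually generating the data, as a callable of T1."""
        if self.kind == "rr_error":
            return lambda t1: f_weight(self.params, t1)  # truth keeps the real RR
        if self.kind == "imperfect_inversion":
            p = self.params
            p_beta = SequenceParams(p.tr_ms, p.flip_deg, p.ti_ms, p.rr_ms,
                                    p.n_views, inversion_factor=self.magnitude)
            return lambda t1: f_imperfect(p_beta, t1)
        return lambda t1: f_weight(self.params, t1)

    def model_params(self) -> SequenceParams:
        """The (possibly wrong) protocol the mapper believes in."""
        if self.kind == "rr_error":
            return self.params.with_rr(self.params.rr_ms + self.magnitude)
        return self.params

    def delta(self) -> float:
        """M0 miscalibration factor: estimated M0 over the tissue's true M0.

        When non-reference tissue carries k times the reference weighting,
        the calibration (anchored on the reference) underestimates that
        tissue's M0 by the same factor, so delta = 1/k.
        """
        model = self.model_params()
        if self.kind == "m0_heterogeneity":
            return float(1.0 / self.magnitude)
        if self.kind == "ref_t1_bias":
            return float(f_weight(model, self.ref_t1_ms)
                         / f_weight(model, self.ref_t1_ms + self.magnitude))
        return float(self.true_f()(self.ref_t1_ms) / f_weight(model, self.ref_t1_ms))


def bias_category1(delta: float, t1_ms, params: SequenceParams,
                   min_fprime: float = 1e-9):
    """First-order T1 bias from an M0 miscalibration factor delta."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    fp = np.asarray(f_prime(params, t1_ms))
    if np.any(np.abs(fp) < min_fprime):
        raise ValueError("f'(T1) is ~0; the bias propagation is ill-conditioned")
    out = (1.0 - delta) * np.asarray(f_weight(params, t1_ms)) / (delta * fp)
    return out if np.ndim(t1_ms) else float(out)


def bias_category2(f_true, delta: float, t1_ms, params: SequenceParams,
                   min_fprime: float = 1e-9):
    """First-order T1 bias when the model signal law deviates from ``f_true``."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    fp = np.asarray(f_prime(params, t1_ms))
    if np.any(np.abs(fp) < min_fprime):
        raise ValueError("f'(T1) is ~0; the bias propagation is ill-conditioned")
    out = (np.asarray(f_true(t1_ms)) - delta * np.asarray(f_weight(params, t1_ms))) \
        / (delta * fp)
    return out if np.ndim(t1_ms) else float(out)


def _t1_sweep(scenario: BiasScenario, grid: GridSpec) -> np.ndarray:
    lo, hi = scenario.t1_range_ms
    return np.arange(lo, hi + grid.step_ms / 2, grid.step_ms)


def simulate_bias(scenario: BiasScenario, grid: GridSpec = GridSpec()):
    """Direct noiseless simulation of the bias: generate, calibrate, invert.

    Returns ``(t1_true, delta_t1)`` over the scenario's range at the grid
    density.  True signals follow the scenario's truth model; calibration and
    grid inversion use the scenario's (possibly wrong) reference T1 and
    protocol, exactly as the mapper would.
    """
    t1_true = _t1_sweep(scenario, grid)
    f_true = scenario.true_f()
    signals = np.asarray(f_true(t1_true), dtype=float)
    if scenario.kind == "m0_heterogeneity":
        signals = scenario.magnitude * signals  # non-reference tissue only
    model = scenario.model_params()
    assumed_ref_t1 = scenario.ref_t1_ms + (
        scenario.magnitude if scenario.kind == "ref_t1_bias" else 0.0)
    cal = CalibrationPoint(ref_t1_ms=assumed_ref_t1,
                           ref_signal=float(f_true(scenario.ref_t1_ms)))
    m0 = estimate_m0(cal, model)
    est, _, _ = _GridInverter(model, grid).invert(signals, m0)
    return t1_true, est - t1_true


def predict_bias(scenario: BiasScenario, grid: GridSpec = GridSpec()):
    """Analytic first-order bias curve for the same sweep as :func:`simulate_bias`."""
    t1_true = _t1_sweep(scenario, grid)
    model = scenario.model_params()
    delta = scenario.delta()
    if scenario.kind in ("ref_t1_bias", "m0_heterogeneity"):
        bias = bias_category1(delta, t1_true, model)
    else:
        bias = bias_category2(scenario.true_f(), delta, t1_true, model)
    return t1_true, np.asarray(bias)


@dataclass(frozen=True)
class PrecisionSpec:
    """Monte-Carlo precision experiment over (SNR, RR) combinations.

    SNR is defined as the blood signal (reference T1, default 280 ms) divided
    by the Gaussian noise SD.  Calibration uses the noiseless reference
    signal, so the curves isolate per-voxel noise from calibration error.
    """

    tr_ms: float = 5.0
    flip_deg: float = 15.0
    ti_ms: float = 300.0
    n_views: int = 33
    rr_options_ms: tuple[float, ...] = (750.0, 950.0)
    snr_options: tuple[float, ...] = (10.0, 15.0)
    ref_t1_ms: float = DEFAULT_REF_T1_MS
    n_reps: int = 10_000
    t1_values_ms: tuple[float, ...] = tuple(float(t) for t in range(200, 501, 25))
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec)

    def protocol(self, rr_ms: float) -> SequenceParams:
        return SequenceParams(self.tr_ms, self.flip_deg, self.ti_ms, rr_ms,
                              self.n_views)


def monte_carlo_precision(spec: PrecisionSpec) -> pd.DataFrame:
    """SD of the grid-search T1 estimate vs true T1, per (SNR, RR).

    For each true T1, ``n_reps`` realizations of signal + Gaussian noise are
    inverted through the calibrated grid search; the sample SD of the
    estimates (boundary-clipped estimates included) is reported.  Returns a
    DataFrame with columns ``snr, rr_ms, t1_true_ms, sd_ms``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for rr in spec.rr_options_ms:
        params = spec.protocol(rr)
        ref_signal = float(f_weight(params, spec.ref_t1_ms))
        inverter = _GridInverter(params, spec.grid)
        for snr in spec.snr_options:
            sigma = ref_signal / snr
            for t1 in spec.t1_values_ms:
                clean = float(f_weight(params, t1))
                noisy = clean + rng.normal(0.0, sigma, size=spec.n_reps)
                est, _, _ = inverter.invert(noisy, m0=1.0)
                rows.append({"snr": snr, "rr_ms": rr, "t1_true_ms": t1,
                             "sd_ms": float(np.std(est, ddof=1))})
    return pd.DataFrame(rows)
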