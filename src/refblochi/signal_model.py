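"""Steady-state signal models for the inversion-recovery FLASH (LGE) sequence.

The late-gadolinium-enhancement sequence applies, once per inversion-to-
inversion interval RR: a (possibly imperfect) 180-degree inversion, a free
recovery of duration TI, a train of N small-flip-angle (alpha) readout pulses
spaced TR apart, and a final free recovery of RR - TI - N*TR.  The measured
signal is proportional to the longitudinal magnetization Mz in the periodic
steady state, taken just prior to the first alpha pulse (centric phase-encode
ordering puts the contrast-defining k-space center there).

Closed forms
------------
With ``E_TR = exp(-TR/T1)``, ``c = cos(alpha)`` and ``Q = c * E_TR``, the
periodic steady state of the recursion above gives

    Mzss = M0 * (1 - 2 exp(-TI/T1) + p exp(-RR/T1))
                / (1 + cos(alpha)^N exp(-RR/T1))

where the perturbation coefficient

    p = [1 - (1 - E_TR) (1 - Q^N) / (1 - Q)] / E_TR^N        (p >= 1)

captures how the alpha-pulse train raises the recovered magnetization
relative to the textbook inversion-recovery expression
``M0 (1 - 2 exp(-TI/T1) + exp(-RR/T1))``; the two coincide for a single
90-degree excitation (alpha = pi/2, N = 1, where p = 1).  Each closed form in
this module is cross-validated against :func:`bloch_recursion_oracle`, a
direct period-by-period simulation of the same pulse sequence.

All times are in milliseconds.  Flip angles are degrees at every public
interface and converted to radians exactly once, inside
:attr:`SequenceParams.flip_rad`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SequenceParams",
    "TissueState",
    "perturbation_coefficient",
    "mzss_simple",
    "mzss_ir",
    "mzss_noinv",
    "f_weight",
    "f_imperfect",
    "f_prime",
    "bloch_recursion_oracle",
]


class ParameterError(ValueError):
    """An acquisition parameter violates the sequence-timing constraints."""


@dataclass(frozen=True)
class SequenceParams:
    """IR-FLASH protocol: TR, flip angle, TI, RR, views-per-segment, inversion factor.

    Parameters
    ----------
    tr_ms : float
        Time between consecutive alpha pulses (ms), > 0.
    flip_deg : float
        Readout flip angle alpha in degrees, in (0, 90).
    ti_ms : float
        Inversion time: inversion pulse to first alpha pulse (ms), > 0.
    rr_ms : float
        Inversion-to-inversion interval (one or more cardiac R-R intervals, ms).
        Must leave a non-negative recovery window: ``ti_ms + n_views*tr_ms <= rr_ms``.
    n_views : int
        Number of alpha pulses per segment (views per segment), >= 1.
    inversion_factor : float
        Inversion efficiency beta in (0, 1]; 1 is a perfect 180-degree pulse.
    """

    tr_ms: float
    flip_deg: float
    ti_ms: float
    rr_ms: float
    n_views: int
    inversion_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tr_ms", "flip_deg", "ti_ms", "rr_ms"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not (0 < self.flip_deg < 90):
            raise ParameterError(f"flip_deg must lie in (0, 90), got {self.flip_deg!r}")
        if int(self.n_views) != self.n_views or self.n_views < 1:
            raise ParameterError(f"n_views must be an integer >= 1, got {self.n_views!r}")
        if self.ti_ms + self.n_views * self.tr_ms > self.rr_ms + 1e-9:
            raise ParameterError(
                "ti_ms + n_views*tr_ms exceeds rr_ms "
                f"({self.ti_ms} + {self.n_views}*{self.tr_ms} > {self.rr_ms})"
            )
        if not (0 < self.inversion_factor <= 1):
            raise ParameterError(
                f"inversion_factor must lie in (0, 1], got {self.inversion_factor!r}"
            )

    @property
    def flip_rad(self) -> float:
        return float(np.deg2rad(self.flip_deg))

    @property
    def recovery_ms(self) -> float:
        """Free recovery after the pulse train: RR - TI - N*TR."""
        return self.rr_ms - self.ti_ms - self.n_views * self.tr_ms

    def with_ti(self, ti_ms: float) -> "SequenceParams":
        return replace(self, ti_ms=ti_ms)

    def with_rr(self, rr_ms: float) -> "SequenceParams":
        return replace(self, rr_ms=rr_ms)


@dataclass(frozen=True)
class TissueState:
    """A tissue voxel: longitudinal relaxation time and scale factor.

    ``m0`` is the combined scaling of proton density, T2* weighting, coil
    sensitivity and global gain that multiplies the T1-weighting f(T1).
    """

    t1_ms: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.t1_ms) or self.t1_ms <= 0:
            raise ParameterError(f"t1_ms must be finite and > 0, got {self.t1_ms!r}")
        if not np.isfinite(self.m0):
            raise ParameterError(f"m0 must be finite, got {self.m0!r}")


def _check_t1(t1_ms) -> np.ndarray:
    t1 = np.asarray(t1_ms, dtype=float)
    if not np.all(np.isfinite(t1)) or np.any(t1 <= 0):
        raise ParameterError("t1_ms must be finite and > 0")
    return t1


def perturbation_coefficient(params: SequenceParams, t1_ms) -> np.ndarray | float:
    """Perturbation coefficient p >= 1 of the alpha-pulse train.

    p is the factor multiplying exp(-RR/T1) in the steady-state numerator;
    it equals 1 for a single 90-degree pulse and grows with N and alpha,
    reflecting saturation by the readout train.  Vectorized over ``t1_ms``.
    """
    t1 = _check_t1(t1_ms)
    e_tr = np.exp(-params.tr_ms / t1)
    q = np.cos(params.flip_rad) * e_tr
    n = params.n_views
    # geometric sum (1-Q^N)/(1-Q), with the Q -> 1 limit equal to N
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(np.abs(1.0 - q) > 1e-12, (1.0 - q**n) / (1.0 - q), float(n))
    p = (1.0 - (1.0 - e_tr) * s) / e_tr**n
    return p if p.ndim else float(p)


def _perturbed_tail(params: SequenceParams, t1: np.ndarray) -> np.ndarray:
    """The term p * exp(-RR/T1), computed in a form stable at short T1.

    p itself grows like exp(N*TR/T1) as T1 -> 0, but the product
    p * exp(-RR/T1) = exp(-(RR - N*TR)/T1) * [1 - (1 - E_TR) * S]
    stays bounded; evaluating it this way avoids overflow.
    """
    e_tr = np.exp(-params.tr_ms / t1)
    q = np.cos(params.flip_rad) * e_tr
    n = params.n_views
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(np.abs(1.0 - q) > 1e-12, (1.0 - q**n) / (1.0 - q), float(n))
    return np.exp(-(params.rr_ms - n * params.tr_ms) / t1) * (1.0 - (1.0 - e_tr) * s)


def mzss_simple(t1_ms, m0, ti_ms, rr_ms) -> np.ndarray | float:
    """Textbook steady-state inversion-recovery magnetization.

    ``M0 * (1 - 2 exp(-TI/T1) + exp(-RR/T1))`` — the single-90-degree-pulse
    model that neglects the perturbation of the readout train.
    """
    t1 = _check_t1(t1_ms)
    if ti_ms <= 0 or rr_ms <= 0:
        raise ParameterError("ti_ms and rr_ms must be > 0")
    out = m0 * (1.0 - 2.0 * np.exp(-ti_ms / t1) + np.exp(-rr_ms / t1))
    return out if np.ndim(out) else float(out)


def f_weight(params: SequenceParams, t1_ms) -> np.ndarray | float:
    """T1-weighting f(T1): the unit-M0 steady-state signal of the IR-FLASH train.

    Strictly decreasing over the post-contrast range for TI around 300 ms,
    which is what makes the signal-to-T1 inversion one-to-one.
    """
    t1 = _check_t1(t1_ms)
    e_rr = np.exp(-params.rr_ms / t1)
    num = 1.0 - 2.0 * np.exp(-params.ti_ms / t1) + _perturbed_tail(params, t1)
    den = 1.0 + np.cos(params.flip_rad) ** params.n_views * e_rr
    out = num / den
    return out if np.ndim(out) else float(out)


def f_imperfect(params: SequenceParams, t1_ms) -> np.ndarray | float:
    """T1-weighting with an imperfect inversion of efficiency beta.

    ``(1 - (1+beta) exp(-TI/T1) + p beta exp(-RR/T1))
      / (1 + beta cos(alpha)^N exp(-RR/T1))``;
    reduces to :func:`f_weight` at beta = 1.  beta is taken from
    ``params.inversion_factor``.
    """
    t1 = _check_t1(t1_ms)
    beta = params.inversion_factor
    e_rr = np.exp(-params.rr_ms / t1)
    num = (1.0 - (1.0 + beta) * np.exp(-params.ti_ms / t1)
           + beta * _perturbed_tail(params, t1))
    den = 1.0 + beta * np.cos(params.flip_rad) ** params.n_views * e_rr
    out = num / den
    return out if np.ndim(out) else float(out)


def mzss_ir(params: SequenceParams, state: TissueState) -> float:
    """Steady-state signal of the inversion-prepared FLASH train, M0 * f(T1).

    Uses :func:`f_imperfect` when ``params.inversion_factor < 1``; with a
    perfect inversion and alpha = 90 deg, N = 1 it equals :func:`mzss_simple`
    exactly.
    """
    if params.inversion_factor < 1.0:
        return float(state.m0 * f_imperfect(params, state.t1_ms))
    return float(state.m0 * f_weight(params, state.t1_ms))


def g_noinv(params: SequenceParams, t1_ms) -> np.ndarray | float:
    """Unit-M0 steady-state signal with the inversion pulse disabled.

    ``(1 - p exp(-RR/T1)) / (1 - cos(alpha)^N exp(-RR/T1))``.  The TI field
    of ``params`` is ignored (there is no inversion to time against); the
    alpha-0 degeneracy (0/0 -> 1, undisturbed equilibrium) is guarded.
    """
    t1 = _check_t1(t1_ms)
    e_rr = np.exp(-params.rr_ms / t1)
    num = 1.0 - _perturbed_tail(params, t1)
    den = 1.0 - np.cos(params.flip_rad) ** params.n_views * e_rr
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(den) > 1e-300, num / den, 1.0)
    return out if out.ndim else float(out)


def mzss_noinv(params: SequenceParams, state: TissueState) -> float:
    """Steady-state signal without inversion: M0 * g(T1)."""
    return float(state.m0 * g_noinv(params, state.t1_ms))


def f_prime(params: SequenceParams, t1_ms, h_ms: float = 1.0) -> np.ndarray | float:
    """d f / d T1 by central finite difference (1/ms).

    The perturbation coefficient depends on T1, so a symbolic derivative is
    error-prone; a central difference with h = 1 ms is well below the 2.5 ms
    grid-search step.  Negative over the post-contrast range for TI ~ 300 ms
    protocols, with |f'| decreasing in T1 (precision worsens at long T1).
    Valid for ``t1_ms > h_ms``.
    """
    t1 = _check_t1(t1_ms)
    if np.any(t1 <= h_ms):
        raise ParameterError(f"t1_ms must exceed the difference step {h_ms} ms")
    beta = params.inversion_factor
    f = f_imperfect if beta < 1.0 else f_weight
    out = (f(params, t1 + h_ms) - f(params, t1 - h_ms)) / (2.0 * h_ms)
    return out if np.ndim(out) else float(out)


def bloch_recursion_oracle(
    params: SequenceParams,
    state: TissueState,
    invert: bool = True,
    n_periods: int = 100_000,
    tol: float = 1e-13,
) -> float:
    """Discrete Bloch recursion run to its periodic steady state.

    Simulates, period by period: ``Mz -> -beta*Mz`` (if ``invert``), free
    relaxation over TI, then N cycles of (alpha pulse: ``Mz -> Mz cos(alpha)``,
    relaxation over TR), then free relaxation over RR - TI - N*TR.  Returns
    M0 times the converged Mz just prior to the first alpha pulse.  Without
    inversion the TI interval is ordinary free recovery, so the sampling point
    is RR - N*TR - (recovery) after the previous train, identical timing.

    This is the independent validation oracle for every closed form in this
    module; it shares no algebra with them.
    """
    t1 = state.t1_ms
    c = np.cos(params.flip_rad)
    e_tr = np.exp(-params.tr_ms / t1)
    e_ti = np.exp(-params.ti_ms / t1)
    e_rec = np.exp(-params.recovery_ms / t1)
    beta = params.inversion_factor
    mz = 1.0
    prev = None
    for _ in range(n_periods):
        if invert:
            mz = -beta * mz
        mz = mz * e_ti + (1.0 - e_ti)
        pre_train = mz
        for _ in range(params.n_views):
            mz = mz * c
            mz = mz * e_tr + (1.0 - e_tr)
        mz = mz * e_rec + (1.0 - e_rec)
        if prev is not None and abs(pre_train - prev) < tol:
            return state.m0 * pre_train
        prev = pre_train
    raise RuntimeError(
        f"Bloch recursion did not converge within {n_periods} periods (tol={tol})"
    )
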