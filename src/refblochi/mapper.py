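"""Single-TI T1 mapping: M0 calibration, grid-search inversion, ECV approximation.

The mapping engine rests on the one-to-one (monotone decreasing) relationship
between the LGE signal and the underlying T1 for TI around 300 ms: given the
scalar M0 from a single-point calibration on a reference tissue of known T1
(typically blood), every voxel's intensity is transformed to T1 by a grid
search over a practical post-contrast range (default 100-800 ms in 2.5 ms
steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_model import SequenceParams, f_weight
from .volume import Volume

__all__ = [
    "CalibrationPoint",
    "GridSpec",
    "T1MapResult",
    "EcvParams",
    "CalibrationError",
    "estimate_m0",
    "invert_signal",
    "map_volume",
    "ecva",
]


class CalibrationError(ValueError):
    """The reference tissue cannot support a single-point calibration."""


@dataclass(frozen=True)
class CalibrationPoint:
    """A reference tissue: its known T1 and its mean (detrended) signal."""

    ref_t1_ms: float
    ref_signal: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ref_t1_ms) or self.ref_t1_ms <= 0:
            raise CalibrationError(f"ref_t1_ms must be > 0, got {self.ref_t1_ms!r}")
        if not np.isfinite(self.ref_signal) or self.ref_signal <= 0:
            raise CalibrationError(f"ref_signal must be > 0, got {self.ref_signal!r}")


@dataclass(frozen=True)
class GridSpec:
    """T1 search grid (ms): default 100-800 ms, 2.5 ms density."""

    t1_min_ms: float = 100.0
    t1_max_ms: float = 800.0
    step_ms: float = 2.5

    def __post_init__(self) -> None:
        if not (self.t1_min_ms < self.t1_max_ms) or self.step_ms <= 0:
            raise ValueError(f"invalid grid {self}")

    def values(self) -> np.ndarray:
        return np.arange(self.t1_min_ms, self.t1_max_ms + self.step_ms / 2, self.step_ms)


@dataclass
class T1MapResult:
    """Voxel-wise T1 map plus the calibration scalar and boundary diagnostics."""

    t1_volume: Volume
    boundary_mask: np.ndarray
    m0_estimate: float
    grid: GridSpec = field(default_factory=GridSpec)


def estimate_m0(cal: CalibrationPoint, params: SequenceParams,
                tiny: float = 1e-6) -> float:
    """Scalar M0 from a single-point calibration: ref_signal / f(ref T1).

    Raises :class:`CalibrationError` when the reference T1 sits too close to
    the null point of the signal curve (f(ref T1) ~ 0), where the division is
    ill-conditioned.
    """
    fr = f_weight(params, cal.ref_t1_ms)
    if not np.isfinite(fr) or fr <= tiny:
        raise CalibrationError(
            f"f(ref T1 = {cal.ref_t1_ms} ms) = {fr:.3g} is too close to the signal "
            "null point for a stable calibration; choose a different reference"
        )
    return cal.ref_signal / fr


class _GridInverter:
    """Precomputed lookup of f over the grid, shared across voxels.

    Results are identical to per-voxel evaluation of f; argmin over an
    ascending grid breaks exact ties toward the smaller T1.
    """

    def __init__(self, params: SequenceParams, grid: GridSpec):
        self.grid = grid
        self.t1_grid = grid.values()
        self.f_grid = np.asarray(f_weight(params, self.t1_grid))

    def invert(self, signals: np.ndarray, m0: float):
        """Return (t1, boundary_flag, valid_flag) arrays for a signal array."""
        s = np.asarray(signals, dtype=float)
        valid = np.isfinite(s)
        model = m0 * self.f_grid
        idx = np.argmin(np.abs(np.where(valid, s, 0.0)[..., None] - model), axis=-1)
        t1 = self.t1_grid[idx]
        boundary = (idx == 0) | (idx == self.t1_grid.size - 1)
        t1 = np.where(valid, t1, np.nan)
        boundary &= valid
        return t1, boundary, valid


def invert_signal(signal, m0: float, params: SequenceParams,
                  grid: GridSpec = GridSpec()):
    """Grid-search signal-to-T1 inversion.

    Returns ``(t1_ms, at_boundary)`` with the shapes of ``signal``; scalars in,
    scalars out.  A non-finite signal yields NaN rather than an exception.
    Exact residual ties resolve to the smaller T1 (conservative for scar).
    """
    if m0 <= 0 or not np.isfinite(m0):
        raise CalibrationError(f"m0 must be finite and > 0, got {m0!r}")
    inv = _GridInverter(params, grid)
    t1, boundary, _ = inv.invert(np.asarray(signal, dtype=float), m0)
    if np.ndim(signal) == 0:
        return float(t1), bool(boundary)
    return t1, boundary


def map_volume(volume: Volume, mask: Volume, cal: CalibrationPoint,
               params: SequenceParams, grid: GridSpec = GridSpec()) -> T1MapResult:
    """Transform a (detrended) LGE volume into a T1 map inside a mask.

    The caller is responsible for coil-sensitivity detrending (see
    :mod:`refblochi.detrend`); the calibration signal must be measured on the
    same intensity scale as ``volume``.  Voxels outside the mask, and voxels
    with non-finite intensity, are NaN in the output map.
    """
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    m0 = estimate_m0(cal, params)
    inv = _GridInverter(params, grid)
    inside = np.asarray(mask.data) != 0
    t1_map = np.full(volume.shape, np.nan)
    boundary = np.zeros(volume.shape, dtype=bool)
    t1, bnd, valid = inv.invert(np.asarray(volume.data, dtype=float)[inside], m0)
    t1_map[inside] = t1
    boundary[inside] = bnd
    return T1MapResult(t1_volume=volume.like(t1_map), boundary_mask=boundary,
                       m0_estimate=m0, grid=grid)


@dataclass(frozen=True)
class EcvParams:
    """Assumed native T1s and hematocrit for the ECV approximation.

    Native (pre-contrast) myocardial and blood T1s are hard to measure in the
    same session as a 3D LGE, so population defaults are assumed: myocardium
    1150 ms, blood 1500 ms, hematocrit 0.45.
    """

    t1_m0_native_ms: float = 1150.0
    t1_b0_native_ms: float = 1500.0
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        if self.t1_m0_native_ms <= 0 or self.t1_b0_native_ms <= 0:
            raise ValueError("native T1s must be > 0")
        if not (0 < self.hematocrit < 1):
            raise ValueError(f"hematocrit must lie in (0, 1), got {self.hematocrit!r}")


def ecva(t1_m_ms, t1_b_ms, ecv_params: EcvParams = EcvParams()):
    """Approximate extracellular volume fraction from post-contrast T1s.

    ``ECVa = (1/T1_m - 1/T1_m0) * (1 - HCT) / (1/T1_b - 1/T1_b0)`` with the
    assumed native T1s of :class:`EcvParams`.  Vectorized over the
    post-contrast myocardial T1; the result is deliberately unclamped (ECVa
    may exceed 1 - HCT in dense fibrosis).
    """
    t1_m = np.asarray(t1_m_ms, dtype=float)
    t1_b = float(t1_b_ms)
    if np.any(t1_m <= 0) or t1_b <= 0:
        raise ValueError("post-contrast T1s must be > 0")
    denom = 1.0 / t1_b - 1.0 / ecv_params.t1_b0_native_ms
    if abs(denom) < 1e-12:
        raise ValueError(
            "blood R1 change is ~0 (post-contrast blood T1 equals the assumed "
            "native value); ECVa is undefined"
        )
    out = (1.0 / t1_m - 1.0 / ecv_params.t1_m0_native_ms) * (
        1.0 - ecv_params.hematocrit
    ) / denom
    return out if np.ndim(out) else float(out)
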