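"""Coil-sensitivity detrending by trivariate cubic-polynomial VOI fitting.

Receive-coil sensitivity multiplies the LGE image by a smooth, slowly varying
field.  Blood in the cardiac chambers is (to good approximation) isointense,
so intensities sampled over a non-contiguous blood-pool volume of interest
trace the coil profile.  A full trivariate cubic polynomial (20 monomials
x^i y^j z^k with i+j+k <= 3) is least-squares fitted to the VOI intensities,
extrapolated over the heart, and divided out of the volume.

Coordinates are normalized to [-1, 1] per axis over the volume bounding box
before fitting; this keeps the 20-term design well conditioned and makes the
coefficients comparable across volume sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume

__all__ = ["TrendModel", "FitDegenerateError", "fit_trend", "apply_detrend", "N_TERMS"]

# exponents (i, j, k) of every monomial x^i y^j z^k with i + j + k <= 3
_EXPONENTS = [(i, j, k) for i in range(4) for j in range(4) for k in range(4)
              if i + j + k <= 3]
N_TERMS = len(_EXPONENTS)  # 20


class FitDegenerateError(RuntimeError):
    """The VOI geometry cannot identify a full cubic trend."""


class ExtrapolationError(RuntimeError):
    """The extrapolated trend is non-positive somewhere in the target region."""


@dataclass
class TrendModel:
    """Fitted cubic trend: coefficients plus the coordinate normalization."""

    coefficients: np.ndarray      # (20,) in normalized coordinates
    center: np.ndarray            # (3,) voxel-index center per axis
    scale: np.ndarray             # (3,) voxel-index half-extent per axis
    residual_rms: float = float("nan")

    def evaluate(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Evaluate the trend on the full voxel grid of the given shape."""
        axes = np.indices(shape).reshape(3, -1).T
        design = _design(axes, self.center, self.scale)
        return (design @ self.coefficients).reshape(shape)


def _design(ijk: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    xyz = (ijk - center) / scale
    cols = [xyz[:, 0] ** i * xyz[:, 1] ** j * xyz[:, 2] ** k for i, j, k in _EXPONENTS]
    return np.stack(cols, axis=1)


def fit_trend(volume: Volume, voi_mask: Volume, min_ratio: int = 5) -> TrendModel:
    """Least-squares fit of the cubic coil trend to blood-pool VOI intensities.

    Requires at least ``min_ratio * 20`` VOI voxels and a full-rank design
    (coplanar or otherwise degenerate VOI geometry raises
    :class:`FitDegenerateError` with guidance).
    """
    if volume.shape != voi_mask.shape:
        raise ValueError(f"volume shape {volume.shape} != VOI shape {voi_mask.shape}")
    inside = np.asarray(voi_mask.data) != 0
    n_vox = int(inside.sum())
    if n_vox < min_ratio * N_TERMS:
        raise FitDegenerateError(
            f"VOI has {n_vox} voxels; at least {min_ratio * N_TERMS} are needed "
            f"to constrain the {N_TERMS}-term cubic trend"
        )
    ijk = np.argwhere(inside).astype(float)
    y = np.asarray(volume.data, dtype=float)[inside]
    if not np.all(np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("VOI intensities must be finite and positive")
    shape = np.array(volume.shape, dtype=float)
    center = (shape - 1.0) / 2.0
    scale = np.maximum(shape / 2.0, 1.0)
    design = _design(ijk, center, scale)
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < N_TERMS:
        raise FitDegenerateError(
            f"cubic design is rank-deficient (rank {rank} < {N_TERMS}); the VOI "
            "voxels are geometrically degenerate (e.g. coplanar) — spread the "
            "VOI across more slices and in-plane positions"
        )
    rms = float(np.sqrt(np.mean((design @ coeffs - y) ** 2)))
    return TrendModel(coefficients=coeffs, center=center, scale=scale, residual_rms=rms)


def apply_detrend(volume: Volume, trend: TrendModel,
                  region: Volume | None = None) -> Volume:
    """Divide the extrapolated trend out of the volume inside ``region``.

    ``region`` defaults to the whole volume; voxels outside it pass through
    unchanged.  If the cubic extrapolation is non-positive anywhere in the
    region the call refuses to divide (silent sign flips would corrupt the
    downstream T1 map) and raises :class:`ExtrapolationError`.
    """
    field = trend.evaluate(volume.shape)
    inside = np.ones(volume.shape, dtype=bool) if region is None \
        else np.asarray(region.data) != 0
    if np.any(field[inside] <= 0):
        raise ExtrapolationError(
            "extrapolated coil trend is non-positive inside the target region; "
            "the cubic is blowing up away from the VOI — restrict the region "
            "to the heart or enlarge the VOI coverage"
        )
    out = np.asarray(volume.data, dtype=float).copy()
    out[inside] = out[inside] / field[inside]
    return volume.like(out)
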