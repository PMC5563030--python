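"""Volume container, NIfTI I/O and sequence-parameter sidecars.

NIfTI-1 is the sole on-disk volume format; masks are NIfTI volumes with
nonzero meaning "included".  Sequence parameters travel in a small JSON or
YAML sidecar with keys ``tr_ms, flip_deg, ti_ms, rr_ms, n_views`` and an
optional ``inversion_factor`` (defaults to 1.0, a perfect inversion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .signal_model import ParameterError, SequenceParams

__all__ = ["Volume", "read_volume", "write_volume", "read_params", "FormatError"]


class FormatError(ValueError):
    """A file does not match the expected on-disk format."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and orientation metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"expected a 3D array, got {self.data.ndim}D")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "Volume":
        """A new Volume with the same geometry and different data."""
        if data.shape != self.data.shape:
            raise FormatError(f"shape {data.shape} != {self.data.shape}")
        return Volume(data=data, spacing=self.spacing, affine=self.affine.copy())


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 volume; array, spacing and affine survive round trips."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, file has {data.ndim} dimensions")
    zooms = img.header.get_zooms()[:3]
    return Volume(data=np.asarray(data), spacing=tuple(float(z) for z in zooms),
                  affine=np.asarray(img.affine, dtype=float))


def write_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data), volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


_REQUIRED_KEYS = ("tr_ms", "flip_deg", "ti_ms", "rr_ms", "n_views")


def params_from_dict(d: dict) -> SequenceParams:
    missing = [k for k in _REQUIRED_KEYS if k not in d]
    if missing:
        raise FormatError(f"sequence-parameter sidecar missing key(s): {', '.join(missing)}")
    try:
        return SequenceParams(
            tr_ms=float(d["tr_ms"]),
            flip_deg=float(d["flip_deg"]),
            ti_ms=float(d["ti_ms"]),
            rr_ms=float(d["rr_ms"]),
            n_views=int(d["n_views"]),
            inversion_factor=float(d.get("inversion_factor", 1.0)),
        )
    except ParameterError as exc:
        raise FormatError(f"invalid sequence parameters: {exc}") from exc


def read_params(path: str | Path) -> SequenceParams:
    """Load a validated SequenceParams from a JSON or YAML sidecar."""
    text = Path(path).read_text()
    suffix = Path(path).suffix.lower()
    if suffix == ".json":
        d = json.loads(text)
    else:
        d = yaml.safe_load(text)
    if not isinstance(d, dict):
        raise FormatError(f"{path}: expected a mapping of parameter keys")
    return params_from_dict(d)
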