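"""Digital phantoms emitting simulated LGE volumes with known ground truth.

Two schematic geometries stand in for scanner data: a tube array mimicking a
Gd-doped-water phantom (six T1s spanning the post-contrast range), and a
cardiac-like arrangement of blood pool, myocardial shell, scar sector and
empty background.  Geometry is deliberately schematic — the mapping method is
voxel-wise, so geometry only exercises detrending, masking and ROI handling.

Each voxel's noiseless intensity composes exactly as the signal model does:

    image = C(x,y,z) * A * PD * exp(-TE/T2*) * f(T1)

with a smooth multiplicative coil field C (exponential of a seeded low-order
polynomial, hence strictly positive), per-compartment proton density and T2*
weighting, and the steady-state T1-weighting f.  Gaussian noise at a stated
blood SNR (or optionally Rician, for magnitude-image realism) is added last.
All stochastic output is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .multi_ti import MultiTiSeries
from .signal_model import SequenceParams, f_weight, g_noinv
from .volume import Volume

__all__ = [
    "M0Composition",
    "PhantomSpec",
    "ProtocolVariant",
    "generate_phantom",
    "generate_multi_ti",
    "protocol_suite",
    "blood_water_fraction",
    "MYOCARDIUM_WATER_FRACTION",
]

# tissue water fractions used to argue proton-density near-uniformity
PLASMA_WATER_FRACTION = 0.93
ERYTHROCYTE_WATER_FRACTION = 0.64
MYOCARDIUM_WATER_FRACTION = 0.80


def blood_water_fraction(hematocrit: float = 0.45,
                         plasma_water: float = PLASMA_WATER_FRACTION,
                         erythrocyte_water: float = ERYTHROCYTE_WATER_FRACTION,
                         ) -> float:
    """Water content of whole blood from its plasma/erythrocyte partition.

    Plasma (the 1 - HCT fraction) is ~93% water and erythrocytes ~64% by
    weight, so at HCT = 0.45 whole blood is ~80% water — essentially the same
    as myocardium.  This near-equality of proton density between blood and
    myocardium is one pillar of the M0-uniformity assumption behind the
    single-point calibration.
    """
    if not (0 < hematocrit < 1):
        raise ValueError(f"hematocrit must lie in (0, 1), got {hematocrit!r}")
    return (1.0 - hematocrit) * plasma_water + hematocrit * erythrocyte_water


@dataclass(frozen=True)
class M0Composition:
    """Non-T1 weighting of each compartment: A * PD * exp(-TE/T2*).

    ``pd`` and ``t2star_ms`` map compartment names to proton density and T2*
    (ms).  Set ``t2star_ms`` to None to omit the T2* term (useful when the
    per-compartment factors are prescribed directly through ``pd``).
    Defaults give heart-like near-unity heterogeneity: the myocardium/blood
    and scar/blood weighting ratios come out within ~7% of unity.
    """

    a_const: float = 1.0
    te_ms: float = 1.9
    pd: dict = field(default_factory=lambda: {
        "blood": 0.80, "myocardium": 0.84, "scar": 0.77})
    t2star_ms: dict | None = field(default_factory=lambda: {
        "blood": 180.0, "myocardium": 45.0, "scar": 40.0})

    def factor(self, name: str) -> float:
        w = self.a_const * self.pd[name]
        if self.t2star_ms is not None:
            w *= float(np.exp(-self.te_ms / self.t2star_ms[name]))
        return w

    @classmethod
    def from_factors(cls, factors: dict) -> "M0Composition":
        """Prescribe the combined per-compartment weighting directly."""
        return cls(a_const=1.0, pd=dict(factors), t2star_ms=None)

    @classmethod
    def uniform(cls, names=("blood", "myocardium", "scar"),
                value: float = 1.0) -> "M0Composition":
        return cls.from_factors({n: value for n in names})


# base phantom protocol: TR/alpha/N/RR/TI = 3.8 ms/15 deg/37/800 ms/300 ms
BASE_PHANTOM_PROTOCOL = SequenceParams(tr_ms=3.8, flip_deg=15.0, ti_ms=300.0,
                                       rr_ms=800.0, n_views=37)

DEFAULT_TUBE_T1S_MS = (200.0, 272.0, 344.0, 416.0, 488.0, 560.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative phantom description; every realization is seeded.

    ``geometry`` is ``"cardiac"`` (blood pool disc, myocardial annulus, scar
    sector, empty background) or ``"tubes"`` (an array of Gd-doped-water-like
    tubes).  ``noise_model`` is ``"none"``, ``"gaussian"`` or ``"rician"``;
    ``snr`` is the reference-compartment signal over the noise SD.
    """

    geometry: str = "cardiac"
    shape: tuple[int, int, int] = (40, 40, 12)
    spacing: tuple[float, float, float] = (1.2, 1.2, 3.0)
    t1_ms: dict = field(default_factory=lambda: {
        "blood": 280.0, "myocardium": 450.0, "scar": 230.0})
    tube_t1s_ms: tuple[float, ...] = DEFAULT_TUBE_T1S_MS
    m0: M0Composition = field(default_factory=M0Composition)
    protocol: SequenceParams = BASE_PHANTOM_PROTOCOL
    noise_model: str = "none"
    snr: float = 20.0
    coil_amplitude: float = 0.0   # 0 disables the coil field (C = 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("cardiac", "tubes"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")

    @property
    def reference_compartment(self) -> str:
        """Compartment anchoring the SNR definition and default calibration."""
        if self.geometry == "cardiac":
            return "blood"
        shortest = int(np.argmin(self.tube_t1s_ms))
        return f"tube{shortest + 1}"

    def compartments(self) -> dict:
        """name -> (label, t1_ms); label 0 is signal-free background."""
        if self.geometry == "cardiac":
            return {name: (i + 1, self.t1_ms[name])
                    for i, name in enumerate(("blood", "myocardium", "scar"))}
        return {f"tube{i + 1}": (i + 1, t1)
                for i, t1 in enumerate(self.tube_t1s_ms)}

    def m0_factor(self, name: str) -> float:
        if self.geometry == "tubes":
            # doped water tubes share one composition unless overridden
            return self.m0.factor(name) if name in self.m0.pd else self.m0.a_const
        return self.m0.factor(name)


def _labels(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.hypot(x - cx, y - cy)
    labels2d = np.zeros((nx, ny), dtype=np.int16)
    if spec.geometry == "cardiac":
        r_blood = 0.28 * min(nx, ny)
        r_epi = 0.42 * min(nx, ny)
        labels2d[r <= r_blood] = 1
        shell = (r > r_blood) & (r <= r_epi)
        labels2d[shell] = 2
        theta = np.arctan2(y - cy, x - cx)
        labels2d[shell & (theta > 0.3) & (theta < 1.3)] = 3  # scar sector
    else:
        n_tubes = len(spec.tube_t1s_ms)
        n_cols = int(np.ceil(np.sqrt(n_tubes)))
        n_rows = int(np.ceil(n_tubes / n_cols))
        radius = 0.42 * min(nx / n_cols, ny / n_rows) / 2.0 * 2.0
        for t in range(n_tubes):
            row, col = divmod(t, n_cols)
            tx = (col + 0.5) * nx / n_cols
            ty = (row + 0.5) * ny / n_rows
            labels2d[np.hypot(x - tx + 0.5, y - ty + 0.5) <= radius] = t + 1
    return np.repeat(labels2d[:, :, None], nz, axis=2)


def _coil_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """exp of a seeded random quadratic in normalized coordinates (positive)."""
    if spec.coil_amplitude == 0:
        return np.ones(spec.shape)
    axes = [np.linspace(-1.0, 1.0, n) for n in spec.shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x**2, y**2, z**2]
    coeffs = rng.normal(0.0, spec.coil_amplitude, size=len(terms))
    logc = sum(c * t for c, t in zip(coeffs, terms))
    return np.exp(logc)


def _assemble(spec: PhantomSpec, tissue_signal) -> tuple[Volume, dict]:
    """Build image and truth from a per-compartment noiseless signal function."""
    rng = np.random.default_rng(spec.seed)
    labels = _labels(spec)
    coil = _coil_field(spec, rng)
    t1_map = np.zeros(spec.shape)
    m0_map = np.zeros(spec.shape)
    clean = np.zeros(spec.shape)
    for name, (label, t1) in spec.compartments().items():
        sel = labels == label
        w = spec.m0_factor(name)
        t1_map[sel] = t1
        m0_map[sel] = w
        clean[sel] = w * tissue_signal(t1)
    clean *= coil
    ref_name = spec.reference_compartment
    _, ref_t1 = spec.compartments()[ref_name]
    sigma = spec.m0_factor(ref_name) * abs(tissue_signal(ref_t1)) / spec.snr
    if spec.noise_model == "none":
        image = clean
    elif spec.noise_model == "gaussian":
        image = clean + rng.normal(0.0, sigma, spec.shape)
    else:  # rician magnitude: quadrature Gaussian channels
        image = np.hypot(clean + rng.normal(0.0, sigma, spec.shape),
                         rng.normal(0.0, sigma, spec.shape))
    geom = dict(spacing=spec.spacing)
    truth = {
        "t1": Volume(t1_map, **geom),
        "m0": Volume(m0_map, **geom),
        "coil": Volume(coil, **geom),
        "labels": Volume(labels, **geom),
    }
    return Volume(image, **geom), truth


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, dict]:
    """Simulated single-TI LGE volume plus truth maps (t1, m0, coil, labels)."""
    return _assemble(spec, lambda t1: float(f_weight(spec.protocol, t1)))


def generate_multi_ti(spec: PhantomSpec, tis_ms) -> tuple[MultiTiSeries, dict]:
    """Inversion volumes at each TI plus a no-inversion volume, sharing truth.

    All volumes share the spec's seed-derived coil field; the noise
    realization differs per volume (independent acquisitions).
    """
    clean_spec = replace(spec, noise_model="none")
    ti_volumes = []
    truth = None
    for offset, ti in enumerate(tis_ms):
        proto = spec.protocol.with_ti(float(ti))
        # the coil field comes from the shared base seed, so it is identical
        # across the series; noise (if any) is drawn per volume below
        img, truth = _assemble(replace(clean_spec, protocol=proto),
                               lambda t1, _p=proto: float(f_weight(_p, t1)))
        if spec.noise_model != "none":
            img, _ = _renoise(replace(spec, seed=spec.seed + 1 + offset), img, truth)
        ti_volumes.append((float(ti), img))
    img0, _ = _assemble(clean_spec, lambda t1: float(g_noinv(spec.protocol, t1)))
    if spec.noise_model != "none":
        img0, _ = _renoise(replace(spec, seed=spec.seed + 1 + len(tis_ms)),
                           img0, truth, noinv=True)
    series = MultiTiSeries(ti_volumes=ti_volumes, noinv_volume=img0,
                           params=spec.protocol)
    return series, truth


def _renoise(spec: PhantomSpec, clean: Volume, truth: dict,
             noinv: bool = False) -> tuple[Volume, dict]:
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference_compartment
    _, ref_t1 = spec.compartments()[ref]
    model = g_noinv(spec.protocol, ref_t1) if noinv else f_weight(spec.protocol, ref_t1)
    sigma = spec.m0_factor(ref) * abs(float(model)) / spec.snr
    data = np.asarray(clean.data, dtype=float)
    if spec.noise_model == "gaussian":
        noisy = data + rng.normal(0.0, sigma, data.shape)
    else:
        noisy = np.hypot(data + rng.normal(0.0, sigma, data.shape),
                         rng.normal(0.0, sigma, data.shape))
    return clean.like(noisy), truth


@dataclass(frozen=True)
class ProtocolVariant:
    """One member of the phantom protocol family; snr_factor scales the noise."""

    name: str
    params: SequenceParams
    snr_factor: float = 1.0


def protocol_suite() -> list[ProtocolVariant]:
    """The seven-protocol phantom family: a base protocol and single-parameter variants.

    Base: TR/alpha/N/RR/TI = 3.8 ms/15 deg/37/800 ms/300 ms.  Variants change
    one knob each: flip angle to 10 deg, RR to 700 and to 900 ms, N to 51,
    TR to 5.4 ms, and an SNR-reduced (factor 4) acquisition of the base.
    """
    base = BASE_PHANTOM_PROTOCOL
    return [
        ProtocolVariant("base", base),
        ProtocolVariant("alpha_10deg", replace(base, flip_deg=10.0)),
        ProtocolVariant("rr_700ms", base.with_rr(700.0)),
        ProtocolVariant("rr_900ms", base.with_rr(900.0)),
        ProtocolVariant("n_51", replace(base, n_views=51)),
        ProtocolVariant("tr_5p4ms", replace(base, tr_ms=5.4)),
        ProtocolVariant("snr_quarter", base, snr_factor=0.25),
    ]
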