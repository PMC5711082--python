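"""Organ-dose accumulation over a slab-discretised stylised phantom.

The MIRD-5 stylised adult phantom is discretised head to mid-thigh into
208 axial slabs of 5 mm.  A scanner-specific Monte Carlo dataset supplies,
for every organ and every slab, the organ dose per unit free-in-air CTDI
delivered when that single slab is irradiated.  A scan is then the
weighted sum of slab contributions over its coverage:

    D_o = CTDIair(kV) * (mAs_rot / 100) * RelCTDI(collimation)
          * sum_s coeff[o][s] * w[s] / p_eff

where ``w[s]`` is the fractional coverage of slab s by the irradiated
range (half-open [start, end), partial end slabs weighted by overlap /
slab thickness), ``mAs_rot = mA * rotation time``, and ``p_eff`` is the
pitch for helical scans and 1 for axial modes.  CTDIair is normalised per
100 mAs, hence the /100.

Three scan modes are supported: ``helical`` (continuous table feed,
coverage is the scan range, dose scales as 1/pitch), ``axial_contiguous``
(successive rotations in beam-width steps; each rotation irradiates one
collimation-wide window), and ``volume_axial`` (a single wide-collimation
rotation with no table motion; coverage is the collimation window centred
on the requested range).  When the relative CTDI of the two collimations
is equal, contiguous-axial and volume acquisitions over identical
coverage give identical doses.

Helical over-ranging (extra rotations beyond the imaged range) is not
modelled; coverage is exactly the requested range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ctdi import ValidationError, rel_ctdi
from .matching import ScannerModel

__all__ = [
    "SlabPhantom",
    "DoseDataset",
    "ScanProtocol",
    "OrganDoseResult",
    "slabs_covered",
    "organ_dose",
    "compare_modes",
]

SCAN_MODES = ("axial_contiguous", "helical", "volume_axial")


@dataclass(frozen=True)
class SlabPhantom:
    """Axial slab discretisation of a stylised phantom.

    Slab i occupies the half-open interval [i*t, (i+1)*t) mm measured from
    the head end (z = 0 at the top of slab 0).
    """

    organ_names: tuple[str, ...]
    n_slabs: int = 208
    slab_thickness_mm: float = 5.0
    z_origin: str = "head end of slab 0"

    def __post_init__(self) -> None:
        names = tuple(self.organ_names)
        if self.n_slabs < 1:
            raise ValidationError("n_slabs must be >= 1")
        if self.slab_thickness_mm <= 0:
            raise ValidationError("slab_thickness_mm must be > 0")
        if len(set(names)) != len(names) or not names:
            raise ValidationError("organ names must be unique and non-empty")
        object.__setattr__(self, "organ_names", names)

    @property
    def extent_mm(self) -> float:
        return self.n_slabs * self.slab_thickness_mm


@dataclass(frozen=True)
class DoseDataset:
    """Per-slab organ dose coefficients for one reference scanner and kV.

    ``coeff[i, s]`` is the dose to organ i per unit free-in-air CTDI when
    slab s alone is irradiated (dimensionless, mGy per mGy).
    """

    phantom: SlabPhantom
    coeff: np.ndarray
    kv: float
    dataset_id: str

    def __post_init__(self) -> None:
        c = np.asarray(self.coeff, dtype=float)
        n_org = len(self.phantom.organ_names)
        if c.shape != (n_org, self.phantom.n_slabs):
            raise ValidationError(
                f"coefficient matrix must be ({n_org}, {self.phantom.n_slabs}), got {c.shape}"
            )
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValidationError("coefficients must be finite and nonnegative")
        object.__setattr__(self, "coeff", c)


@dataclass(frozen=True)
class ScanProtocol:
    """One acquisition: technique factors plus the irradiated range."""

    kv: float
    ma: float
    rotation_time_s: float
    collimation_mm: float
    start_mm: float
    end_mm: float
    mode: str = "helical"
    pitch: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in SCAN_MODES:
            raise ValidationError(f"mode must be one of {SCAN_MODES}, got {self.mode!r}")
        if self.end_mm <= self.start_mm:
            raise ValidationError("end_mm must exceed start_mm")
        if self.ma < 0 or self.rotation_time_s <= 0 or self.collimation_mm <= 0:
            raise ValidationError("ma must be >= 0; rotation time and collimation > 0")
        if self.mode != "volume_axial" and self.pitch <= 0:
            raise ValidationError("pitch must be > 0")
        if self.mode == "volume_axial" and self.collimation_mm < self.end_mm - self.start_mm:
            raise ValidationError(
                "volume_axial requires collimation_mm >= scan range "
                f"({self.collimation_mm:g} < {self.end_mm - self.start_mm:g})"
            )

    @property
    def mas_per_rotation(self) -> float:
        return self.ma * self.rotation_time_s

    @property
    def scan_length_mm(self) -> float:
        return self.end_mm - self.start_mm


@dataclass(frozen=True)
class OrganDoseResult:
    """Per-organ absorbed doses (mGy) for one phantom and protocol."""

    doses_mGy: dict[str, float]
    protocol: ScanProtocol
    dataset_id: str
    phantom_label: str = "MIRD-5"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.doses_mGy.values()):
            raise ValidationError("organ doses must be nonnegative")

    def scaled(self, k: float) -> "OrganDoseResult":
        return OrganDoseResult(
            doses_mGy={o: k * v for o, v in self.doses_mGy.items()},
            protocol=self.protocol,
            dataset_id=self.dataset_id,
            phantom_label=self.phantom_label,
        )


def _coverage_weights(start_mm: float, end_mm: float, phantom: SlabPhantom) -> np.ndarray:
    """Fractional per-slab coverage of [start, end) clipped to the phantom."""
    t = phantom.slab_thickness_mm
    edges_lo = np.arange(phantom.n_slabs) * t
    edges_hi = edges_lo + t
    overlap = np.minimum(edges_hi, end_mm) - np.maximum(edges_lo, start_mm)
    return np.clip(overlap, 0.0, t) / t


def slabs_covered(protocol: ScanProtocol, phantom: SlabPhantom) -> np.ndarray:
    """Per-slab coverage weight in [0, 1] of the protocol's scan range.

    Weight 1 for fully covered slabs, overlap/thickness for partially
    covered end slabs, 0 elsewhere (half-open [start, end) convention).
    """
    if protocol.end_mm <= 0 or protocol.start_mm >= phantom.extent_mm:
        raise ValidationError(
            f"scan range [{protocol.start_mm:g}, {protocol.end_mm:g}) mm does not "
            f"overlap the phantom extent [0, {phantom.extent_mm:g}) mm"
        )
    return _coverage_weights(protocol.start_mm, protocol.end_mm, phantom)


def _mode_weights(protocol: ScanProtocol, phantom: SlabPhantom) -> tuple[np.ndarray, float]:
    """Coverage weights and effective pitch divisor for the protocol mode."""
    if protocol.mode == "helical":
        return slabs_covered(protocol, phantom), protocol.pitch
    if protocol.mode == "axial_contiguous":
        length = protocol.scan_length_mm
        n_rot = int(np.ceil(length / protocol.collimation_mm - 1e-12))
        if abs(n_rot * protocol.collimation_mm - length) > 1e-9:
            warnings.warn(
                f"scan length {length:g} mm is not a multiple of the {protocol.collimation_mm:g} mm "
                f"collimation; the last of {n_rot} rotations extends past the requested end",
                stacklevel=3,
            )
        w = np.zeros(phantom.n_slabs)
        got_overlap = False
        for i in range(n_rot):
            lo = protocol.start_mm + i * protocol.collimation_mm
            hi = lo + protocol.collimation_mm
            wi = _coverage_weights(lo, hi, phantom)
            got_overlap = got_overlap or wi.any()
            w += wi
        if not got_overlap:
            raise ValidationError("axial coverage does not overlap the phantom")
        return w, 1.0
    # volume_axial: single rotation, beam centred on the requested range
    centre = 0.5 * (protocol.start_mm + protocol.end_mm)
    lo = centre - protocol.collimation_mm / 2.0
    hi = centre + protocol.collimation_mm / 2.0
    w = _coverage_weights(lo, hi, phantom)
    if not w.any():
        raise ValidationError("volume beam window does not overlap the phantom")
    return w, 1.0


def organ_dose(
    dataset: DoseDataset,
    protocol: ScanProtocol,
    scanner: ScannerModel,
) -> OrganDoseResult:
    """Per-organ doses for one acquisition on one reference dataset.

    Requires the dataset kV to equal the protocol kV, and the scanner to
    carry measurements at that kV and the protocol collimation in its
    relative-CTDI table.
    """
    if dataset.kv != protocol.kv:
        raise ValidationError(
            f"dataset is for {dataset.kv:g} kV but protocol requests {protocol.kv:g} kV"
        )
    m = scanner.at_kv(protocol.kv)
    rc = rel_ctdi(scanner.rel_ctdi_table, protocol.collimation_mm)
    w, p_eff = _mode_weights(protocol, dataset.phantom)
    scale = m.ctdi_air * (protocol.mas_per_rotation / 100.0) * rc / p_eff
    doses = dataset.coeff @ w * scale
    return OrganDoseResult(
        doses_mGy={o: float(d) for o, d in zip(dataset.phantom.organ_names, doses)},
        protocol=protocol,
        dataset_id=dataset.dataset_id,
    )


def compare_modes(
    dataset: DoseDataset,
    scanner: ScannerModel,
    start_mm: float,
    end_mm: float,
    axial_collimation_mm: float,
    volume_collimation_mm: float,
    *,
    ma: float = 200.0,
    rotation_time_s: float = 0.5,
) -> dict[str, OrganDoseResult]:
    """Contiguous-axial versus single-wide-axial doses over one range.

    Both acquisitions cover the identical range at the same mAs per
    rotation, so the only difference is the relative CTDI of the two
    collimations.
    """
    if volume_collimation_mm < end_mm - start_mm:
        raise ValidationError("volume collimation must cover the scan range")
    base = dict(
        kv=dataset.kv,
        ma=ma,
        rotation_time_s=rotation_time_s,
        start_mm=start_mm,
        end_mm=end_mm,
    )
    axial = ScanProtocol(
        collimation_mm=axial_collimation_mm, mode="axial_contiguous", **base
    )
    volume = ScanProtocol(
        collimation_mm=volume_collimation_mm, mode="volume_axial", **base
    )
    return {
        "axial_contiguous": organ_dose(dataset, axial, scanner),
        "volume_axial": organ_dose(dataset, volume, scanner),
    }
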