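"""CT dose index (CTDI) metrics.

The CTDI100 is the integral of the single-rotation longitudinal dose
profile D(z) over the central +/-50 mm, divided by the total nominal beam
width N*T clamped at 100 mm::

    CTDI100 = integral_{-50}^{+50} D(z) dz / min(N*T, 100)

where N is the detector row count and T the nominal slice thickness in mm.
For N*T > 100 mm the quantity becomes the average dose over the central
100 mm of a single axial scan rather than the full-profile average, hence
the clamp.

Derived quantities: the weighted CTDI (1/3 centre + 2/3 periphery of a
PMMA phantom), the dose-length product (DLP), and the collimation-dependent
relative CTDI normalised to 1.0 at a reference beam width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseProfile",
    "BeamGeometry",
    "RelCTDITable",
    "compute_ctdi100",
    "compute_ctdiw",
    "compute_dlp",
    "rel_ctdi",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class DoseProfile:
    """Sampled longitudinal dose distribution D(z) along the scanner axis.

    Parameters
    ----------
    z_mm : array-like
        Strictly increasing axial positions in mm.
    dose_mGy : array-like
        Nonnegative dose reading at each position.
    isocenter_mm : float, optional
        Axial position treated as z = 0 for the +/-50 mm integration
        window. Defaults to the mid-span of ``z_mm``; no automatic
        peak-finding is performed.
    description : str
        Free-text provenance note.
    """

    z_mm: np.ndarray
    dose_mGy: np.ndarray
    isocenter_mm: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z_mm, dtype=float)
        d = np.asarray(self.dose_mGy, dtype=float)
        if z.ndim != 1 or d.ndim != 1 or z.shape != d.shape:
            raise ValidationError("z_mm and dose_mGy must be 1-D arrays of equal length")
        if z.size < 2:
            raise ValidationError("a dose profile needs at least 2 samples")
        if not np.all(np.diff(z) > 0):
            raise ValidationError("z_mm must be strictly increasing")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValidationError("dose_mGy must be finite and nonnegative")
        object.__setattr__(self, "z_mm", z)
        object.__setattr__(self, "dose_mGy", d)
        if self.isocenter_mm is None:
            object.__setattr__(self, "isocenter_mm", 0.5 * (z[0] + z[-1]))

    @property
    def span_mm(self) -> tuple[float, float]:
        return float(self.z_mm[0]), float(self.z_mm[-1])


@dataclass(frozen=True)
class BeamGeometry:
    """Beam collimation: N detector rows of nominal slice thickness T (mm)."""

    n_rows: int
    nominal_slice_mm: float

    def __post_init__(self) -> None:
        if self.n_rows < 1:
            raise ValidationError("n_rows must be >= 1")
        if self.nominal_slice_mm <= 0:
            raise ValidationError("nominal_slice_mm must be > 0")

    @property
    def nt_mm(self) -> float:
        """Total nominal beam width N*T in mm."""
        return self.n_rows * self.nominal_slice_mm


@dataclass(frozen=True)
class RelCTDITable:
    """Relative CTDI versus collimation, normalised to 1.0 at a reference width.

    Collimations form a discrete scanner menu; lookups are exact, never
    interpolated.
    """

    collimation_mm: tuple[float, ...]
    rel_ctdi: tuple[float, ...]
    reference_collimation_mm: float

    def __post_init__(self) -> None:
        widths = tuple(float(w) for w in self.collimation_mm)
        factors = tuple(float(f) for f in self.rel_ctdi)
        if len(widths) != len(factors) or not widths:
            raise ValidationError("collimation_mm and rel_ctdi must be non-empty and equal length")
        if any(np.diff(widths) <= 0):
            raise ValidationError("collimation widths must be strictly increasing")
        if any(f <= 0 for f in factors):
            raise ValidationError("all relative CTDI factors must be > 0")
        if self.reference_collimation_mm not in widths:
            raise ValidationError("reference collimation must appear in the table")
        ref = factors[widths.index(self.reference_collimation_mm)]
        if ref != 1.0:
            raise ValidationError(
                f"factor at reference collimation {self.reference_collimation_mm} mm "
                f"must be exactly 1.0, got {ref}"
            )
        object.__setattr__(self, "collimation_mm", widths)
        object.__setattr__(self, "rel_ctdi", factors)


def compute_ctdi100(profile: DoseProfile, geom: BeamGeometry) -> float:
    """CTDI100 in mGy from a sampled dose profile.

    The numerator is the trapezoidal integral of the samples clipped to
    [-50, +50] mm about the profile isocenter, with linear interpolation at
    the window boundaries; the denominator is min(N*T, 100) mm.

    Raises
    ------
    ValidationError
        If the profile does not cover the full +/-50 mm window.
    """
    iso = float(profile.isocenter_mm)
    lo, hi = iso - 50.0, iso + 50.0
    z0, z1 = profile.span_mm
    if z0 > lo or z1 < hi:
        raise ValidationError(
            f"profile spans [{z0:g}, {z1:g}] mm but must cover "
            f"[{lo:g}, {hi:g}] mm (isocenter {iso:g} +/- 50 mm)"
        )
    z = profile.z_mm
    d = profile.dose_mGy
    # clip to the window, adding interpolated boundary samples
    inside = (z > lo) & (z < hi)
    zc = np.concatenate(([lo], z[inside], [hi]))
    dc = np.concatenate(([np.interp(lo, z, d)], d[inside], [np.interp(hi, z, d)]))
    numerator = np.trapezoid(dc, zc)
    return float(numerator / min(geom.nt_mm, 100.0))


def compute_ctdiw(ctdi_c: float, ctdi_p: float) -> float:
    """Weighted CTDI: one third centre plus two thirds periphery (mGy)."""
    if ctdi_c < 0 or ctdi_p < 0:
        raise ValidationError("CTDI inputs must be nonnegative")
    return ctdi_c / 3.0 + 2.0 * ctdi_p / 3.0


def compute_dlp(ctdi_vol: float, scan_length_mm: float) -> float:
    """Dose-length product in mGy*cm (scan length supplied in mm)."""
    if ctdi_vol < 0 or scan_length_mm < 0:
        raise ValidationError("DLP inputs must be nonnegative")
    return ctdi_vol * scan_length_mm / 10.0


def rel_ctdi(table: RelCTDITable, collimation_mm: float) -> float:
    """Tabulated relative CTDI at an exactly listed collimation."""
    w = float(collimation_mm)
    try:
        idx = table.collimation_mm.index(w)
    except ValueError:
        avail = ", ".join(f"{c:g}" for c in table.collimation_mm)
        raise ValidationError(
            f"collimation {w:g} mm not in table; available widths (mm): {avail}"
        ) from None
    return table.rel_ctdi[idx]
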