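"""Seeded synthetic inputs with known ground truth.

Real per-slab Monte Carlo organ-dose datasets and published phantom
conversion factors are third-party data that cannot ship with this
repository.  These generators emulate their structure — localized, smooth
per-organ longitudinal coefficient profiles over a 208 x 5 mm slab grid,
per-kV CTDI measurement sets, collimation menus, conversion-factor tables
for the 13 examination categories, and reference scanner libraries with a
planted best match — so the whole pipeline is exercisable offline.

Every generator is a pure function of its seed: the same seed reproduces
byte-identical outputs.  Dose-dataset manifests (exact organ-dose answers
for a catalogue of protocols) are computed here by straight-line
summation that imports nothing from the dose engine, making them true
independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ctdi import DoseProfile, RelCTDITable, ValidationError
from .conversion import EXAM_CATEGORIES, ConversionTable, ExamCategory
from .engine import DoseDataset, SlabPhantom
from .matching import (
    CTDIMeasurementSet,
    ImpactFactors,
    ReferenceScannerLibrary,
    ScannerModel,
    characterize_scanner,
)

__all__ = [
    "FixtureSpec",
    "DEFAULT_ORGANS",
    "make_dose_profile",
    "make_scanner",
    "make_dose_dataset",
    "make_cf_tables",
    "make_reference_library",
]

# Union of the tissues the dose comparisons report, plus the remainder
# organs an effective-dose map needs; sex-specific organs included so the
# hermaphrodite stylised phantom can carry all of them.
DEFAULT_ORGANS = (
    "brain",
    "salivary_glands",
    "thyroid",
    "oesophagus",
    "lungs",
    "breasts",
    "liver",
    "stomach",
    "adrenals",
    "kidneys",
    "pancreas",
    "spleen",
    "small_intestine",
    "colon",
    "bladder",
    "testes",
    "ovaries",
    "uterus",
    "prostate",
    "heart",
    "thymus",
    "gall_bladder",
    "red_bone_marrow",
    "bone_surface",
    "skin",
    "muscle",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic input bundle."""

    seed: int
    n_organs: int = len(DEFAULT_ORGANS)
    n_slabs: int = 208
    slab_thickness_mm: float = 5.0
    profile_family: str = "gaussian"
    kv_list: tuple[float, ...] = (80.0, 100.0, 120.0, 135.0)

    def __post_init__(self) -> None:
        if self.n_organs < 1 or self.n_slabs < 1:
            raise ValidationError("counts must be >= 1")
        if self.n_organs > len(DEFAULT_ORGANS):
            raise ValidationError(f"at most {len(DEFAULT_ORGANS)} organs available")
        if self.profile_family not in ("gaussian", "box", "mixture"):
            raise ValidationError("profile_family must be gaussian, box, or mixture")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))


# -- dose profiles -----------------------------------------------------------

def _gaussian_window_integral(amp: float, sigma: float, half: float = 50.0) -> float:
    """Closed-form integral of amp*exp(-z^2/2 sigma^2) over [-half, half]."""
    return amp * sigma * math.sqrt(2 * math.pi) * math.erf(half / (sigma * math.sqrt(2)))


def make_dose_profile(
    spec: FixtureSpec,
    *,
    amplitude_mGy: float = 10.0,
    sigma_mm: float = 20.0,
    width_mm: float = 100.0,
) -> tuple[DoseProfile, dict]:
    """A single-rotation longitudinal profile plus its analytic sidecar.

    Samples at 1 mm spacing over [-150, 150] mm.  The sidecar records the
    closed-form integral over the central +/-50 mm and the CTDI100 it
    implies for a menu of total beam widths, so the trapezoidal pipeline
    can be checked against an exact answer.
    """
    z = np.arange(-150.0, 150.0 + 0.5, 1.0)
    fam = spec.profile_family
    if fam == "box":
        d = np.where(np.abs(z) <= width_mm / 2.0, amplitude_mGy, 0.0)
        integral = amplitude_mGy * min(width_mm, 100.0)
    elif fam == "gaussian":
        d = amplitude_mGy * np.exp(-(z**2) / (2 * sigma_mm**2))
        integral = _gaussian_window_integral(amplitude_mGy, sigma_mm)
    else:  # mixture: primary beam plus symmetric scatter tails
        rng = spec.rng(salt=1)
        a2 = amplitude_mGy * rng.uniform(0.05, 0.2)
        s2 = sigma_mm * rng.uniform(2.0, 3.0)
        d = amplitude_mGy * np.exp(-(z**2) / (2 * sigma_mm**2)) + a2 * np.exp(
            -(z**2) / (2 * s2**2)
        )
        integral = _gaussian_window_integral(
            amplitude_mGy, sigma_mm
        ) + _gaussian_window_integral(a2, s2)
    profile = DoseProfile(
        z_mm=z, dose_mGy=d, description=f"synthetic {fam} profile, seed {spec.seed}"
    )
    sidecar = {
        "family": fam,
        "seed": spec.seed,
        "analytic_integral_mGy_mm": integral,
        "ctdi100_by_nt_mm": {
            str(nt): integral / min(nt, 100.0) for nt in (16, 32, 100, 128, 160)
        },
    }
    return profile, sidecar


# -- scanners ----------------------------------------------------------------

def make_scanner(spec: FixtureSpec, name: str = "synthetic-scanner") -> ScannerModel:
    """A plausible scanner: per-kV CTDI sets rising with kV, 2-160 mm menu.

    Head-phantom centre/periphery ratios sit near unity (little
    attenuation in 160 mm PMMA) and body ratios much lower at the centre,
    mirroring real characterisation tables.
    """
    rng = spec.rng(salt=2)
    measurements = []
    for kv in spec.kv_list:
        air = float(rng.uniform(15.0, 30.0) * (kv / 120.0) ** 2.5)
        c_head = air * float(rng.uniform(0.65, 0.85))
        p_head = air * float(rng.uniform(0.70, 0.90))
        c_body = air * float(rng.uniform(0.10, 0.25))
        p_body = air * float(rng.uniform(0.30, 0.50))
        measurements.append(
            CTDIMeasurementSet(
                kv=kv,
                ctdi100_c_head=c_head,
                ctdi100_p_head=p_head,
                ctdi100_c_body=c_body,
                ctdi100_p_body=p_body,
                ctdi_air=air,
            )
        )
    widths = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 160.0)
    factors = []
    for w in widths:
        if w == 16.0:
            factors.append(1.0)
        else:
            # narrow beams waste penumbra (factor > 1), wide beams gain
            factors.append(float(np.round(1.0 + 0.12 * math.log(16.0 / w), 4)))
    table = RelCTDITable(
        collimation_mm=widths, rel_ctdi=tuple(factors), reference_collimation_mm=16.0
    )
    return ScannerModel(name=name, measurements=tuple(measurements), rel_ctdi_table=table)


# -- dose datasets with independent manifests --------------------------------

def _manifest_organ_dose(
    coeff_row: list[float],
    slab_mm: float,
    n_slabs: int,
    start_mm: float,
    end_mm: float,
    mode: str,
    collimation_mm: float,
    pitch: float,
    ctdi_air: float,
    mas_per_rotation: float,
    rel_ctdi_factor: float,
) -> float:
    """Straight-line oracle for one organ dose; no engine imports.

    Plain Python loops over slabs and (for axial mode) rotations,
    accumulating overlap fractions directly from interval arithmetic.
    """
    def window_weight(lo: float, hi: float, s: int) -> float:
        slab_lo = s * slab_mm
        slab_hi = slab_lo + slab_mm
        ov = min(hi, slab_hi) - max(lo, slab_lo)
        return max(0.0, min(ov, slab_mm)) / slab_mm

    total = 0.0
    if mode == "helical":
        for s in range(n_slabs):
            total += coeff_row[s] * window_weight(start_mm, end_mm, s)
        total /= pitch
    elif mode == "axial_contiguous":
        n_rot = math.ceil((end_mm - start_mm) / collimation_mm - 1e-12)
        for i in range(n_rot):
            lo = start_mm + i * collimation_mm
            for s in range(n_slabs):
                total += coeff_row[s] * window_weight(lo, lo + collimation_mm, s)
    else:  # volume_axial
        centre = (start_mm + end_mm) / 2.0
        lo = centre - collimation_mm / 2.0
        for s in range(n_slabs):
            total += coeff_row[s] * window_weight(lo, lo + collimation_mm, s)
    return ctdi_air * (mas_per_rotation / 100.0) * rel_ctdi_factor * total


def make_dose_dataset(
    spec: FixtureSpec,
    scanner: ScannerModel | None = None,
    kv: float = 120.0,
) -> tuple[DoseDataset, dict]:
    """A per-slab coefficient matrix plus a manifest of exact answers.

    Each organ gets a smooth Gaussian longitudinal profile centred at a
    distinct slab, truncated to finite support (4 sigma), with peak
    coefficient of order 1 — emulating the normalisation of organ dose
    per unit free-in-air CTDI.  The manifest catalogues organ doses for a
    set of protocols, computed by :func:`_manifest_organ_dose`.
    """
    rng = spec.rng(salt=3)
    organs = DEFAULT_ORGANS[: spec.n_organs]
    phantom = SlabPhantom(
        organ_names=organs,
        n_slabs=spec.n_slabs,
        slab_thickness_mm=spec.slab_thickness_mm,
    )
    centres = rng.choice(spec.n_slabs, size=len(organs), replace=spec.n_slabs < len(organs))
    coeff = np.zeros((len(organs), spec.n_slabs))
    slabs = np.arange(spec.n_slabs)
    for i, c in enumerate(centres):
        sigma = float(rng.uniform(2.0, 8.0))
        amp = float(rng.uniform(0.3, 1.5))
        prof = amp * np.exp(-((slabs - c) ** 2) / (2 * sigma**2))
        prof[np.abs(slabs - c) > 4 * sigma] = 0.0
        coeff[i] = prof
    dataset = DoseDataset(
        phantom=phantom, coeff=coeff, kv=kv, dataset_id=f"synthetic-{spec.seed}"
    )

    manifest: dict = {"seed": spec.seed, "dataset_id": dataset.dataset_id, "protocols": []}
    if scanner is not None:
        m = scanner.at_kv(kv)
        extent = phantom.extent_mm
        protos = [
            dict(mode="helical", collimation_mm=32.0, pitch=1.0,
                 start_mm=0.0, end_mm=min(160.0, extent)),
            dict(mode="helical", collimation_mm=32.0, pitch=2.0,
                 start_mm=0.0, end_mm=min(160.0, extent)),
            dict(mode="axial_contiguous", collimation_mm=32.0, pitch=1.0,
                 start_mm=0.0, end_mm=min(160.0, extent)),
            dict(mode="volume_axial", collimation_mm=160.0, pitch=1.0,
                 start_mm=0.0, end_mm=min(160.0, extent)),
            dict(mode="helical", collimation_mm=16.0, pitch=1.0,
                 start_mm=0.0, end_mm=extent),
        ]
        for p in protos:
            widths = scanner.rel_ctdi_table.collimation_mm
            rc = scanner.rel_ctdi_table.rel_ctdi[widths.index(p["collimation_mm"])]
            doses = {
                organ: _manifest_organ_dose(
                    coeff[i].tolist(),
                    spec.slab_thickness_mm,
                    spec.n_slabs,
                    p["start_mm"],
                    p["end_mm"],
                    p["mode"],
                    p["collimation_mm"],
                    p["pitch"],
                    m.ctdi_air,
                    100.0,  # catalogue protocols use 200 mA x 0.5 s
                    rc,
                )
                for i, organ in enumerate(organs)
            }
            manifest["protocols"].append(
                {**p, "kv": kv, "ma": 200.0, "rotation_time_s": 0.5, "doses_mGy": doses}
            )
    return dataset, manifest


# -- conversion-factor tables ------------------------------------------------

FEMALE_ONLY_ORGANS = ("ovaries", "uterus")
MALE_ONLY_ORGANS = ("testes", "prostate")


def make_cf_tables(
    spec: FixtureSpec, organs: tuple[str, ...] | None = None
) -> dict[tuple[str, str], ConversionTable]:
    """Random conversion tables for all 13 categories and both sexes.

    Factors are drawn uniformly in [0.3, 2.0].  Male tables omit
    female-only organs and vice versa; identity tables (sex ``none``) are
    included under each category for stylised-phantom passthrough.
    """
    rng = spec.rng(salt=4)
    organs = DEFAULT_ORGANS[: spec.n_organs] if organs is None else tuple(organs)
    tables: dict[tuple[str, str], ConversionTable] = {}
    for cat in EXAM_CATEGORIES:
        for sex in ("male", "female"):
            omit = FEMALE_ONLY_ORGANS if sex == "male" else MALE_ONLY_ORGANS
            cf = {
                o: float(np.round(rng.uniform(0.3, 2.0), 4))
                for o in organs
                if o not in omit
            }
            tables[(cat, sex)] = ConversionTable(
                category=ExamCategory(name=cat, sex=sex), cf=cf
            )
        tables[(cat, "none")] = ConversionTable(
            category=ExamCategory(name=cat, sex="none"), cf={o: 1.0 for o in organs}
        )
    return tables


# -- reference libraries -----------------------------------------------------

def make_reference_library(
    spec: FixtureSpec,
    target: ScannerModel,
    kv: float = 120.0,
    n_entries: int = 10,
) -> tuple[ReferenceScannerLibrary, str]:
    """A library with one planted near-exact match for the target scanner.

    The planted entry's factors lie within 1% (relative) of the target's;
    every decoy is at least 5% away in one factor, so the planted entry
    wins by construction.  Returns the library and the planted
    dataset_id.
    """
    if n_entries < 1:
        raise ValidationError("library needs at least one entry")
    rng = spec.rng(salt=5)
    tf: ImpactFactors = next(
        f for f in characterize_scanner(target) if f.kv == kv
    )
    planted_id = f"ds-planted-{spec.seed}"
    entries = [
        (
            "ref-planted",
            kv,
            tf.imf_head * float(1 + rng.uniform(-0.01, 0.01)),
            tf.imf_body * float(1 + rng.uniform(-0.01, 0.01)),
            planted_id,
        )
    ]
    for i in range(n_entries - 1):
        # push each decoy at least 5% off in both factors
        dh = float(rng.uniform(0.05, 0.6)) * float(rng.choice([-1, 1]))
        db = float(rng.uniform(0.05, 0.6)) * float(rng.choice([-1, 1]))
        entries.append(
            (
                f"ref-decoy-{i}",
                kv,
                tf.imf_head * (1 + dh),
                tf.imf_body * (1 + db),
                f"ds-decoy-{i}",
            )
        )
    perm = rng.permutation(len(entries))
    shuffled = tuple(entries[int(j)] for j in perm)
    return ReferenceScannerLibrary(entries=shuffled), planted_id
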