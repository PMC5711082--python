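"""Equivalent and effective dose under ICRP 103 tissue weighting.

Organ doses D_T (mGy) become equivalent doses via the radiation weighting
factor, H_T = D_T * w_R (w_R = 1 for photons, so the values relabel
mGy -> mSv), and aggregate to effective dose:

    ED = sum_T w_T * H_T            (mSv)

with the ICRP 103 tissue weights.  The remainder tissues share a single
weight applied to the arithmetic mean of the remainder-tissue equivalent
doses; remainder tissues absent from the dose map are excluded from the
mean (with a warning) rather than counted as zeros, because stylised-
phantom datasets do not score every ICRP 103 remainder tissue and zeros
would bias ED downward silently.

Effective dose is defined for a sex-averaged reference person:
tissue-wise equivalent doses of the male and female phantoms are
averaged, with the sex-specific gonads (testes / ovaries) each entering
the gonad average at half weight.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

from .ctdi import ValidationError
from .conversion import ConversionTable, apply_cf
from .engine import DoseDataset, OrganDoseResult, ScanProtocol, organ_dose
from .matching import ScannerModel

__all__ = [
    "RadiationWeighting",
    "TissueWeightingScheme",
    "EffectiveDoseResult",
    "PHOTONS",
    "load_builtin_scheme",
    "map_organs_to_tissues",
    "equivalent_dose",
    "effective_dose",
    "sex_averaged_ed",
    "full_pipeline",
]


@dataclass(frozen=True)
class RadiationWeighting:
    """Radiation weighting factor w_R (1.0 for photons)."""

    w_r: float = 1.0

    def __post_init__(self) -> None:
        if self.w_r <= 0:
            raise ValidationError("w_r must be > 0")


PHOTONS = RadiationWeighting(w_r=1.0)


@dataclass(frozen=True)
class TissueWeightingScheme:
    """Named tissue weights plus a shared remainder weight.

    ``weights`` maps tissue -> w_T and may include the key ``"remainder"``
    whose weight is applied once to the mean equivalent dose of the
    ``remainder_tissues``.  Weights must be positive and sum to 1 (the
    remainder weight counted once).
    """

    name: str
    weights: dict[str, float]
    remainder_tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError("weighting scheme needs at least one tissue")
        if any(w <= 0 for w in self.weights.values()):
            raise ValidationError("all tissue weights must be > 0")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"tissue weights must sum to 1 (remainder counted once); got {total!r}"
            )
        if "remainder" in self.weights and not self.remainder_tissues:
            raise ValidationError("a remainder weight requires a remainder tissue list")
        object.__setattr__(self, "remainder_tissues", tuple(self.remainder_tissues))

    @property
    def named_tissues(self) -> tuple[str, ...]:
        return tuple(t for t in self.weights if t != "remainder")

    @property
    def all_tissues(self) -> tuple[str, ...]:
        return self.named_tissues + self.remainder_tissues


@dataclass(frozen=True)
class EffectiveDoseResult:
    """Per-tissue equivalent doses and the aggregated effective dose (mSv)."""

    h_t: dict[str, float]
    ed: float
    sex: str
    scheme_name: str

    def __post_init__(self) -> None:
        if self.ed < 0:
            raise ValidationError("effective dose must be nonnegative")


def load_builtin_scheme(name: str = "icrp103") -> TissueWeightingScheme:
    """Load a built-in tissue weighting scheme (currently only ``icrp103``).

    The sum-to-one invariant is validated on construction; an ICRP 60
    slot exists in the API but ships no data.
    """
    if name != "icrp103":
        raise ValidationError(f"no built-in scheme named {name!r} (available: icrp103)")
    raw = json.loads(
        resources.files("ctdose.data").joinpath(f"{name}.json").read_text()
    )
    return TissueWeightingScheme(
        name=raw["name"],
        weights=dict(raw["weights"]),
        remainder_tissues=tuple(raw["remainder"]),
    )


# Organ vocabulary of slab datasets -> ICRP 103 tissue names.  Sex-specific
# gonads both resolve to "gonads"; uterus scores the uterus-cervix
# remainder tissue.
DEFAULT_ORGAN_TISSUE_MAP = {
    "red_bone_marrow": "bone-marrow",
    "bone_marrow": "bone-marrow",
    "colon": "colon",
    "lung": "lung",
    "lungs": "lung",
    "stomach": "stomach",
    "breasts": "breast",
    "breast": "breast",
    "testes": "gonads",
    "ovaries": "gonads",
    "bladder": "bladder",
    "oesophagus": "oesophagus",
    "esophagus": "oesophagus",
    "liver": "liver",
    "thyroid": "thyroid",
    "bone_surface": "bone-surface",
    "brain": "brain",
    "salivary_glands": "salivary-glands",
    "skin": "skin",
    "adrenals": "adrenals",
    "gall_bladder": "gall-bladder",
    "heart": "heart",
    "kidneys": "kidneys",
    "muscle": "muscle",
    "pancreas": "pancreas",
    "prostate": "prostate",
    "small_intestine": "small-intestine",
    "spleen": "spleen",
    "thymus": "thymus",
    "uterus": "uterus-cervix",
}


def map_organs_to_tissues(
    doses: dict[str, float],
    mapping: dict[str, str] | None = None,
) -> dict[str, float]:
    """Rekey an organ dose map to scheme tissue names.

    Organs with no mapping are dropped with a warning.  If two organs map
    to the same tissue (testes and ovaries both to gonads, in a
    hermaphrodite map) their doses are averaged.
    """
    mapping = DEFAULT_ORGAN_TISSUE_MAP if mapping is None else mapping
    acc: dict[str, list[float]] = {}
    unmapped = []
    for organ, d in doses.items():
        tissue = mapping.get(organ)
        if tissue is None:
            unmapped.append(organ)
            continue
        acc.setdefault(tissue, []).append(d)
    if unmapped:
        warnings.warn(
            "organs with no tissue mapping ignored: " + ", ".join(sorted(unmapped)),
            stacklevel=2,
        )
    return {t: sum(v) / len(v) for t, v in acc.items()}


def equivalent_dose(
    d_t: dict[str, float],
    w: RadiationWeighting = PHOTONS,
) -> dict[str, float]:
    """Equivalent doses H_T = D_T * w_R, in mSv."""
    if any(v < 0 for v in d_t.values()):
        raise ValidationError("organ doses must be nonnegative")
    return {o: v * w.w_r for o, v in d_t.items()}


def effective_dose(h_t: dict[str, float], scheme: TissueWeightingScheme) -> float:
    """Effective dose in mSv: weighted sum of tissue equivalent doses.

    Named scheme tissues missing from ``h_t`` contribute 0 with a
    warning; the remainder contribution is the remainder weight times the
    arithmetic mean of the remainder tissues that are present.
    """
    missing = [t for t in scheme.named_tissues if t not in h_t]
    if missing:
        warnings.warn(
            "scheme tissues absent from dose map contribute zero: "
            + ", ".join(missing),
            stacklevel=2,
        )
    ed = sum(
        w * h_t.get(t, 0.0) for t, w in scheme.weights.items() if t != "remainder"
    )
    if "remainder" in scheme.weights:
        present = [h_t[t] for t in scheme.remainder_tissues if t in h_t]
        absent = [t for t in scheme.remainder_tissues if t not in h_t]
        if absent:
            warnings.warn(
                "remainder tissues absent from dose map excluded from the mean: "
                + ", ".join(absent),
                stacklevel=2,
            )
        if present:
            ed += scheme.weights["remainder"] * (sum(present) / len(present))
    return float(ed)


def _ed_result(
    h_t: dict[str, float], scheme: TissueWeightingScheme, sex: str
) -> EffectiveDoseResult:
    return EffectiveDoseResult(
        h_t=dict(h_t),
        ed=effective_dose(h_t, scheme),
        sex=sex,
        scheme_name=scheme.name,
    )


def sex_averaged_ed(
    male: EffectiveDoseResult,
    female: EffectiveDoseResult,
    scheme: TissueWeightingScheme | None = None,
) -> EffectiveDoseResult:
    """Reference-person result: tissue-wise average of male and female.

    Tissues present in both sexes average normally; tissues present in
    one sex only (testes or ovaries within the gonad entry, prostate,
    uterus-cervix) enter at half weight, i.e. their single-sex value is
    halved.  ED is recomputed from the averaged map.
    """
    if male.scheme_name != female.scheme_name:
        raise ValidationError(
            f"cannot average results from different schemes "
            f"({male.scheme_name!r} vs {female.scheme_name!r})"
        )
    if scheme is None:
        scheme = load_builtin_scheme(male.scheme_name)
    elif scheme.name != male.scheme_name:
        raise ValidationError("supplied scheme does not match the results' scheme name")
    tissues = set(male.h_t) | set(female.h_t)
    h_avg = {
        t: (male.h_t.get(t, 0.0) + female.h_t.get(t, 0.0)) / 2.0 for t in tissues
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _ed_result(h_avg, scheme, sex="averaged")


@dataclass(frozen=True)
class DoseReport:
    """Full pipeline output: organ doses per phantom plus effective doses."""

    mird: OrganDoseResult
    icrp_male: OrganDoseResult
    icrp_female: OrganDoseResult
    ed_male: EffectiveDoseResult
    ed_female: EffectiveDoseResult
    ed_averaged: EffectiveDoseResult

    def to_dict(self) -> dict:
        p = self.mird.protocol
        return {
            "protocol": {
                "kv": p.kv,
                "ma": p.ma,
                "rotation_time_s": p.rotation_time_s,
                "collimation_mm": p.collimation_mm,
                "pitch": p.pitch,
                "start_mm": p.start_mm,
                "end_mm": p.end_mm,
                "mode": p.mode,
            },
            "dataset_id": self.mird.dataset_id,
            "organ_doses_mGy": {
                "MIRD-5": self.mird.doses_mGy,
                "ICRP110-male": self.icrp_male.doses_mGy,
                "ICRP110-female": self.icrp_female.doses_mGy,
            },
            "equivalent_doses_mSv": {
                "male": self.ed_male.h_t,
                "female": self.ed_female.h_t,
                "averaged": self.ed_averaged.h_t,
            },
            "effective_dose_mSv": {
                "male": self.ed_male.ed,
                "female": self.ed_female.ed,
                "averaged": self.ed_averaged.ed,
            },
            "scheme": self.ed_male.scheme_name,
        }


def full_pipeline(
    scanner: ScannerModel,
    dataset: DoseDataset,
    protocol: ScanProtocol,
    cf_table_male: ConversionTable,
    cf_table_female: ConversionTable,
    scheme: TissueWeightingScheme,
    *,
    organ_tissue_map: dict[str, str] | None = None,
) -> DoseReport:
    """Deterministic composition of the whole dose chain.

    organ_dose -> apply_cf (per sex) -> equivalent_dose -> effective_dose
    -> sex averaging.  Warnings about uncovered organs and absent
    remainder tissues are suppressed here (the per-stage functions still
    emit them when called directly).
    """
    mird = organ_dose(dataset, protocol, scanner)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        male = apply_cf(mird, cf_table_male)
        female = apply_cf(mird, cf_table_female)
        ed_m = _ed_result(
            map_organs_to_tissues(equivalent_dose(male.doses_mGy), organ_tissue_map),
            scheme,
            sex="male",
        )
        ed_f = _ed_result(
            map_organs_to_tissues(equivalent_dose(female.doses_mGy), organ_tissue_map),
            scheme,
            sex="female",
        )
    return DoseReport(
        mird=mird,
        icrp_male=male,
        icrp_female=female,
        ed_male=ed_m,
        ed_female=ed_f,
        ed_averaged=sex_averaged_ed(ed_m, ed_f, scheme),
    )
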