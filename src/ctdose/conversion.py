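"""Stylised-to-voxel phantom dose conversion.

The stylised MIRD-5 phantom is a partially hermaphrodite adult; the
voxelised ICRP Publication 110 reference phantoms are separate male and
female anatomies.  Per-organ conversion factors bridge the two:

    CF[o] = D_o(ICRP 110) / D_o(MIRD-5)

derived once per examination category (13 categories, e.g. chest,
abdomen-pelvis, head) and sex, and applied multiplicatively:

    D_o(ICRP 110) = D_o(MIRD-5) * CF[o]

Organs present in a MIRD-5 result but missing from the conversion table
are dropped from the converted result with a warning — a missing CF means
the voxel-phantom dose is undefined for that category, and passing the
stylised dose through unchanged would silently mix phantoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .ctdi import ValidationError
from .engine import OrganDoseResult

__all__ = [
    "EXAM_CATEGORIES",
    "ExamCategory",
    "ConversionTable",
    "select_category",
    "derive_cf",
    "apply_cf",
]

EXAM_CATEGORIES = (
    "chest-abdomen-pelvis",
    "chest",
    "abdomen-pelvis",
    "abdomen",
    "pelvis",
    "adrenals",
    "liver",
    "kidneys",
    "liver-kidneys",
    "kidneys-bladder",
    "head",
    "neck",
    "head-neck",
)

SEXES = ("male", "female", "none")


@dataclass(frozen=True)
class ExamCategory:
    """One of the 13 examination categories, with target-phantom sex.

    ``sex="none"`` designates MIRD-5 passthrough (identity conversion).
    """

    name: str
    sex: str

    def __post_init__(self) -> None:
        if self.name not in EXAM_CATEGORIES:
            raise ValidationError(
                f"unknown category {self.name!r}; valid: {', '.join(EXAM_CATEGORIES)}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass(frozen=True)
class ConversionTable:
    """Per-organ conversion factors for one category and sex."""

    category: ExamCategory
    cf: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.cf.values()):
            raise ValidationError("all conversion factors must be > 0")


def identity_table(organs, sex: str = "none", category: str = "head") -> ConversionTable:
    """All-ones table: MIRD-5 passthrough for the given organ list."""
    return ConversionTable(
        category=ExamCategory(name=category, sex=sex),
        cf={o: 1.0 for o in organs},
    )


def select_category(name: str, sex: str = "none") -> ExamCategory:
    """Canonicalise a category name (case-insensitive, space/hyphen tolerant)."""
    canon = name.strip().lower().replace("_", "-").replace(" ", "-")
    while "--" in canon:
        canon = canon.replace("--", "-")
    if canon not in EXAM_CATEGORIES:
        raise ValidationError(
            f"unknown examination category {name!r}; valid names: "
            + ", ".join(EXAM_CATEGORIES)
        )
    return ExamCategory(name=canon, sex=sex.strip().lower())


def derive_cf(
    icrp_doses: dict[str, float],
    mird_doses: dict[str, float],
    category: ExamCategory | None = None,
) -> ConversionTable:
    """Conversion factors as per-organ voxel/stylised dose ratios.

    Organs absent from either map are omitted with a warning; a zero
    stylised dose for a shared organ is an error (the ratio is undefined).
    """
    if category is None:
        category = ExamCategory(name="head", sex="none")
    shared = [o for o in mird_doses if o in icrp_doses]
    dropped = sorted(set(icrp_doses) ^ set(mird_doses))
    if dropped:
        warnings.warn(
            "organs present in only one dose map omitted from CF table: "
            + ", ".join(dropped),
            stacklevel=2,
        )
    cf = {}
    for o in shared:
        if mird_doses[o] == 0:
            raise ValidationError(
                f"stylised-phantom dose for {o!r} is zero; conversion factor undefined"
            )
        cf[o] = icrp_doses[o] / mird_doses[o]
    return ConversionTable(category=category, cf=cf)


def apply_cf(mird_result: OrganDoseResult, table: ConversionTable) -> OrganDoseResult:
    """Convert a stylised-phantom result to the voxel reference phantom.

    Organs not covered by the table are dropped with a warning; the
    resulting phantom label records the target sex.
    """
    uncovered = sorted(o for o in mird_result.doses_mGy if o not in table.cf)
    if uncovered:
        warnings.warn(
            "organs without a conversion factor dropped from converted result: "
            + ", ".join(uncovered),
            stacklevel=2,
        )
    doses = {
        o: d * table.cf[o]
        for o, d in mird_result.doses_mGy.items()
        if o in table.cf
    }
    if table.category.sex == "none":
        label = "MIRD-5"
    else:
        label = f"ICRP110-{table.category.sex}"
    return OrganDoseResult(
        doses_mGy=doses,
        protocol=mird_result.protocol,
        dataset_id=mird_result.dataset_id,
        phantom_label=label,
    )
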