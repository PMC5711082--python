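"""Readers and writers for the plain-text interchange formats.

All tables are CSV with headers (pandas round-trips them); structured
inputs (scanners, schemes, reports) are JSON.  Formats:

* dose profile:        ``z_mm,dose_mGy``
* relative CTDI:       ``collimation_mm,rel_ctdi`` (reference row = 1.0)
* reference library:   ``name,kv,imf_head,imf_body,dataset_id``
* dose dataset:        long form ``organ,slab_index,coefficient`` plus a
  JSON sidecar ``{dataset_id, kv, n_slabs, slab_thickness_mm}``
* conversion factors:  ``category,sex,organ,cf``
* scanner:             JSON ``{name, measurements: [...], rel_ctdi: {...}}``
* weighting scheme:    JSON ``{name, weights, remainder}``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ctdi import DoseProfile, RelCTDITable, ValidationError
from .conversion import ConversionTable, select_category
from .engine import DoseDataset, SlabPhantom
from .matching import CTDIMeasurementSet, ReferenceScannerLibrary, ScannerModel
from .effective import DoseReport, TissueWeightingScheme

__all__ = [
    "read_dose_profile",
    "write_dose_profile",
    "read_rel_ctdi_table",
    "write_rel_ctdi_table",
    "read_scanner",
    "write_scanner",
    "read_reference_library",
    "write_reference_library",
    "read_dose_dataset",
    "write_dose_dataset",
    "read_cf_tables",
    "write_cf_tables",
    "read_scheme",
    "write_report",
]


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} is missing columns: {', '.join(missing)}")


def read_dose_profile(path: str | Path) -> DoseProfile:
    df = pd.read_csv(path)
    _require_columns(df, ("z_mm", "dose_mGy"), "dose profile CSV")
    return DoseProfile(
        z_mm=df["z_mm"].to_numpy(float),
        dose_mGy=df["dose_mGy"].to_numpy(float),
        description=str(path),
    )


def write_dose_profile(profile: DoseProfile, path: str | Path) -> None:
    pd.DataFrame({"z_mm": profile.z_mm, "dose_mGy": profile.dose_mGy}).to_csv(
        path, index=False
    )


def read_rel_ctdi_table(path: str | Path) -> RelCTDITable:
    df = pd.read_csv(path).sort_values("collimation_mm")
    _require_columns(df, ("collimation_mm", "rel_ctdi"), "relative CTDI CSV")
    widths = tuple(df["collimation_mm"].astype(float))
    factors = tuple(df["rel_ctdi"].astype(float))
    refs = [w for w, f in zip(widths, factors) if f == 1.0]
    if not refs:
        raise ValidationError("relative CTDI table must contain a reference row with value 1.0")
    return RelCTDITable(
        collimation_mm=widths, rel_ctdi=factors, reference_collimation_mm=refs[0]
    )


def write_rel_ctdi_table(table: RelCTDITable, path: str | Path) -> None:
    pd.DataFrame(
        {"collimation_mm": table.collimation_mm, "rel_ctdi": table.rel_ctdi}
    ).to_csv(path, index=False)


def read_scanner(path: str | Path) -> ScannerModel:
    raw = json.loads(Path(path).read_text())
    measurements = tuple(
        CTDIMeasurementSet(
            kv=float(m["kv"]),
            ctdi100_c_head=float(m["head"]["c"]),
            ctdi100_p_head=float(m["head"]["p"]),
            ctdi100_c_body=float(m["body"]["c"]),
            ctdi100_p_body=float(m["body"]["p"]),
            ctdi_air=float(m["air"]),
        )
        for m in raw["measurements"]
    )
    rel = raw["rel_ctdi"]
    table = RelCTDITable(
        collimation_mm=tuple(float(w) for w in rel["collimation_mm"]),
        rel_ctdi=tuple(float(f) for f in rel["rel_ctdi"]),
        reference_collimation_mm=float(rel["reference_collimation_mm"]),
    )
    return ScannerModel(name=raw["name"], measurements=measurements, rel_ctdi_table=table)


def write_scanner(scanner: ScannerModel, path: str | Path) -> None:
    raw = {
        "name": scanner.name,
        "measurements": [
            {
                "kv": m.kv,
                "head": {"c": m.ctdi100_c_head, "p": m.ctdi100_p_head},
                "body": {"c": m.ctdi100_c_body, "p": m.ctdi100_p_body},
                "air": m.ctdi_air,
            }
            for m in scanner.measurements
        ],
        "rel_ctdi": {
            "collimation_mm": list(scanner.rel_ctdi_table.collimation_mm),
            "rel_ctdi": list(scanner.rel_ctdi_table.rel_ctdi),
            "reference_collimation_mm": scanner.rel_ctdi_table.reference_collimation_mm,
        },
    }
    Path(path).write_text(json.dumps(raw, indent=2) + "\n")


def read_reference_library(path: str | Path) -> ReferenceScannerLibrary:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ("name", "kv", "imf_head", "imf_body", "dataset_id"), "library CSV")
    entries = tuple(
        (str(r["name"]), float(r["kv"]), float(r["imf_head"]), float(r["imf_body"]),
         str(r["dataset_id"]))
        for _, r in df.iterrows()
    )
    return ReferenceScannerLibrary(entries=entries)


def write_reference_library(library: ReferenceScannerLibrary, path: str | Path) -> None:
    pd.DataFrame(
        library.entries, columns=["name", "kv", "imf_head", "imf_body", "dataset_id"]
    ).to_csv(path, index=False, float_format="%.17g")


def read_dose_dataset(csv_path: str | Path, sidecar_path: str | Path | None = None) -> DoseDataset:
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    df = pd.read_csv(csv_path)
    _require_columns(df, ("organ", "slab_index", "coefficient"), "dose dataset CSV")
    organs = tuple(dict.fromkeys(df["organ"]))  # preserve first-appearance order
    phantom = SlabPhantom(
        organ_names=organs,
        n_slabs=int(meta["n_slabs"]),
        slab_thickness_mm=float(meta["slab_thickness_mm"]),
    )
    coeff = np.zeros((len(organs), phantom.n_slabs))
    idx = {o: i for i, o in enumerate(organs)}
    for _, r in df.iterrows():
        coeff[idx[r["organ"]], int(r["slab_index"])] = float(r["coefficient"])
    return DoseDataset(
        phantom=phantom, coeff=coeff, kv=float(meta["kv"]), dataset_id=str(meta["dataset_id"])
    )


def write_dose_dataset(dataset: DoseDataset, csv_path: str | Path) -> None:
    """Long-form CSV (nonzero coefficients only) plus the JSON sidecar."""
    csv_path = Path(csv_path)
    rows = []
    for i, organ in enumerate(dataset.phantom.organ_names):
        (nz,) = np.nonzero(dataset.coeff[i])
        if nz.size == 0:
            rows.append({"organ": organ, "slab_index": 0, "coefficient": 0.0})
        for s in nz:
            rows.append(
                {"organ": organ, "slab_index": int(s), "coefficient": dataset.coeff[i, s]}
            )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    meta = {
        "dataset_id": dataset.dataset_id,
        "kv": dataset.kv,
        "n_slabs": dataset.phantom.n_slabs,
        "slab_thickness_mm": dataset.phantom.slab_thickness_mm,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def read_cf_tables(path: str | Path) -> dict[tuple[str, str], ConversionTable]:
    """All conversion tables in one CSV, keyed by (category, sex)."""
    df = pd.read_csv(path)
    _require_columns(df, ("category", "sex", "organ", "cf"), "conversion factor CSV")
    tables: dict[tuple[str, str], ConversionTable] = {}
    for (cat, sex), grp in df.groupby(["category", "sex"], sort=False):
        category = select_category(str(cat), str(sex))
        cf = dict(zip(grp["organ"].astype(str), grp["cf"].astype(float)))
        tables[(category.name, category.sex)] = ConversionTable(category=category, cf=cf)
    return tables


def write_cf_tables(
    tables: dict[tuple[str, str], ConversionTable], path: str | Path
) -> None:
    rows = [
        {"category": t.category.name, "sex": t.category.sex, "organ": o, "cf": v}
        for t in tables.values()
        for o, v in t.cf.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scheme(path: str | Path) -> TissueWeightingScheme:
    raw = json.loads(Path(path).read_text())
    return TissueWeightingScheme(
        name=raw["name"],
        weights=dict(raw["weights"]),
        remainder_tissues=tuple(raw.get("remainder", ())),
    )


def write_report(report: DoseReport, json_path: str | Path, csv_path: str | Path | None = None) -> None:
    """JSON summary, optionally with a per-organ CSV alongside."""
    d = report.to_dict()
    Path(json_path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    if csv_path is not None:
        organs = sorted(report.mird.doses_mGy)
        rows = [
            {
                "organ": o,
                "D_mird_mGy": report.mird.doses_mGy.get(o),
                "D_icrp_male_mGy": report.icrp_male.doses_mGy.get(o),
                "D_icrp_female_mGy": report.icrp_female.doses_mGy.get(o),
            }
            for o in organs
        ]
        pd.DataFrame(rows).to_csv(csv_path, index=False)
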