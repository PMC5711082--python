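"""Scanner characterisation and matching via ImPACT factors.

A new scanner is characterised, per tube voltage, by two dimensionless
linear combinations of its CTDI100 centre/periphery measurements
normalised by the free-in-air CTDI:

    ImF_head = 0.4738 * (CTDI100,c / CTDIair) + 0.8045 * (CTDI100,p / CTDIair) + 0.0752
    ImF_body = 3.5842 * (CTDI100,c / CTDIair) + 0.6328 * (CTDI100,p / CTDIair) - 0.0902

using head-phantom (160 mm PMMA) measurements for the head factor and
body-phantom (320 mm PMMA) measurements for the body factor.  The pair is
then compared against a library of reference scanners that carry Monte
Carlo organ-dose datasets, and the closest library entry is selected.

The published worksheet does not document its matching rule; here the
match score is the sum of relative absolute differences of the head and
body factors, equally weighted, isolated in :func:`match_scanner` so it
can be swapped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .ctdi import RelCTDITable, ValidationError

__all__ = [
    "IMF_HEAD_COEFFS",
    "IMF_BODY_COEFFS",
    "CTDIMeasurementSet",
    "ScannerModel",
    "ImpactFactors",
    "ReferenceScannerLibrary",
    "impact_factor_head",
    "impact_factor_body",
    "characterize_scanner",
    "match_scanner",
]

# (centre-ratio slope, periphery-ratio slope, intercept)
IMF_HEAD_COEFFS = (0.4738, 0.8045, 0.0752)
IMF_BODY_COEFFS = (3.5842, 0.6328, -0.0902)


@dataclass(frozen=True)
class CTDIMeasurementSet:
    """Per-kV CTDI characterisation, all in mGy per 100 mAs.

    ``ctdi100_c_head`` / ``ctdi100_p_head`` are centre / mean-periphery
    values in the 160 mm PMMA head phantom, the ``_body`` pair in the
    320 mm body phantom, and ``ctdi_air`` is measured free in air.
    """

    kv: float
    ctdi100_c_head: float
    ctdi100_p_head: float
    ctdi100_c_body: float
    ctdi100_p_body: float
    ctdi_air: float

    def __post_init__(self) -> None:
        vals = (
            self.ctdi100_c_head,
            self.ctdi100_p_head,
            self.ctdi100_c_body,
            self.ctdi100_p_body,
            self.ctdi_air,
        )
        if any(v <= 0 for v in vals):
            raise ValidationError("all CTDI measurements must be > 0")
        if self.ctdi_air < self.ctdi100_c_body:
            raise ValidationError(
                "free-in-air CTDI must be >= body-phantom centre CTDI "
                f"(got air {self.ctdi_air} < centre {self.ctdi100_c_body})"
            )


@dataclass(frozen=True)
class ScannerModel:
    """A scanner: name, per-kV CTDI measurements, and its Rel. CTDI table."""

    name: str
    measurements: tuple[CTDIMeasurementSet, ...]
    rel_ctdi_table: RelCTDITable

    def __post_init__(self) -> None:
        ms = tuple(self.measurements)
        if not ms:
            raise ValidationError("scanner needs at least one kV measurement set")
        kvs = [m.kv for m in ms]
        if len(set(kvs)) != len(kvs):
            raise ValidationError("kV values must be unique")
        object.__setattr__(self, "measurements", ms)

    def at_kv(self, kv: float) -> CTDIMeasurementSet:
        for m in self.measurements:
            if m.kv == kv:
                return m
        avail = ", ".join(f"{m.kv:g}" for m in self.measurements)
        raise ValidationError(f"scanner {self.name!r} has no measurements at {kv:g} kV; available: {avail}")


@dataclass(frozen=True)
class ImpactFactors:
    kv: float
    imf_head: float
    imf_body: float


@dataclass(frozen=True)
class ReferenceScannerLibrary:
    """Reference scanners with known factors and dataset identifiers.

    Entries are ``(scanner name, kv, imf_head, imf_body, dataset_id)``.
    """

    entries: tuple[tuple[str, float, float, float, str], ...]

    def __post_init__(self) -> None:
        entries = tuple(tuple(e) for e in self.entries)
        if not entries:
            raise ValidationError("reference library must be non-empty")
        keys = [(e[0], e[1]) for e in entries]
        if len(set(keys)) != len(keys):
            raise ValidationError("(name, kV) pairs must be unique")
        object.__setattr__(self, "entries", entries)

    def kvs(self) -> list[float]:
        return sorted({e[1] for e in self.entries})


def _factor(ctdi_c: float, ctdi_p: float, ctdi_air: float, coeffs) -> float:
    if ctdi_air <= 0:
        raise ValidationError("ctdi_air must be > 0")
    if ctdi_c < 0 or ctdi_p < 0:
        raise ValidationError("CTDI inputs must be nonnegative")
    a, b, c = coeffs
    return a * (ctdi_c / ctdi_air) + b * (ctdi_p / ctdi_air) + c


def impact_factor_head(ctdi_c: float, ctdi_p: float, ctdi_air: float) -> float:
    """Head ImPACT factor from head-phantom centre/periphery CTDI and CTDIair."""
    return _factor(ctdi_c, ctdi_p, ctdi_air, IMF_HEAD_COEFFS)


def impact_factor_body(ctdi_c: float, ctdi_p: float, ctdi_air: float) -> float:
    """Body ImPACT factor from body-phantom centre/periphery CTDI and CTDIair."""
    return _factor(ctdi_c, ctdi_p, ctdi_air, IMF_BODY_COEFFS)


def characterize_scanner(model: ScannerModel) -> list[ImpactFactors]:
    """One :class:`ImpactFactors` record per kV, in measurement order."""
    out = []
    for m in model.measurements:
        out.append(
            ImpactFactors(
                kv=m.kv,
                imf_head=impact_factor_head(m.ctdi100_c_head, m.ctdi100_p_head, m.ctdi_air),
                imf_body=impact_factor_body(m.ctdi100_c_body, m.ctdi100_p_body, m.ctdi_air),
            )
        )
    return out


def match_score(target: ImpactFactors, imf_head: float, imf_body: float) -> float:
    """Sum of relative absolute differences of head and body factors."""
    return abs(imf_head - target.imf_head) / abs(target.imf_head) + abs(
        imf_body - target.imf_body
    ) / abs(target.imf_body)


def match_scanner(
    target: list[ImpactFactors],
    library: ReferenceScannerLibrary,
    kv: float,
) -> tuple[str, float]:
    """Best-matching reference dataset for the target factors at one kV.

    Returns ``(dataset_id, score)`` minimising :func:`match_score`, ties
    broken by library order.  If the library has no entry at the requested
    kV the nearest available kV is used with a warning.
    """
    tf = next((t for t in target if t.kv == kv), None)
    if tf is None:
        avail = ", ".join(f"{t.kv:g}" for t in target)
        raise ValidationError(f"target factors missing {kv:g} kV; available: {avail}")
    lib_kvs = library.kvs()
    if kv in lib_kvs:
        use_kv = kv
    else:
        use_kv = min(lib_kvs, key=lambda k: (abs(k - kv), k))
        warnings.warn(
            f"library has no entries at {kv:g} kV; using nearest {use_kv:g} kV",
            stacklevel=2,
        )
    best: tuple[str, float] | None = None
    for name, entry_kv, head, body, dataset_id in library.entries:
        if entry_kv != use_kv:
            continue
        score = match_score(tf, head, body)
        if best is None or score < best[1]:
            best = (dataset_id, score)
    assert best is not None
    return best


def rank_matches(
    target: list[ImpactFactors],
    library: ReferenceScannerLibrary,
    kv: float,
) -> list[tuple[str, str, float]]:
    """All library entries at the matched kV as (name, dataset_id, score), best first."""
    tf = next((t for t in target if t.kv == kv), None)
    if tf is None:
        raise ValidationError(f"target factors missing {kv:g} kV")
    lib_kvs = library.kvs()
    use_kv = kv if kv in lib_kvs else min(lib_kvs, key=lambda k: (abs(k - kv), k))
    scored = [
        (name, dataset_id, match_score(tf, head, body))
        for name, entry_kv, head, body, dataset_id in library.entries
        if entry_kv == use_kv
    ]
    return sorted(scored, key=lambda t: t[2])
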