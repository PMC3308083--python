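"""WORMS-style ordinal lesion scores: validation, per-subject maxima, prevalence.

Scales follow the modified whole-organ MRI score used for compartment-based
knee grading: cartilage on an 8-point scale {0, 1, 2.0, 2.5, 3, 4, 5, 6}
(2.5 marks a small full-thickness focal defect), meniscus per region on
{0..4}, and bone-marrow lesions on {0..3}. Subjects without readings are
excluded list-wise from prevalence denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import COMPARTMENTS, MENISCUS_REGIONS
from .exceptions import ConfigurationError, DegenerateDataError, ValidationError

__all__ = [
    "CARTILAGE_SCALE",
    "MENISCUS_SCALE",
    "BML_SCALE",
    "WormsRecord",
    "PrevalenceResult",
    "validate_worms",
    "worms_max_score",
    "lesion_prevalence",
    "records_to_frame",
    "frame_to_records",
]

CARTILAGE_SCALE: tuple[float, ...] = (0.0, 1.0, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0)
MENISCUS_SCALE: tuple[int, ...] = (0, 1, 2, 3, 4)
BML_SCALE: tuple[int, ...] = (0, 1, 2, 3)

_TISSUES = ("cartilage", "meniscus", "bml")

# CSV column stems per tissue (schema: cart_pat, ..., men_ma, ..., bml_pat, ...)
_CART_COLS = ("cart_pat", "cart_mf", "cart_mt", "cart_lf", "cart_lt")
_MEN_COLS = ("men_ma", "men_mb", "men_mp", "men_la", "men_lb", "men_lp")
_BML_COLS = ("bml_pat", "bml_mf", "bml_mt", "bml_lf", "bml_lt")


@dataclass
class WormsRecord:
    """One subject's ordinal lesion scores across tissues and sites."""

    subject_id: str = ""
    cartilage: dict[str, float] = field(default_factory=dict)
    meniscus: dict[str, int] = field(default_factory=dict)
    bml: dict[str, int] = field(default_factory=dict)
    readings_available: bool = True

    def validate(self) -> "WormsRecord":
        return validate_worms(self)

    def scores(self, tissue: str) -> dict:
        if tissue == "cartilage":
            return self.cartilage
        if tissue == "meniscus":
            return self.meniscus
        if tissue == "bml":
            return self.bml
        raise ConfigurationError(f"unknown tissue '{tissue}'")

    def max_score(self, tissue: str) -> float | None:
        return worms_max_score(self, tissue)


@dataclass
class PrevalenceResult:
    tissue: str
    threshold: str
    n_with_lesion: int
    n_readable: int
    proportion: float
    by_compartment: dict[str, float] | None = None

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


def validate_worms(record: WormsRecord) -> WormsRecord:
    """Check every score against its declared scale; half-grades only for cartilage."""
    if not record.readings_available:
        return record
    for tissue, scale in (("cartilage", CARTILAGE_SCALE),
                          ("meniscus", MENISCUS_SCALE),
                          ("bml", BML_SCALE)):
        expected = COMPARTMENTS if tissue != "meniscus" else MENISCUS_REGIONS
        table = record.scores(tissue)
        for site in expected:
            if site not in table:
                raise ValidationError(f"{tissue}: missing site '{site}'")
            v = table[site]
            if not any(np.isclose(v, s) for s in scale):
                raise ValidationError(
                    f"{tissue}/{site}: score {v!r} is not on the scale {scale}"
                )
    return record


def worms_max_score(record: WormsRecord, tissue: str) -> float | None:
    """Per-subject maximum over the tissue's sites; None when readings are missing."""
    if not record.readings_available:
        return None
    return float(max(record.scores(tissue).values()))


def _meets(value: float, threshold: str) -> bool:
    if threshold == ">0":
        return value > 0
    if threshold == ">=2":
        return value >= 2
    raise ConfigurationError(f"unknown threshold '{threshold}' (use '>0' or '>=2')")


def lesion_prevalence(cohort: Iterable[WormsRecord], tissue: str,
                      threshold: str = ">0",
                      by_compartment: bool = False) -> PrevalenceResult:
    """Fraction of readable subjects with any site meeting the threshold.

    Subjects with ``readings_available=False`` are excluded from the
    denominator. Bone-marrow lesions only support the ``>0`` analysis.
    """
    if tissue not in _TISSUES:
        raise ConfigurationError(f"unknown tissue '{tissue}'")
    if tissue == "bml" and threshold != ">0":
        raise ConfigurationError("bone-marrow lesion prevalence is defined for '>0' only")
    readable = [r for r in cohort if r.readings_available]
    if not readable:
        raise DegenerateDataError("no readable WORMS records in cohort")
    hits = sum(_meets(worms_max_score(r, tissue), threshold) for r in readable)
    per_site = None
    if by_compartment:
        sites = readable[0].scores(tissue).keys()
        per_site = {
            s: sum(_meets(r.scores(tissue)[s], threshold) for r in readable) / len(readable)
            for s in sites
        }
    return PrevalenceResult(
        tissue=tissue, threshold=threshold, n_with_lesion=int(hits),
        n_readable=len(readable), proportion=hits / len(readable),
        by_compartment=per_site,
    )


def records_to_frame(records: Sequence[WormsRecord]) -> pd.DataFrame:
    """Long->wide CSV schema: one row per subject, NaN rows for missing readings."""
    rows = []
    for r in records:
        row: dict = {"subject_id": r.subject_id,
                     "readings_available": r.readings_available}
        for cols, sites, table in (
                (_CART_COLS, COMPARTMENTS, r.cartilage),
                (_MEN_COLS, MENISCUS_REGIONS, r.meniscus),
                (_BML_COLS, COMPARTMENTS, r.bml)):
            for col, site in zip(cols, sites):
                row[col] = table.get(site, np.nan) if r.readings_available else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[WormsRecord]:
    records = []
    for _, row in frame.iterrows():
        available = bool(row.get("readings_available", True))
        if available and row[list(_CART_COLS)].isna().any():
            available = False
        if not available:
            records.append(WormsRecord(subject_id=str(row["subject_id"]),
                                       readings_available=False))
            continue
        rec = WormsRecord(
            subject_id=str(row["subject_id"]),
            cartilage={s: float(row[c]) for c, s in zip(_CART_COLS, COMPARTMENTS)},
            meniscus={s: int(row[c]) for c, s in zip(_MEN_COLS, MENISCUS_REGIONS)},
            bml={s: int(row[c]) for c, s in zip(_BML_COLS, COMPARTMENTS)},
        )
        records.append(rec.validate())
    return records
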