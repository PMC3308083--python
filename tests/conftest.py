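"""Shared fixtures: small study configs and a cohort reproducing printed lesion counts."""

from dataclasses import replace

import numpy as np
import pytest

from cartt2.config import COMPARTMENTS, MENISCUS_REGIONS, SimConfig
from cartt2.worms import WormsRecord


@pytest.fixture
def tiny_sim() -> SimConfig:
    """Desk-scale config: 3+3 subjects, 2 slices, 32x32 images."""
    return replace(SimConfig(), n_incidence=3, n_control=3, n_slices=2,
                   image_shape=(32, 32), seed=11).validate()


def _record(subject_id: str, cart_max: float = 0.0, bml_max: int = 0,
            men_max: int = 0, available: bool = True) -> WormsRecord:
    if not available:
        return WormsRecord(subject_id=subject_id, readings_available=False)
    cart = {c: 0.0 for c in COMPARTMENTS}
    cart["patella"] = cart_max
    men = {m: 0 for m in MENISCUS_REGIONS}
    men["medial_posterior"] = men_max
    bml = {c: 0 for c in COMPARTMENTS}
    bml["medial_femur"] = bml_max
    return WormsRecord(subject_id=subject_id, cartilage=cart, meniscus=men,
                       bml=bml).validate()


def build_counted_cohort(n_readable: int, n_missing: int, n_cart_any: int,
                         n_cart_mod: int, n_bml: int, n_men_any: int = 0,
                         n_men_mod: int = 0, prefix: str = "S"):
    """Deterministic cohort with exactly the requested subject-level counts.

    Lesion categories overlap maximally (moderate subjects are a subset of
    any-lesion subjects), which is all the subject-level prevalence counters
    see.
    """
    records = []
    for i in range(n_readable):
        cart = 2.0 if i < n_cart_mod else (1.0 if i < n_cart_any else 0.0)
        men = 2 if i < n_men_mod else (1 if i < n_men_any else 0)
        bml = 1 if i < n_bml else 0
        records.append(_record(f"{prefix}{i:03d}", cart, bml, men))
    for i in range(n_missing):
        records.append(_record(f"{prefix}M{i:03d}", available=False))
    return records


@pytest.fixture
def table4_incidence():
    """92 incidence subjects: 88 readable, cartilage 59/44, BML 29, meniscus 42/22."""
    return build_counted_cohort(88, 4, n_cart_any=59, n_cart_mod=44, n_bml=29,
                                n_men_any=42, n_men_mod=22, prefix="INC")


@pytest.fixture
def table4_control():
    """53 control subjects: 45 readable, cartilage 33/19, BML 19, meniscus 18/9."""
    return build_counted_cohort(45, 8, n_cart_any=33, n_cart_mod=19, n_bml=19,
                                n_men_any=18, n_men_mod=9, prefix="CTL")
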