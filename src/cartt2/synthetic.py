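"""Synthetic knee-MRI cohort generator.

Emulates a two-group observational imaging study: an "incidence" group with
risk factors for knee osteoarthritis and a healthy control group, both with
normal radiographs and no pain. For each subject the generator draws
demographics from truncated group distributions, per-compartment true
cartilage T2 means from correlated group distributions, a laminar T2 field on
five annular cartilage bands (depth gradient from the bone interface to the
articular surface plus zero-mean spatial heterogeneity), renders a
multi-echo magnitude stack with Rician noise, and draws ordinal WORMS-style
lesion scores whose cohort marginals match configured prevalences and whose
cartilage scores are positively coupled to the subject's T2 offset.

Everything is driven by a single integer seed via ``numpy.random.SeedSequence``
spawning, so a fixed :class:`~cartt2.config.SimConfig` reproduces the cohort
bit for bit.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

from .config import (COMPARTMENTS, COMPARTMENT_LABELS, MENISCUS_REGIONS,
                     SimConfig)
from .exceptions import GeometryError
from .relaxometry import EchoStack
from .worms import WormsRecord

__all__ = [
    "SubjectRecord",
    "TrueT2Field",
    "sample_subjects",
    "sample_compartment_means",
    "build_t2_field",
    "render_echoes",
    "sample_worms",
    "simulate_subject_images",
    "true_t2_cohort_table",
    "subjects_to_frame",
]

# Annular-band geometry: five sectors of a common annulus, one per compartment.
_SECTOR_SPAN = 64.0   # degrees per compartment band
_SECTOR_GAP = 8.0     # degrees between bands
_BAND_THICKNESS = 3.5  # pixels, giving 3-4 px across the band


@dataclass
class SubjectRecord:
    """One simulated subject's covariates (study inclusion criteria baked in)."""

    subject_id: str
    group: str
    age: float
    sex: str  # "F" or "M"
    bmi: float
    womac_pain: int = 0
    kl_score: int = 0


@dataclass
class TrueT2Field:
    """Ground-truth laminar T2 field with compartment labels (one subject)."""

    t2: np.ndarray           # (slice, row, col), ms; NaN outside cartilage
    s0: np.ndarray           # (slice, row, col); 0 in background
    labels: np.ndarray       # (slice, row, col) int, 0 background, 1-5 compartments
    compartment_means: dict[str, float] = field(default_factory=dict)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    """Redraw-until-inside truncated normal (matches cohort inclusion windows)."""
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def sample_subjects(config: SimConfig, seed: int | None = None) -> list[SubjectRecord]:
    """Draw the cohort's subject records (demographics only), deterministically."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[SubjectRecord] = []
    for group, n in (("incidence", config.n_incidence), ("control", config.n_control)):
        if n == 0:
            continue
        ages = _truncated_normal(rng, *config.age_mean_sd[group], *config.age_range, n)
        bmis = _truncated_normal(rng, *config.bmi_mean_sd[group], *config.bmi_range, n)
        female = rng.random(n) < config.female_fraction[group]
        for i in range(n):
            records.append(SubjectRecord(
                subject_id=f"{group[:3].upper()}{i + 1:04d}",
                group=group,
                age=float(ages[i]),
                sex="F" if female[i] else "M",
                bmi=float(bmis[i]),
            ))
    return records


def subjects_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "bmi": [r.bmi for r in records],
            "womac_pain": [r.womac_pain for r in records],
            "kl_score": [r.kl_score for r in records],
        }
    )


def sample_compartment_means(group: str, config: SimConfig,
                             rng: np.random.Generator) -> dict[str, float]:
    """Draw one subject's five true compartment-mean T2 values (ms).

    A shared standard-normal factor with loading ``t2_intercompartment_rho``
    correlates compartments so the subject-level five-compartment average has
    realistic dispersion.
    """
    rho = config.t2_intercompartment_rho
    z0 = rng.standard_normal()
    means = {}
    for comp in COMPARTMENTS:
        mu, sd = config.t2_mean_sd[group][comp]
        z = rho * z0 + np.sqrt(1.0 - rho * rho) * rng.standard_normal()
        means[comp] = float(mu + sd * z)
    return means


def implied_all_average_sd(config: SimConfig, group: str) -> float:
    """Model-implied SD of the subject-level five-compartment average T2."""
    sds = np.array([config.t2_mean_sd[group][c][1] for c in COMPARTMENTS])
    rho2 = config.t2_intercompartment_rho ** 2
    var = (np.sum(sds ** 2) + rho2 * (np.sum(sds) ** 2 - np.sum(sds ** 2))) / 25.0
    return float(np.sqrt(var))


def _band_geometry(image_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Label image (rows x cols) with five annular band sectors, plus depth in [0, 1].

    Depth 0 is the inner (bone-interface) edge, 1 the outer (surface) edge.
    """
    nr, nc = image_shape
    r_out_max = min(nr, nc) / 2.0 - 2.0
    r_in = r_out_max - _BAND_THICKNESS
    if r_in < 2.0 * _BAND_THICKNESS:
        raise GeometryError(
            f"image_shape {image_shape} cannot hold five 3-4 px annular bands"
        )
    cy, cx = (nr - 1) / 2.0, (nc - 1) / 2.0
    rr, cc = np.mgrid[0:nr, 0:nc]
    rad = np.hypot(rr - cy, cc - cx)
    ang = np.degrees(np.arctan2(rr - cy, cc - cx)) % 360.0
    labels = np.zeros((nr, nc), dtype=np.int16)
    depth = np.zeros((nr, nc))
    in_band = (rad >= r_in) & (rad < r_in + _BAND_THICKNESS)
    for k, comp in enumerate(COMPARTMENTS):
        a0 = k * (_SECTOR_SPAN + _SECTOR_GAP)
        sector = in_band & (ang >= a0) & (ang < a0 + _SECTOR_SPAN)
        labels[sector] = COMPARTMENT_LABELS[comp]
        depth[sector] = (rad[sector] - r_in) / _BAND_THICKNESS
    return labels, depth


def build_t2_field(subject: SubjectRecord, config: SimConfig,
                   rng: np.random.Generator,
                   means: dict[str, float] | None = None) -> TrueT2Field:
    """Build one subject's 3D laminar true-T2 field and compartment label masks.

    Within each band: drawn compartment mean + linear depth gradient
    (zero-mean across the band) + zero-mean spatial noise of SD
    ``heterogeneity_sd[group]``. The field is recentred so the within-band
    mean equals the drawn compartment mean exactly, then floored at
    ``t2_floor`` to keep T2 physical.
    """
    config.validate()
    if means is None:
        means = sample_compartment_means(subject.group, config, rng)
    labels2d, depth2d = _band_geometry(tuple(config.image_shape))
    het = config.heterogeneity_sd[subject.group]
    n_sl = config.n_slices
    shape3d = (n_sl, *config.image_shape)
    t2 = np.full(shape3d, np.nan)
    s0 = np.zeros(shape3d)
    labels = np.broadcast_to(labels2d, shape3d).copy()
    for s in range(n_sl):
        for comp in COMPARTMENTS:
            m = labels2d == COMPARTMENT_LABELS[comp]
            vals = (means[comp]
                    + config.depth_gradient * (depth2d[m] - 0.5)
                    + het * rng.standard_normal(int(m.sum())))
            vals += means[comp] - vals.mean()  # exact within-band mean
            t2[s][m] = np.maximum(vals, config.t2_floor)
            s0[s][m] = config.s0
    return TrueT2Field(t2=t2, s0=s0, labels=labels, compartment_means=means)


def render_echoes(fieldmap: TrueT2Field, config: SimConfig,
                  rng: np.random.Generator) -> EchoStack:
    """Render the multi-echo magnitude stack with two-channel (Rician) noise.

    Each echo's magnitude is ``sqrt((S0 exp(-TE/T2) + n1)^2 + n2^2)`` with
    ``n1, n2 ~ N(0, noise_sigma^2)``; background pixels (S0 = 0) are pure
    noise. The squared expectation matches the fitted model with
    ``B^2 = 2 noise_sigma^2``.
    """
    tes = np.asarray(config.echo_times, dtype=float)
    shape = fieldmap.t2.shape
    clean = np.zeros((*shape, tes.size))
    inside = fieldmap.labels > 0
    t2_in = fieldmap.t2[inside]
    s0_in = fieldmap.s0[inside]
    clean[inside] = s0_in[:, None] * np.exp(-tes[None, :] / t2_in[:, None])
    sigma = config.noise_sigma
    if sigma > 0:
        n1 = rng.normal(0.0, sigma, clean.shape)
        n2 = rng.normal(0.0, sigma, clean.shape)
        data = np.hypot(clean + n1, n2)
    else:
        data = clean
    return EchoStack(data=data, echo_times=tes,
                     pixel_spacing=tuple(config.pixel_spacing),
                     slice_gap=config.slice_gap,
                     slice_thickness=config.slice_thickness)


# ---------------------------------------------------------------------------
# Ordinal lesion scores
# ---------------------------------------------------------------------------

# Within-subject compartment weights for the primary lesion site, shaped after
# the observed compartment distribution (patella-dominant for cartilage,
# posterior medial meniscus dominant for menisci).
_CART_SITE_WEIGHTS = {
    "incidence": (0.545, 0.125, 0.045, 0.090, 0.193),
    "control": (0.577, 0.111, 0.022, 0.044, 0.222),
}
_MEN_SITE_WEIGHTS = {
    "incidence": (0.011, 0.125, 0.431, 0.068, 0.045, 0.113),
    "control": (0.005, 0.200, 0.333, 0.022, 0.005, 0.111),
}
_BML_SITE_WEIGHTS = (0.30, 0.20, 0.15, 0.15, 0.20)
_SECONDARY_SITE_P = 0.12  # chance each non-primary site also carries a mild lesion

_CART_SEVERE_SCORES = ((2.0, 2.5, 3.0, 4.0, 5.0, 6.0),
                       (0.50, 0.20, 0.20, 0.05, 0.03, 0.02))
_MEN_SEVERE_SCORES = ((2, 3, 4), (0.70, 0.25, 0.05))
_BML_SCORES = ((1, 2, 3), (0.60, 0.30, 0.10))


@functools.lru_cache(maxsize=64)
def _coupled_intercept(p: float, beta: float) -> float:
    """Intercept a such that E_z~N(0,1)[expit(a + beta z)] = p (Gauss-Hermite)."""
    if beta == 0.0:
        return float(np.log(p / (1.0 - p))) if 0 < p < 1 else (np.inf if p >= 1 else -np.inf)
    nodes, weights = roots_hermitenorm(61)
    w = weights / weights.sum()

    def marginal(a):
        return float(np.sum(w * expit(a + beta * nodes))) - p

    return brentq(marginal, -40.0, 40.0)


def _draw_sites(rng: np.random.Generator, weights: Sequence[float],
                severe: bool, severe_scores, n_sites: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    scores = np.zeros(n_sites)
    primary = rng.choice(n_sites, p=w)
    if severe:
        vals, probs = severe_scores
        scores[primary] = rng.choice(vals, p=probs)
    else:
        scores[primary] = 1
    others = rng.random(n_sites) < _SECONDARY_SITE_P
    others[primary] = False
    scores[others] = 1
    return scores


def sample_worms(subject: SubjectRecord, config: SimConfig,
                 rng: np.random.Generator, t2_z: float = 0.0) -> WormsRecord:
    """Draw one subject's ordinal lesion scores.

    ``t2_z`` is the subject's standardized all-compartment T2 offset; cartilage
    lesion odds follow a logistic link in ``t2_z`` with slope
    ``config.t2_worms_coupling``, while the cohort marginal prevalence is held
    at the configured value by solving for the intercept under a standard
    normal offset distribution. Meniscus and bone-marrow scores are drawn
    independently of T2.
    """
    g = subject.group
    beta = config.t2_worms_coupling
    if rng.random() < config.worms_missing_rate[g]:
        return WormsRecord(subject_id=subject.subject_id, readings_available=False)

    prev = config.lesion_prevalence
    p_any, p_mod = prev["cartilage"][g]
    p_lesion = float(expit(_coupled_intercept(p_any, beta) + beta * t2_z)) if 0 < p_any < 1 else p_any
    cart = np.zeros(len(COMPARTMENTS))
    if rng.random() < p_lesion:
        severe = p_any > 0 and rng.random() < min(p_mod / p_any, 1.0)
        cart = _draw_sites(rng, _CART_SITE_WEIGHTS[g], severe,
                           _CART_SEVERE_SCORES, len(COMPARTMENTS))

    p_any_m, p_mod_m = prev["meniscus"][g]
    men = np.zeros(len(MENISCUS_REGIONS))
    if rng.random() < p_any_m:
        severe = p_any_m > 0 and rng.random() < min(p_mod_m / p_any_m, 1.0)
        men = _draw_sites(rng, _MEN_SITE_WEIGHTS[g], severe,
                          _MEN_SEVERE_SCORES, len(MENISCUS_REGIONS))

    (p_bml,) = prev["bml"][g]
    bml = np.zeros(len(COMPARTMENTS))
    if rng.random() < p_bml:
        bml = _draw_sites(rng, _BML_SITE_WEIGHTS, True, _BML_SCORES,
                          len(COMPARTMENTS))

    return WormsRecord(
        subject_id=subject.subject_id,
        cartilage=dict(zip(COMPARTMENTS, cart.tolist())),
        meniscus=dict(zip(MENISCUS_REGIONS, [int(v) for v in men])),
        bml=dict(zip(COMPARTMENTS, [int(v) for v in bml])),
        readings_available=True,
    ).validate()


# ---------------------------------------------------------------------------
# Cohort-level drivers
# ---------------------------------------------------------------------------

def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def true_t2_cohort_table(config: SimConfig, with_worms: bool = True) -> pd.DataFrame:
    """Fast cohort table using *true* (image-free) compartment T2 means.

    One row per subject with demographics, true per-compartment mean T2, the
    five-compartment average, and (optionally) WORMS scores and lesion
    indicators. Used for statistics-stage simulations where the imaging and
    fitting stages would only add noise and runtime.
    """
    config.validate()
    subjects = sample_subjects(config, config.seed)
    ss = np.random.SeedSequence(config.seed)
    _, t2_ss, worms_ss = ss.spawn(3)
    t2_rngs = [np.random.default_rng(s) for s in t2_ss.spawn(len(subjects))]
    worms_rngs = [np.random.default_rng(s) for s in worms_ss.spawn(len(subjects))]

    rows = []
    for subj, rng_t2, rng_w in zip(subjects, t2_rngs, worms_rngs):
        means = sample_compartment_means(subj.group, config, rng_t2)
        all_avg = float(np.mean(list(means.values())))
        mu_all = float(np.mean([config.t2_mean_sd[subj.group][c][0] for c in COMPARTMENTS]))
        sd_all = implied_all_average_sd(config, subj.group)
        t2_z = (all_avg - mu_all) / sd_all
        row = {"subject_id": subj.subject_id, "group": subj.group,
               "age": subj.age, "sex": subj.sex, "bmi": subj.bmi}
        for comp in COMPARTMENTS:
            row[f"mean_t2_{comp}"] = means[comp]
        row["mean_t2_all"] = all_avg
        if with_worms:
            rec = sample_worms(subj, config, rng_w, t2_z=t2_z)
            row["worms_readable"] = rec.readings_available
            if rec.readings_available:
                row["worms_max_cartilage"] = rec.max_score("cartilage")
                row["worms_max_meniscus"] = rec.max_score("meniscus")
                row["worms_max_bml"] = rec.max_score("bml")
                row["cartilage_lesion"] = rec.max_score("cartilage") > 0
                row["meniscus_lesion"] = rec.max_score("meniscus") > 0
                row["bml_lesion"] = rec.max_score("bml") > 0
            else:
                for k in ("worms_max_cartilage", "worms_max_meniscus",
                          "worms_max_bml"):
                    row[k] = np.nan
                for k in ("cartilage_lesion", "meniscus_lesion", "bml_lesion"):
                    row[k] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_subject_images(config: SimConfig) -> Iterator[
        tuple[SubjectRecord, TrueT2Field, EchoStack]]:
    """Yield ``(subject, true field, echo stack)`` per subject, seeded from config.

    Images are generated lazily so cohort-scale runs never hold more than one
    subject's stack in memory.
    """
    config.validate()
    subjects = sample_subjects(config, config.seed)
    ss = np.random.SeedSequence(config.seed)
    _, t2_ss, _, img_ss = ss.spawn(4)
    t2_rngs = t2_ss.spawn(len(subjects))
    img_rngs = img_ss.spawn(len(subjects))
    for subj, t2_s, img_s in zip(subjects, t2_rngs, img_rngs):
        rng_t2 = np.random.default_rng(t2_s)
        rng_img = np.random.default_rng(img_s)
        means = sample_compartment_means(subj.group, config, rng_t2)
        fieldmap = build_t2_field(subj, config, rng_img, means=means)
        stack = render_echoes(fieldmap, config, rng_img)
        yield subj, fieldmap, stack
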