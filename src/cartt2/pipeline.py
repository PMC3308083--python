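"""End-to-end orchestration: simulate -> fit -> texture -> score -> analyze.

Each stage reads/writes plain intermediates (NIfTI volumes, CSV tables, JSON
summaries) under the run directory, so any stage can later be re-run against
real data in place of the simulator. A JSON manifest records the seed, a
config hash and package versions for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import COMPARTMENTS, RunConfig
from .exceptions import CartT2Error
from .io import write_echo_stack, write_labels, write_t2map
from .relaxometry import fit_map
from .stats import adjusted_group_difference, logistic_prevalence_or
from .synthetic import (sample_worms, simulate_subject_images, subjects_to_frame,
                        sample_subjects, implied_all_average_sd)
from .texture import compartment_texture
from .worms import lesion_prevalence, records_to_frame, frame_to_records

log = logging.getLogger("cartt2")

_SHORT = {"patella": "pat", "medial_femur": "mf", "medial_tibia": "mt",
          "lateral_femur": "lf", "lateral_tibia": "lt", "all": "all"}


class StageError(CartT2Error):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            log.info("stage %s: start", name)
            try:
                out = fn(*a, **kw)
            except Exception as exc:
                raise StageError(f"[{name}] {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapper
    return deco


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, frozenset):
            return sorted(o)
        return str(o)
    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


@_stage("simulate")
def stage_simulate(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Generate subjects, WORMS scores and per-subject imaging; write them out."""
    sim = config.sim
    subjects = sample_subjects(sim, sim.seed)
    frame = subjects_to_frame(subjects)

    ss = np.random.SeedSequence(sim.seed)
    _, t2_ss, worms_ss, _ = ss.spawn(4)
    worms_rngs = [np.random.default_rng(s) for s in worms_ss.spawn(len(subjects))]

    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    worms_records = []
    true_means = []
    for (subj, fieldmap, stack), rng_w in zip(simulate_subject_images(sim), worms_rngs):
        write_echo_stack(stack, img_dir / f"{subj.subject_id}_echoes.nii.gz")
        write_labels(fieldmap.labels, img_dir / f"{subj.subject_id}_labels.nii.gz",
                     sim.pixel_spacing, sim.slice_thickness + sim.slice_gap)
        all_avg = float(np.mean(list(fieldmap.compartment_means.values())))
        mu_all = float(np.mean([sim.t2_mean_sd[subj.group][c][0] for c in COMPARTMENTS]))
        z = (all_avg - mu_all) / implied_all_average_sd(sim, subj.group)
        worms_records.append(sample_worms(subj, sim, rng_w, t2_z=z))
        true_means.append({"subject_id": subj.subject_id,
                           **{f"true_t2_{c}": fieldmap.compartment_means[c]
                              for c in COMPARTMENTS}})
    records_to_frame(worms_records).to_csv(outdir / "worms.csv", index=False)
    frame = frame.merge(pd.DataFrame(true_means), on="subject_id")
    frame.to_csv(outdir / "subjects.csv", index=False)
    return frame


@_stage("fit")
def stage_fit(config: RunConfig, outdir: Path) -> None:
    """Fit T2 maps for every simulated subject."""
    from .io import read_echo_stack, read_labels
    img_dir = outdir / "images"
    map_dir = outdir / "maps"
    map_dir.mkdir(exist_ok=True)
    subjects = pd.read_csv(outdir / "subjects.csv")["subject_id"]
    for sid in subjects:
        stack = read_echo_stack(img_dir / f"{sid}_echoes.nii.gz")
        labels = read_labels(img_dir / f"{sid}_labels.nii.gz")
        t2map = fit_map(stack, labels > 0, config.fit)
        write_t2map(t2map, map_dir / sid)


@_stage("texture")
def stage_texture(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Per-subject, per-compartment mean T2 + GLCM features -> cohort.csv."""
    from .io import read_labels, read_t2map
    map_dir = outdir / "maps"
    img_dir = outdir / "images"
    subjects = pd.read_csv(outdir / "subjects.csv")
    rows = []
    for sid in subjects["subject_id"]:
        t2map = read_t2map(map_dir / sid)
        labels = read_labels(img_dir / f"{sid}_labels.nii.gz")
        feats = compartment_texture(t2map, labels, config.texture)
        row = {"subject_id": sid}
        for comp, short in _SHORT.items():
            for col in ("mean_t2", "contrast", "entropy", "variance"):
                row[f"{col}_{short}"] = feats.loc[comp, col]
        rows.append(row)
    cohort = subjects.merge(pd.DataFrame(rows), on="subject_id")

    worms = frame_to_records(pd.read_csv(outdir / "worms.csv"))
    wrows = []
    for rec in worms:
        wrows.append({
            "subject_id": rec.subject_id,
            "worms_readable": rec.readings_available,
            "worms_max_cartilage": rec.max_score("cartilage"),
            "worms_max_meniscus": rec.max_score("meniscus"),
            "worms_max_bml": rec.max_score("bml"),
        })
    cohort = cohort.merge(pd.DataFrame(wrows), on="subject_id", how="left")
    for tissue in ("cartilage", "meniscus", "bml"):
        cohort[f"{tissue}_lesion"] = cohort[f"worms_max_{tissue}"] > 0
        cohort.loc[cohort[f"worms_max_{tissue}"].isna(), f"{tissue}_lesion"] = np.nan
    cohort.to_csv(outdir / "cohort.csv", index=False)
    return cohort


@_stage("score")
def stage_score(config: RunConfig, outdir: Path) -> dict:
    """Group-wise lesion prevalence table (JSON)."""
    worms = frame_to_records(pd.read_csv(outdir / "worms.csv"))
    groups = pd.read_csv(outdir / "subjects.csv").set_index("subject_id")["group"]
    out: dict = {}
    for group in ("incidence", "control"):
        sub = [r for r in worms if groups.get(r.subject_id) == group]
        if not sub:
            continue
        gdict = {}
        for tissue in ("cartilage", "meniscus", "bml"):
            thresholds = (">0",) if tissue == "bml" else (">0", ">=2")
            for thr in thresholds:
                res = lesion_prevalence(sub, tissue, thr)
                gdict[f"{tissue} {thr}"] = {
                    "n_with_lesion": res.n_with_lesion,
                    "n_readable": res.n_readable,
                    "percent": round(res.percent, 1),
                }
        out[group] = gdict
    (outdir / "prevalence.json").write_text(json.dumps(out, indent=1))
    return out


@_stage("analyze")
def stage_analyze(config: RunConfig, outdir: Path) -> pd.DataFrame:
    """Adjusted group comparisons of T2 parameters plus prevalence odds ratios."""
    cohort = pd.read_csv(outdir / "cohort.csv")
    rows = []
    for param in ("mean_t2", "contrast", "entropy", "variance"):
        for comp in ("all", "mf", "mt"):
            col = f"{param}_{comp}"
            res = adjusted_group_difference(cohort, col, config.covariates)
            rows.append({
                "parameter": param, "compartment": comp,
                "incidence_mean": res.mean_incidence, "incidence_sd": res.sd_incidence,
                "control_mean": res.mean_control, "control_sd": res.sd_control,
                "p_unadjusted": res.p_unadjusted, "p_adjusted": res.p_adjusted,
                "coefficient": res.coefficient,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
            })
    comparisons = pd.DataFrame(rows)
    comparisons.to_csv(outdir / "comparisons.csv", index=False)

    ors = []
    for tissue in ("cartilage", "meniscus", "bml"):
        col = f"{tissue}_lesion"
        try:
            res = logistic_prevalence_or(cohort, col, config.covariates)
            ors.append({"lesion": tissue, "odds_ratio": res.odds_ratio,
                        "ci_low": res.ci_low, "ci_high": res.ci_high,
                        "p": res.p_value})
        except CartT2Error as exc:
            ors.append({"lesion": tissue, "error": str(exc)})
    pd.DataFrame(ors).to_csv(outdir / "prevalence_or.csv", index=False)
    return comparisons


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write a manifest; returns a summary bundle."""
    config.sim.seed = config.seed
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    log.addHandler(handler)
    try:
        stage_simulate(config, outdir)
        stage_fit(config, outdir)
        cohort = stage_texture(config, outdir)
        prevalence = stage_score(config, outdir)
        comparisons = stage_analyze(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_subjects": int(len(cohort)),
        "versions": {"cartt2": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"cohort": cohort, "prevalence": prevalence,
            "comparisons": comparisons, "manifest": manifest}
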