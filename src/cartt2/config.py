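"""Configuration objects for simulation, fitting, texture analysis and pipeline runs.

All configs are plain dataclasses with explicit ``validate()`` methods that raise
:class:`~cartt2.exceptions.ConfigurationError` naming the offending field, so a
bad YAML file fails loudly at load time rather than deep inside a fit loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

from .exceptions import ConfigurationError

#: Cartilage compartments in mask-label order (label = index + 1).
COMPARTMENTS: tuple[str, ...] = (
    "patella",
    "medial_femur",
    "medial_tibia",
    "lateral_femur",
    "lateral_tibia",
)

#: Integer mask label for each compartment.
COMPARTMENT_LABELS: dict[str, int] = {c: i + 1 for i, c in enumerate(COMPARTMENTS)}

#: Meniscus regions (medial/lateral x anterior/body/posterior).
MENISCUS_REGIONS: tuple[str, ...] = (
    "medial_anterior",
    "medial_body",
    "medial_posterior",
    "lateral_anterior",
    "lateral_body",
    "lateral_posterior",
)

GROUPS: tuple[str, str] = ("incidence", "control")


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{name}: {msg}")


def _default_t2_mean_sd() -> dict[str, dict[str, tuple[float, float]]]:
    # MF / MT rows are the reported group distributions; LF / LT / patella are
    # chosen so each group's five-compartment mean equals the reported
    # all-compartment average (incidence 32.65 ms, control 32.07 ms).
    return {
        "incidence": {
            "patella": (31.80, 2.30),
            "medial_femur": (37.68, 2.28),
            "medial_tibia": (30.27, 1.88),
            "lateral_femur": (34.80, 2.10),
            "lateral_tibia": (28.70, 1.90),
        },
        "control": {
            "patella": (31.59, 2.20),
            "medial_femur": (36.85, 2.16),
            "medial_tibia": (29.51, 1.77),
            "lateral_femur": (34.20, 2.00),
            "lateral_tibia": (28.20, 1.80),
        },
    }


def _default_lesion_prevalence() -> dict[str, dict[str, tuple[float, ...]]]:
    # (P(any lesion, score > 0), P(moderate lesion, max score >= 2)) per group;
    # bone marrow lesions carry only the "> 0" analysis.
    return {
        "cartilage": {"incidence": (0.670, 0.500), "control": (0.733, 0.422)},
        "meniscus": {"incidence": (0.477, 0.250), "control": (0.400, 0.155)},
        "bml": {"incidence": (0.329,), "control": (0.422,)},
    }


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort generator.

    Defaults encode the two OAI-style cohorts: subjects aged 45-55 with BMI
    19-27, WOMAC pain 0 and KL 0, split into an at-risk ("incidence") group
    and a healthy control group, with group-specific cartilage T2
    distributions and lesion-prevalence marginals.
    """

    n_incidence: int = 92
    n_control: int = 53

    age_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"incidence": (50.65, 2.89), "control": (50.30, 3.03)}
    )
    age_range: tuple[float, float] = (45.0, 55.0)
    bmi_mean_sd: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"incidence": (23.78, 2.25), "control": (23.90, 2.23)}
    )
    bmi_range: tuple[float, float] = (19.0, 27.0)
    female_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"incidence": 50 / 92, "control": 36 / 53}
    )

    # True-T2 structure: per-compartment subject means (ms), shared-factor
    # correlation between compartments, spatial heterogeneity SD (ms) and the
    # bone-interface-to-surface depth gradient span (ms).
    t2_mean_sd: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=_default_t2_mean_sd
    )
    t2_intercompartment_rho: float = 0.63
    heterogeneity_sd: Mapping[str, float] = field(
        default_factory=lambda: {"incidence": 7.5, "control": 6.0}
    )
    depth_gradient: float = 10.0
    t2_floor: float = 1.0

    # Imaging / acquisition emulation.
    s0: float = 400.0
    noise_sigma: float = 0.5
    echo_times: tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0)
    n_slices: int = 3
    image_shape: tuple[int, int] = (48, 48)
    pixel_spacing: tuple[float, float] = (0.313, 0.446)
    slice_thickness: float = 3.0
    slice_gap: float = 0.5

    # Ordinal lesion scores.
    lesion_prevalence: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=_default_lesion_prevalence
    )
    worms_missing_rate: Mapping[str, float] = field(
        default_factory=lambda: {"incidence": 4 / 92, "control": 8 / 53}
    )
    #: Logistic-link slope coupling cartilage lesion odds to the subject's
    #: standardized T2 offset (0 decouples scores from T2).
    t2_worms_coupling: float = 1.55

    seed: int = 0

    def validate(self) -> "SimConfig":
        _check(self.n_incidence >= 0, "n_incidence", "must be >= 0")
        _check(self.n_control >= 0, "n_control", "must be >= 0")
        _check(self.n_incidence + self.n_control >= 1, "n_incidence/n_control",
               "cohort must contain at least one subject")
        for g in GROUPS:
            for name, table in (("age_mean_sd", self.age_mean_sd),
                                ("bmi_mean_sd", self.bmi_mean_sd)):
                _check(g in table, name, f"missing group '{g}'")
                _check(table[g][1] > 0, name, f"SD for '{g}' must be > 0")
            _check(0.0 <= self.female_fraction[g] <= 1.0, "female_fraction",
                   f"'{g}' must be a probability in [0, 1]")
            _check(self.heterogeneity_sd[g] >= 0, "heterogeneity_sd",
                   f"'{g}' must be >= 0")
            for comp in COMPARTMENTS:
                _check(comp in self.t2_mean_sd[g], "t2_mean_sd",
                       f"missing compartment '{comp}' for group '{g}'")
                mean, sd = self.t2_mean_sd[g][comp]
                _check(mean > 0, "t2_mean_sd", f"{g}/{comp} mean must be > 0")
                _check(sd > 0, "t2_mean_sd", f"{g}/{comp} SD must be > 0")
            _check(0.0 <= self.worms_missing_rate[g] <= 1.0, "worms_missing_rate",
                   f"'{g}' must be a probability in [0, 1]")
            for tissue, per_group in self.lesion_prevalence.items():
                for p in per_group[g]:
                    _check(0.0 <= p <= 1.0, "lesion_prevalence",
                           f"{tissue}/{g} entries must be probabilities in [0, 1]")
        _check(-1.0 < self.t2_intercompartment_rho < 1.0, "t2_intercompartment_rho",
               "must lie in (-1, 1)")
        _check(self.age_range[0] < self.age_range[1], "age_range", "must be increasing")
        _check(self.bmi_range[0] < self.bmi_range[1], "bmi_range", "must be increasing")
        _check(self.noise_sigma >= 0, "noise_sigma", "must be >= 0")
        _check(self.s0 > 0, "s0", "must be > 0")
        _check(self.t2_floor > 0, "t2_floor", "must be > 0")
        tes = tuple(self.echo_times)
        _check(len(tes) >= 2, "echo_times", "need at least two echoes")
        _check(all(b > a for a, b in zip(tes, tes[1:])), "echo_times",
               "must be strictly increasing")
        _check(self.n_slices >= 1, "n_slices", "must be >= 1")
        _check(min(self.image_shape) >= 24, "image_shape",
               "too small to hold five 3-4 px cartilage bands")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FitConfig:
    """Controls for the noise-corrected three-parameter T2 fit.

    The model is fitted in squared-signal space:
    ``S(TE)^2 = S0^2 exp(-2 TE / T2) + B^2``,
    where B absorbs the Rician noise floor of magnitude data.
    """

    excluded_echoes: frozenset = frozenset({0})
    t2_bounds: tuple[float, float] = (0.1, 200.0)
    s0_bounds: tuple[float, float] = (0.0, math.inf)
    b_bounds: tuple[float, float] = (0.0, math.inf)
    max_iterations: int = 200
    tolerance: float = 1e-10
    fallback_policy: str = "mark_invalid"  # or "clamp"

    def validate(self) -> "FitConfig":
        _check(self.t2_bounds[0] > 0 and self.t2_bounds[0] < self.t2_bounds[1],
               "t2_bounds", "must be a positive, increasing interval")
        for name, b in (("s0_bounds", self.s0_bounds), ("b_bounds", self.b_bounds)):
            _check(b[0] >= 0 and b[0] < b[1], name, "must be a non-negative interval")
        _check(self.tolerance > 0, "tolerance", "must be > 0")
        _check(self.max_iterations >= 1, "max_iterations", "must be >= 1")
        _check(self.fallback_policy in ("mark_invalid", "clamp"), "fallback_policy",
               "must be 'mark_invalid' or 'clamp'")
        return self


@dataclass
class TextureConfig:
    """Controls for masked GLCM texture analysis of T2 maps."""

    offset: int = 1
    orientations: tuple[int, ...] = (0, 45, 90, 135)
    quantization: str = "integer_ms"  # or "fixed_bins"
    n_levels: int = 101
    fixed_bins_range: tuple[float, float] = (0.0, 100.0)
    level_clamp: tuple[int, int] = (0, 100)
    symmetric: bool = True
    slice_aggregation: str = "pair_count_weighted"  # or "unweighted"

    def validate(self) -> "TextureConfig":
        _check(self.offset >= 1, "offset", "must be >= 1")
        _check(len(self.orientations) > 0, "orientations", "must be non-empty")
        _check(set(self.orientations) <= {0, 45, 90, 135}, "orientations",
               "must be a subset of {0, 45, 90, 135}")
        _check(self.quantization in ("integer_ms", "fixed_bins"), "quantization",
               "must be 'integer_ms' or 'fixed_bins'")
        _check(self.n_levels >= 2, "n_levels", "must be >= 2")
        _check(self.slice_aggregation in ("pair_count_weighted", "unweighted"),
               "slice_aggregation", "must be 'pair_count_weighted' or 'unweighted'")
        return self


@dataclass
class RunConfig:
    """Full pipeline configuration: simulate -> fit -> texture -> score -> analyze."""

    sim: SimConfig = field(default_factory=SimConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    covariates: tuple[str, ...] = ("age", "sex", "bmi")
    outdir: str = "cartt2_run"
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.sim.validate()
        self.fit.validate()
        self.texture.validate()
        return self


def run_config_from_dict(d: Mapping) -> RunConfig:
    """Build a RunConfig from a nested plain dict (e.g. parsed YAML)."""
    sim = SimConfig(**d.get("sim", {}))
    fit = FitConfig(**{**d.get("fit", {}),
                       **({"excluded_echoes": frozenset(d["fit"]["excluded_echoes"])}
                          if "excluded_echoes" in d.get("fit", {}) else {})})
    tex = TextureConfig(**d.get("texture", {}))
    kwargs = {k: v for k, v in d.items() if k in ("covariates", "outdir", "seed")}
    if "covariates" in kwargs:
        kwargs["covariates"] = tuple(kwargs["covariates"])
    return RunConfig(sim=sim, fit=fit, texture=tex, **kwargs).validate()
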