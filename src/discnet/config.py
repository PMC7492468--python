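"""Study and pipeline configuration.

The study design mirrors a 2x2 (sex x injury) rat annular-puncture
experiment: 48 animals (12 per group), lumbar IVDs L3/4-L5/6 punctured,
endpoints collected over 6 weeks.  Every effect the generator injects and
every noise scale it uses lives here, so tests can switch any of them off.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

SEXES = ("female", "male")
INJURY_GROUPS = ("sham", "injury")
ESTROUS_STAGES = ("proestrus", "estrus", "metestrus", "diestrus")

#: Standard ascending Touch-Test filament kit spanning 0.4-26.0 g.
DEFAULT_FILAMENTS = (0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 26.0)

DRG_LEVELS = ("T13", "L1", "L2", "L3", "L4", "L5")
IVD_LEVELS = ("L1/2", "L2/3", "L3/4", "L4/5", "L5/6")
PUNCTURED_LEVELS = ("L3/4", "L4/5", "L5/6")
HISTOLOGY_CATEGORIES = (
    "af_integrity",
    "afnp_border",
    "np_cellularity",
    "np_matrix",
    "endplate",
)
GENES = ("Calca", "Tac1", "Gapdh")


class ConfigurationError(ValueError):
    """Raised when a study or pipeline configuration is invalid."""


@dataclass
class EffectConfig:
    """Ground-truth effect structure injected by the generator.

    Defaults encode the study's observed directions: a large injury drop in
    male withdrawal threshold with no mean shift in females; injury-driven
    loss of punctured-level IVD height and raised degeneration grade in both
    sexes; no injury effect on axial/torsional/creep biomechanics; male-only
    Calca up-shift at the L2 DRG and Tac1 up-shift at L5; and greater male
    torsional stiffness / torque range.
    """

    # von Frey latent thresholds (grams) and injury fold-drops
    male_baseline_threshold_g: float = 15.0
    female_baseline_threshold_g: float = 10.0
    male_threshold_drop_fold: float = 4.0   # injury divides male threshold by this
    female_threshold_drop_fold: float = 1.0  # no mean injury effect in females

    # radiographic IVD height
    male_baseline_height_mm: float = 0.95
    female_baseline_height_mm: float = 0.90
    height_loss_frac: float = 0.25  # fraction lost at punctured levels x injury

    # histology (per-category expected subscore = base + gain * latent)
    subscore_base: float = 0.2
    subscore_gain: float = 1.5

    # DRG expression fold effects (male only, per the study's direction)
    calca_l2_male_fold: float = 2.0
    tac1_l5_male_fold: float = 2.0

    # axial biomechanics (no injury effect by default)
    tensile_stiffness_n_mm: float = 80.0
    compressive_stiffness_n_mm: float = 150.0
    axial_hysteresis_n_mm: float = 0.5

    # torsional biomechanics, sex-specific
    male_torsional_stiffness: float = 3.0    # N*mm/deg
    female_torsional_stiffness: float = 2.4  # N*mm/deg
    torsional_hysteresis: float = 5.0        # N*mm*deg

    # creep ground truth (5-parameter viscoelastic solid)
    elastic_stiffness: float = 100.0  # N/mm
    fast_stiffness: float = 50.0      # N/mm
    slow_stiffness: float = 25.0      # N/mm
    fast_time_constant: float = 10.0  # s
    slow_time_constant: float = 600.0  # s

    # body weight (grams)
    male_weight_mean: float = 450.0
    male_weight_sd: float = 30.0
    male_weight_gain: float = 50.0
    female_weight_mean: float = 260.0
    female_weight_sd: float = 20.0
    female_weight_gain: float = 15.0

    def scaled(self, factor: float) -> "EffectConfig":
        """Return a copy with all *effect* magnitudes scaled (baselines kept)."""
        out = dataclasses.replace(self)
        out.male_threshold_drop_fold = self.male_threshold_drop_fold ** factor
        out.female_threshold_drop_fold = self.female_threshold_drop_fold ** factor
        out.height_loss_frac = self.height_loss_frac * factor
        out.subscore_gain = self.subscore_gain * factor
        out.calca_l2_male_fold = self.calca_l2_male_fold ** factor
        out.tac1_l5_male_fold = self.tac1_l5_male_fold ** factor
        return out


def _null_effects() -> "EffectConfig":
    """Effects with every group contrast removed (baselines equalised)."""
    e = EffectConfig()
    e.male_threshold_drop_fold = 1.0
    e.female_threshold_drop_fold = 1.0
    e.female_baseline_threshold_g = e.male_baseline_threshold_g
    e.height_loss_frac = 0.0
    e.subscore_gain = 0.0
    e.calca_l2_male_fold = 1.0
    e.tac1_l5_male_fold = 1.0
    e.female_torsional_stiffness = e.male_torsional_stiffness
    e.female_baseline_height_mm = e.male_baseline_height_mm
    e.female_weight_mean = e.male_weight_mean
    e.female_weight_sd = e.male_weight_sd
    e.female_weight_gain = e.male_weight_gain
    return e


@dataclass
class NoiseConfig:
    """Noise scales per raw signal.  All SDs; zero switches a source off."""

    latent_degeneration_sd: float = 0.15

    # von Frey: lognormal animal/week/paw scatter on latent threshold
    threshold_animal_sd_log_male: float = 0.15
    threshold_animal_sd_log_female: float = 0.60  # inflated female variability
    threshold_week_sd_log: float = 0.10
    threshold_paw_sd_log: float = 0.08
    response_slope: float = 8.0  # logistic slope in log-force units

    ct_sd: float = 0.30
    ct_outlier_rate: float = 0.02
    ct_outlier_shift: float = 4.0  # cycles added/subtracted for a wild value

    height_sd_mm: float = 0.03
    subscore_sd: float = 0.30

    biomech_cv: float = 0.05       # lognormal CV on every biomech property
    trace_disp_sd_mm: float = 0.002
    trace_torque_sd_nmm: float = 0.5
    creep_sd_mm: float = 0.005

    def all_zero(self) -> "NoiseConfig":
        """Every source off; the response curve becomes a deterministic step."""
        out = dataclasses.replace(self)
        for f in dataclasses.fields(out):
            setattr(out, f.name, 0.0)
        out.response_slope = float("inf")
        return out

    def scaled(self, factor: float) -> "NoiseConfig":
        out = dataclasses.replace(self)
        for f in dataclasses.fields(out):
            if f.name not in ("response_slope", "ct_outlier_shift"):
                setattr(out, f.name, getattr(out, f.name) * factor)
        return out


@dataclass
class StudyConfig:
    """Full design of one simulated study."""

    n_per_group: int = 12
    seed: int = 0
    #: (sex, injury_group, count) removed after generation, mimicking attrition
    exclusions: Sequence[tuple] = (("male", "injury", 1), ("female", "injury", 1))
    filament_forces: Sequence[float] = DEFAULT_FILAMENTS
    n_applications: int = 5
    timepoints_weeks: Sequence[int] = (0, 2, 4, 6)
    drg_levels: Sequence[str] = DRG_LEVELS
    ivd_levels: Sequence[str] = IVD_LEVELS
    punctured_levels: Sequence[str] = PUNCTURED_LEVELS
    n_raters: int = 3
    n_cohorts: int = 4  # surgery-date batches

    # test protocol parameters
    axial_load_n: float = 8.0
    torsion_amplitude_deg: float = 10.0
    n_cycles: int = 20
    cycle_frequency_hz: float = 1.0
    trace_sampling_hz: float = 100.0
    creep_load_n: float = -8.0
    creep_duration_s: float = 3600.0
    creep_sampling_hz: float = 1.0
    loop_shape: str = "bump"  # or "ellipse"

    effects: EffectConfig = field(default_factory=EffectConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def validate(self) -> None:
        f = list(self.filament_forces)
        if len(f) < 2 or any(b <= a for a, b in zip(f, f[1:])):
            raise ConfigurationError("filament_forces must be strictly increasing")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        for sex, group, count in self.exclusions:
            if sex not in SEXES or group not in INJURY_GROUPS or count < 0:
                raise ConfigurationError(f"bad exclusion entry: {(sex, group, count)}")
        for name in dataclasses.fields(self.noise):
            if getattr(self.noise, name.name) < 0:
                raise ConfigurationError(f"noise.{name.name} must be >= 0")
        for name in ("elastic_stiffness", "fast_stiffness", "slow_stiffness",
                     "fast_time_constant", "slow_time_constant"):
            if getattr(self.effects, name) <= 0:
                raise ConfigurationError(f"effects.{name} must be > 0")
        if self.loop_shape not in ("bump", "ellipse"):
            raise ConfigurationError("loop_shape must be 'bump' or 'ellipse'")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration (simulate -> reduce -> stats -> network)."""

    study: StudyConfig = field(default_factory=StudyConfig)
    cycle_index: int = 20
    fit_window_fraction: float = 0.2
    rout_q_percent: float = 1.0
    alpha: float = 0.05
    min_pairwise_n: int = 4
    out_dir: str = "results/pipeline"

    def validate(self) -> None:
        self.study.validate()
        if not (1 <= self.cycle_index <= self.study.n_cycles):
            raise ConfigurationError("cycle_index out of range")
        if not (0 < self.fit_window_fraction < 1):
            raise ConfigurationError("fit_window_fraction must be in (0,1)")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must be in (0,1]")


# ---------------------------------------------------------------------------
# (de)serialisation

def _to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def conv(v):
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        return v

    return conv(d)


def config_to_dict(cfg: PipelineConfig) -> dict:
    return _to_dict(cfg)


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    study = dict(d.pop("study", {}))
    effects = EffectConfig(**study.pop("effects", {}))
    noise = NoiseConfig(**study.pop("noise", {}))
    study["exclusions"] = [tuple(e) for e in study.get("exclusions", [])] or \
        StudyConfig().exclusions
    sc = StudyConfig(effects=effects, noise=noise, **study)
    cfg = PipelineConfig(study=sc, **d)
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
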