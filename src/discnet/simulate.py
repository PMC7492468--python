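"""Seeded synthetic study generator.

Emulates a 48-animal 2x2 (sex x injury) rat annular-puncture study: raw
compressive-creep curves, 20-cycle axial and torsional traces, von Frey
filament response tables at weeks 0/2/4/6, DRG Ct values for Calca/Tac1
against Gapdh over T13-L5, per-IVD radiographic heights at baseline and
6 weeks, 5-category histology subscores from 3 raters, estrous stage, body
weight and a surgery cohort index.

All signals derive from two per-animal latents:

* ``latent_degeneration`` = injury x (1 + noise) drives histology subscores
  and punctured-level height loss;
* ``latent_sensitivity`` (a log paw-withdrawal threshold) carries the
  sex-specific injury effect on mechanical allodynia.

Everything is driven by a single :class:`~discnet.config.StudyConfig`; the
same config plus the same seed reproduces the dataset bit-for-bit.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .biomech import CreepFitParams, creep_displacement
from .config import (
    ESTROUS_STAGES,
    GENES,
    HISTOLOGY_CATEGORIES,
    StudyConfig,
)

#: nominal Ct of each gene in an unaffected DRG (cycles)
BASE_CT = {"Gapdh": 18.0, "Calca": 22.0, "Tac1": 24.0}


@dataclass
class StudyDataset:
    """All raw per-animal records for one simulated (or imported) study."""

    config: StudyConfig
    animals: pd.DataFrame             # id, sex, injury, cohort, weights, estrous, latents
    filament_responses: pd.DataFrame  # animal_id, week, paw, force_g, response_count
    ct_records: pd.DataFrame          # animal_id, drg_level, gene, ct
    ivd_heights: pd.DataFrame         # animal_id, level, timepoint, height_mm
    histology: pd.DataFrame           # animal_id, rater, category, subscore
    cyclic_traces: pd.DataFrame       # animal_id, kind, time_s, primary, conjugate
    creep_curves: pd.DataFrame        # animal_id, time_s, displacement_mm, load_n
    truth: pd.DataFrame               # per-animal generator ground truth
    excluded_ids: list = field(default_factory=list)

    def check_consistency(self) -> None:
        """Every retained animal must carry every record type."""
        ids = set(self.animals["animal_id"])
        for name in ("filament_responses", "ct_records", "ivd_heights",
                     "histology", "cyclic_traces", "creep_curves", "truth"):
            have = set(getattr(self, name)["animal_id"])
            if have != ids:
                missing = ids ^ have
                raise ValueError(f"{name}: inconsistent animal ids {sorted(missing)}")
        kinds = self.cyclic_traces.groupby("animal_id")["kind"].nunique()
        if (kinds != 2).any():
            raise ValueError("every animal needs an axial and a torsional trace")


# ---------------------------------------------------------------------------
# raw-signal simulators

def simulate_creep_curve(params: CreepFitParams | tuple, load: float,
                         duration: float, sampling_hz: float,
                         noise_sd: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample a creep displacement curve from the 5-parameter solid model.

    Returns ``(time_s, displacement_mm)``; ``time`` includes both endpoints.
    """
    if isinstance(params, CreepFitParams):
        params = params.as_tuple()
    k_e, k_f, k_s, tau_f, tau_s = params
    if min(k_e, k_f, k_s, tau_f, tau_s) <= 0:
        raise ValueError("creep parameters must all be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(rng)
    n = int(round(duration * sampling_hz)) + 1
    t = np.arange(n) / sampling_hz
    d = creep_displacement(t, load, k_e, k_f, k_s, tau_f, tau_s)
    if noise_sd > 0:
        d = d + rng.normal(0.0, noise_sd, size=t.size)
    return t, d


def _hysteresis_bump(x, cutoff, area):
    """Quartic loop-opening profile, zero (value and slope) for |x| >= cutoff.

    ``2 * integral(w) == area`` so the closed loop encloses exactly ``area``;
    vanishing at the extremes keeps the outer-window branches exactly linear.
    """
    w0 = 15.0 * area / (32.0 * cutoff)
    u = np.clip(np.abs(x) / cutoff, 0.0, 1.0)
    return w0 * (1.0 - u ** 2) ** 2


def simulate_cyclic_trace(kind: str, properties: dict, n_cycles: int,
                          frequency_hz: float, sampling_hz: float,
                          hysteresis_area: float, noise_sd: float, rng,
                          loop_shape: str = "bump",
                          transient_amplitude: float = 0.0,
                          transient_tau_cycles: float = 3.0):
    """Generate one cyclic trace.

    ``kind='axial'``: load-controlled sinusoid at +/- ``amplitude`` (N);
    primary channel is displacement (mm) from the tension/compression branch
    stiffnesses ``tensile``/``compressive`` (N/mm).  ``kind='torsional'``:
    rotation-controlled at +/- ``amplitude`` (deg); conjugate torque (N*mm)
    from ``stiffness`` (N*mm/deg).

    Loop area is inserted either as a quartic opening confined to the central
    80% of the controlled range (``loop_shape='bump'``, exact closed-form
    area, end-range branches exactly linear) or as the classical elliptic
    phase lag (``loop_shape='ellipse'``, area pi*a*b).  An optional transient
    decays exponentially over the first cycles and is negligible by cycle 20
    with the default time constant.

    Returns ``(time_s, primary, conjugate)``.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if hysteresis_area < 0:
        raise ValueError("hysteresis_area must be >= 0")
    rng = np.random.default_rng(rng)
    n = int(round(n_cycles / frequency_hz * sampling_hz))
    t = np.arange(n) / sampling_hz
    omega = 2.0 * np.pi * frequency_hz
    phase_sign = np.cos(omega * t)  # >0 while the controlled channel rises

    amp = properties["amplitude"]
    ctrl = amp * np.sin(omega * t)

    if kind == "axial":
        k_t, k_c = properties["tensile"], properties["compressive"]
        derived = np.where(ctrl >= 0, ctrl / k_t, ctrl / k_c)
        if loop_shape == "bump":
            derived = derived - np.sign(phase_sign) * _hysteresis_bump(
                ctrl, 0.8 * amp, hysteresis_area) / 1.0
        else:  # ellipse: displacement lags the force
            derived = derived + (hysteresis_area / (np.pi * amp)) * np.cos(omega * t)
        primary, conjugate = derived, ctrl  # primary=displacement, conjugate=force
    elif kind == "torsional":
        k = properties["stiffness"]
        derived = k * ctrl
        if loop_shape == "bump":
            derived = derived - np.sign(phase_sign) * _hysteresis_bump(
                ctrl, 0.8 * amp, hysteresis_area)
        else:
            derived = derived + (hysteresis_area / (np.pi * amp)) * np.cos(omega * t)
        primary, conjugate = ctrl, derived  # primary=rotation, conjugate=torque
    else:
        raise ValueError(f"unknown trace kind {kind!r}")

    if transient_amplitude != 0.0:
        derived_idx = 0 if kind == "axial" else 1
        settle = transient_amplitude * np.exp(
            -t * frequency_hz / transient_tau_cycles)
        if derived_idx == 0:
            primary = primary + settle * np.sin(omega * t)
        else:
            conjugate = conjugate + settle * np.sin(omega * t)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=t.size)
        if kind == "axial":
            primary = primary + noise
        else:
            conjugate = conjugate + noise
    return t, primary, conjugate


def simulate_filament_responses(latent_threshold_g: float, filament_forces,
                                n_applications: int, slope: float, rng):
    """Binomial response counts per filament for one paw at one session.

    The per-application response probability is logistic in log-force,
    centred on the latent threshold; an infinite slope gives the
    deterministic step-function limit.
    """
    rng = np.random.default_rng(rng)
    forces = np.asarray(filament_forces, dtype=float)
    if latent_threshold_g <= 0:
        raise ValueError("latent threshold must be positive")
    if np.isinf(slope):
        p = (forces >= latent_threshold_g).astype(float)
    else:
        p = expit(slope * (np.log(forces) - np.log(latent_threshold_g)))
    counts = rng.binomial(n_applications, p)
    return forces, counts


# ---------------------------------------------------------------------------
# full study

def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _lognorm(rng, nominal, cv, size=None):
    if cv == 0:
        return nominal if size is None else np.full(size, nominal)
    return nominal * np.exp(rng.normal(0.0, cv, size=size))


def generate_study(config: StudyConfig) -> StudyDataset:
    """Generate a complete synthetic study; deterministic given config+seed."""
    config.validate()
    eff, noi = config.effects, config.noise
    (rng_animals, rng_vf, rng_ct, rng_h, rng_hist, rng_bio,
     rng_trace, rng_creep, rng_excl) = _spawn(config.seed, 9)

    # -- animals ------------------------------------------------------------
    rows = []
    idx = 0
    for sex in ("female", "male"):
        for group_i, group in enumerate(("sham", "injury")):
            for j in range(config.n_per_group):
                injury = group_i
                wmean = eff.female_weight_mean if sex == "female" else eff.male_weight_mean
                wsd = eff.female_weight_sd if sex == "female" else eff.male_weight_sd
                wgain = eff.female_weight_gain if sex == "female" else eff.male_weight_gain
                w0 = rng_animals.normal(wmean, wsd)
                w6 = w0 + wgain + rng_animals.normal(0.0, 0.3 * wsd)
                estrous = (ESTROUS_STAGES[rng_animals.integers(4)]
                           if sex == "female" else None)
                latent_deg = injury * (1.0 + rng_animals.normal(0.0, noi.latent_degeneration_sd))
                rows.append(dict(
                    animal_id=f"{sex[0].upper()}{group_i}{j:02d}",
                    sex=sex, injury_group=group, injury=injury,
                    surgery_date=idx % config.n_cohorts,
                    weight_preop=w0, weight_6wk=w6,
                    estrous_stage=estrous,
                    latent_degeneration=latent_deg,
                ))
                idx += 1
    animals = pd.DataFrame(rows)

    # -- von Frey -----------------------------------------------------------
    vf_rows, truth_thr = [], {}
    for _, a in animals.iterrows():
        if a.sex == "male":
            base, drop = eff.male_baseline_threshold_g, eff.male_threshold_drop_fold
            a_sd = noi.threshold_animal_sd_log_male
        else:
            base, drop = eff.female_baseline_threshold_g, eff.female_threshold_drop_fold
            a_sd = noi.threshold_animal_sd_log_female
        log_base = np.log(base) + rng_vf.normal(0.0, a_sd)
        for week in config.timepoints_weeks:
            shift = np.log(drop) * a.injury * (1 if week >= 2 else 0)
            log_t = log_base - shift + rng_vf.normal(0.0, noi.threshold_week_sd_log)
            truth_thr[(a.animal_id, week)] = np.exp(log_t)
            for paw in ("left", "right"):
                t_paw = np.exp(log_t + rng_vf.normal(0.0, noi.threshold_paw_sd_log))
                forces, counts = simulate_filament_responses(
                    t_paw, config.filament_forces, config.n_applications,
                    noi.response_slope, rng_vf)
                for fo, co in zip(forces, counts):
                    vf_rows.append(dict(animal_id=a.animal_id, week=week, paw=paw,
                                        force_g=fo, response_count=int(co)))
    filament_responses = pd.DataFrame(vf_rows)

    # -- qPCR Ct ------------------------------------------------------------
    ct_rows = []
    for _, a in animals.iterrows():
        for level in config.drg_levels:
            for gene in GENES:
                fold = 1.0
                if a.sex == "male" and a.injury:
                    if gene == "Calca" and level == "L2":
                        fold = eff.calca_l2_male_fold
                    elif gene == "Tac1" and level == "L5":
                        fold = eff.tac1_l5_male_fold
                ct = BASE_CT[gene] - np.log2(fold) + rng_ct.normal(0.0, noi.ct_sd)
                if gene != "Gapdh" and noi.ct_outlier_rate > 0 \
                        and rng_ct.random() < noi.ct_outlier_rate:
                    ct += noi.ct_outlier_shift * (1 if rng_ct.random() < 0.5 else -1)
                ct_rows.append(dict(animal_id=a.animal_id, drg_level=level,
                                    gene=gene, ct=ct))
    ct_records = pd.DataFrame(ct_rows)

    # -- radiographic IVD heights -------------------------------------------
    h_rows = []
    for _, a in animals.iterrows():
        base_h = (eff.female_baseline_height_mm if a.sex == "female"
                  else eff.male_baseline_height_mm)
        for level in config.ivd_levels:
            h0_true = base_h
            loss = (eff.height_loss_frac * a.latent_degeneration
                    if level in config.punctured_levels else 0.0)
            h6_true = h0_true * (1.0 - loss)
            h_rows.append(dict(animal_id=a.animal_id, level=level,
                               timepoint="baseline",
                               height_mm=h0_true + rng_h.normal(0.0, noi.height_sd_mm)))
            h_rows.append(dict(animal_id=a.animal_id, level=level,
                               timepoint="6wk",
                               height_mm=h6_true + rng_h.normal(0.0, noi.height_sd_mm)))
    ivd_heights = pd.DataFrame(h_rows)

    # -- histology subscores -------------------------------------------------
    hist_rows = []
    for _, a in animals.iterrows():
        target = np.clip(eff.subscore_base + eff.subscore_gain * a.latent_degeneration,
                         0.0, 2.0)
        for rater in range(1, config.n_raters + 1):
            for cat in HISTOLOGY_CATEGORIES:
                s = np.clip(np.round(target + rng_hist.normal(0.0, noi.subscore_sd)),
                            0, 2)
                hist_rows.append(dict(animal_id=a.animal_id, rater=rater,
                                      category=cat, subscore=float(s)))
    histology = pd.DataFrame(hist_rows)

    # -- biomechanics: per-animal truth + raw traces -------------------------
    truth_rows, trace_frames, creep_frames = [], [], []
    f0, th0 = config.axial_load_n, config.torsion_amplitude_deg
    for _, a in animals.iterrows():
        cv = noi.biomech_cv
        k_t = _lognorm(rng_bio, eff.tensile_stiffness_n_mm, cv)
        k_c = _lognorm(rng_bio, eff.compressive_stiffness_n_mm, cv)
        a_hyst = _lognorm(rng_bio, eff.axial_hysteresis_n_mm, cv)
        k_tor = _lognorm(rng_bio, eff.male_torsional_stiffness if a.sex == "male"
                         else eff.female_torsional_stiffness, cv)
        t_hyst = _lognorm(rng_bio, eff.torsional_hysteresis, cv)
        k_e = _lognorm(rng_bio, eff.elastic_stiffness, cv)
        k_f = _lognorm(rng_bio, eff.fast_stiffness, cv)
        k_s = _lognorm(rng_bio, eff.slow_stiffness, cv)
        tau_f = _lognorm(rng_bio, eff.fast_time_constant, cv)
        tau_s = _lognorm(rng_bio, eff.slow_time_constant, cv)

        t, d, f = simulate_cyclic_trace(
            "axial", dict(amplitude=f0, tensile=k_t, compressive=k_c),
            config.n_cycles, config.cycle_frequency_hz, config.trace_sampling_hz,
            a_hyst, noi.trace_disp_sd_mm, rng_trace, config.loop_shape)
        trace_frames.append(pd.DataFrame(dict(
            animal_id=a.animal_id, kind="axial", time_s=t, primary=d, conjugate=f)))
        t, th, tq = simulate_cyclic_trace(
            "torsional", dict(amplitude=th0, stiffness=k_tor),
            config.n_cycles, config.cycle_frequency_hz, config.trace_sampling_hz,
            t_hyst, noi.trace_torque_sd_nmm, rng_trace, config.loop_shape)
        trace_frames.append(pd.DataFrame(dict(
            animal_id=a.animal_id, kind="torsional", time_s=t, primary=th, conjugate=tq)))

        tc, dc = simulate_creep_curve(
            (k_e, k_f, k_s, tau_f, tau_s), config.creep_load_n,
            config.creep_duration_s, config.creep_sampling_hz,
            noi.creep_sd_mm, rng_creep)
        creep_frames.append(pd.DataFrame(dict(
            animal_id=a.animal_id, time_s=tc, displacement_mm=dc,
            load_n=config.creep_load_n)))

        total_disp = abs(creep_displacement(
            config.creep_duration_s, config.creep_load_n, k_e, k_f, k_s, tau_f, tau_s))
        tr = dict(
            animal_id=a.animal_id,
            tensile_stiffness=k_t, compressive_stiffness=k_c,
            axial_rom=f0 / k_t + f0 / k_c, axial_hysteresis=a_hyst,
            torsional_stiffness=k_tor, torque_range=2 * k_tor * th0,
            torsional_hysteresis=t_hyst,
            elastic_stiffness=k_e, fast_stiffness=k_f, slow_stiffness=k_s,
            fast_time_constant=tau_f, slow_time_constant=tau_s,
            total_displacement=total_disp,
        )
        for week in config.timepoints_weeks:
            tr[f"threshold_w{week}"] = truth_thr[(a.animal_id, week)]
        truth_rows.append(tr)

    truth = pd.DataFrame(truth_rows)
    cyclic_traces = pd.concat(trace_frames, ignore_index=True)
    creep_curves = pd.concat(creep_frames, ignore_index=True)

    # -- exclusions (attrition after generation) ----------------------------
    excluded = []
    for sex, group, count in config.exclusions:
        pool = animals.query("sex == @sex and injury_group == @group")["animal_id"]
        pool = [x for x in pool if x not in excluded]
        take = min(count, len(pool))
        excluded.extend(rng_excl.choice(pool, size=take, replace=False).tolist())

    def drop(df):
        return df[~df["animal_id"].isin(excluded)].reset_index(drop=True)

    ds = StudyDataset(
        config=config,
        animals=drop(animals),
        filament_responses=drop(filament_responses),
        ct_records=drop(ct_records),
        ivd_heights=drop(ivd_heights),
        histology=drop(histology),
        cyclic_traces=drop(cyclic_traces),
        creep_curves=drop(creep_curves),
        truth=drop(truth),
        excluded_ids=sorted(excluded),
    )
    ds.check_consistency()
    return ds


def null_study_config(seed: int = 0) -> StudyConfig:
    """A config with every group effect removed (for FDR-control studies)."""
    from .config import _null_effects
    cfg = StudyConfig(seed=seed, effects=_null_effects())
    return cfg
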