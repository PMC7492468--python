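"""Self-validation benchmarks: each routine re-runs a slice of the pipeline
under controlled conditions and measures how well the implementation recovers
known ground truth.  Used by the validation tests and the acceptance script.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import biomech
from .config import StudyConfig
from .network import bh_adjust, network_from_table
from .pipeline import reduce_biomech, reduce_dataset, trait_tables
from .simulate import generate_study, simulate_creep_curve

CREEP_TRUE = (100.0, 50.0, 25.0, 10.0, 600.0)  # k_e, k_f, k_s, tau_f, tau_s
CREEP_PARAM_NAMES = ("elastic_stiffness", "fast_stiffness", "slow_stiffness",
                     "fast_time_constant", "slow_time_constant")


def creep_recovery_errors(n_seeds: int = 20, noise_frac: float = 0.01,
                          seed: int = 0) -> dict:
    """Median absolute relative error per creep parameter over replicate fits.

    One-hour creep at -8 N sampled at 1 Hz, Gaussian noise with SD equal to
    ``noise_frac`` of the total displacement.
    """
    total = abs(biomech.creep_displacement(3600.0, -8.0, *CREEP_TRUE))
    errs = []
    for i in range(n_seeds):
        t, d = simulate_creep_curve(CREEP_TRUE, -8.0, 3600.0, 1.0,
                                    noise_frac * total, seed + i)
        fit = biomech.fit_creep_model(t, d, -8.0)
        errs.append([abs(g / v - 1.0) for g, v in zip(fit.as_tuple(), CREEP_TRUE)])
    med = np.median(errs, axis=0)
    return dict(zip(CREEP_PARAM_NAMES, med))


ROUNDTRIP_PROPS = ("tensile_stiffness", "compressive_stiffness", "axial_rom",
                   "torsional_stiffness", "torque_range",
                   "elastic_stiffness", "fast_stiffness", "slow_stiffness",
                   "fast_time_constant", "slow_time_constant",
                   "total_displacement")
ROUNDTRIP_AREAS = ("axial_hysteresis", "torsional_hysteresis")


def roundtrip_errors(seed: int = 0, trace_sampling_hz: float = 1000.0) -> dict:
    """Zero-noise generate -> reduce: max |relative error| vs ground truth.

    Stiffnesses, ROM and ranges are exact up to solver round-off; the loop
    areas are limited by shoelace discretisation (O(samples^-2)).
    """
    cfg = StudyConfig(seed=seed, n_per_group=1, exclusions=(),
                      trace_sampling_hz=trace_sampling_hz)
    cfg.noise = cfg.noise.all_zero()
    ds = generate_study(cfg)
    got = reduce_biomech(ds).set_index("animal_id")
    want = ds.truth.set_index("animal_id")
    out = {}
    for col in ROUNDTRIP_PROPS + ROUNDTRIP_AREAS:
        out[col] = float(np.max(np.abs(got[col] / want[col] - 1.0)))
    return out


def ellipse_area_error(n_samples: int = 1000, a: float = 0.7,
                       b: float = 6.0) -> float:
    """Relative error of the shoelace loop area on a sampled ellipse vs pi*a*b."""
    th = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    area = biomech.loop_area(a * np.cos(th), b * np.sin(th))
    return float(abs(area / (np.pi * a * b) - 1.0))


def null_fdp(n_studies: int = 50, n_traits: int = 30, n_animals: int = 24,
             alpha: float = 0.05, seed: int = 0) -> float:
    """Mean false-discovery proportion of declared edges over null studies.

    Traits are mutually independent Gaussians, so every declared edge is a
    false discovery; studies with no edges contribute FDP = 0.
    """
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_studies):
        tbl = pd.DataFrame(rng.normal(size=(n_animals, n_traits)),
                           columns=[f"t{i:02d}" for i in range(n_traits)])
        g, *_ = network_from_table(tbl, alpha=alpha)
        fdps.append(1.0 if g.number_of_edges() > 0 else 0.0)
    return float(np.mean(fdps))


def bh_oracle_max_abs_diff(n_vectors: int = 100, seed: int = 0) -> float:
    """Exact agreement of bh_adjust with a brute-force step-up oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.random(rng.integers(1, 40))
        m = p.size
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        prev = np.inf
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            prev = min(prev, m * p[i] / rank)
            q[i] = min(prev, 1.0)
        worst = max(worst, float(np.max(np.abs(bh_adjust(p) - q))))
    return worst


SEX_EDGES = (("injury", "vf_w6"), ("injury", "grade_total"),
             ("injury", "height_pct_punctured"))


def sex_dissociation_rates(n_replicates: int = 20, seed: int = 0,
                           alpha: float = 0.05) -> dict:
    """Edge-presence rates over replicate default studies, per sex.

    Returns the fraction of replicates whose male / female network contains
    the injury--(week-6 threshold), injury--grade and injury--height edges.
    """
    counts = {sex: {e: 0 for e in SEX_EDGES} for sex in ("male", "female")}
    for rep in range(n_replicates):
        ds = generate_study(StudyConfig(seed=seed + rep))
        tables = trait_tables(ds, reduce_dataset(ds))
        for sex, tbl in tables.items():
            g, *_ = network_from_table(tbl, alpha=alpha)
            for u, v in SEX_EDGES:
                if g.has_edge(u, v):
                    counts[sex][(u, v)] += 1
    return {sex: {f"{u}--{v}": c / n_replicates for (u, v), c in d.items()}
            for sex, d in counts.items()}
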