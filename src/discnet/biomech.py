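"""Reduction of biomechanical raw traces to scalar IVD properties.

Three test segments are reduced per motion segment:

* 20 cycles of axial tension-compression at +/-8 N, 1 Hz -> tensile and
  compressive stiffness, axial range of motion, axial hysteresis, all taken
  from the 20th loading cycle;
* 20 cycles of torsion at +/-10 deg, 1 Hz -> torsional stiffness, torque
  range, torsional hysteresis (20th cycle);
* 1 h of compressive creep at -8 N -> 5-parameter viscoelastic solid fit.

The creep model is the sum of an instantaneous elastic response and fast and
slow exponential phases, parameterised in stiffnesses::

    d(t) = F * [ 1/k_e + (1/k_f)(1 - exp(-t/tau_f)) + (1/k_s)(1 - exp(-t/tau_s)) ]

with F the signed applied load.  ``tau_f < tau_s`` is a labelling convention
enforced by relabeling after the fit.

End-range stiffness is the least-squares slope of the conjugate channel on
the primary channel over the loading-branch samples lying in the outer
``fit_fraction`` (default 20%) of the relevant extreme, a common convention
for end-range stiffness in spine biomechanics; the cited prior code does not
publish its formulas, so the window is configurable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares


class ReductionError(ValueError):
    """A trace cannot be reduced (too few samples, bad window, ...)."""


@dataclass
class AxialProperties:
    tensile_stiffness: float      # N/mm
    compressive_stiffness: float  # N/mm
    axial_rom: float              # mm
    axial_hysteresis: float       # N*mm (loop area)


@dataclass
class TorsionalProperties:
    torsional_stiffness: float    # N*mm/deg
    torque_range: float           # N*mm
    torsional_hysteresis: float   # N*mm*deg (loop area)


@dataclass
class CreepFitParams:
    """5-parameter viscoelastic solid fit result.

    ``total_displacement`` is the magnitude of the model displacement at the
    end of the test (the instantaneous elastic jump is included).
    """

    elastic_stiffness: float    # k_e, N/mm
    fast_stiffness: float       # k_f, N/mm
    slow_stiffness: float       # k_s, N/mm
    fast_time_constant: float   # tau_f, s
    slow_time_constant: float   # tau_s, s
    total_displacement: float   # mm, |d(t_end)|
    rmse: float = math.nan
    converged: bool = False

    def as_tuple(self):
        return (self.elastic_stiffness, self.fast_stiffness, self.slow_stiffness,
                self.fast_time_constant, self.slow_time_constant)


def creep_displacement(t, load, k_e, k_f, k_s, tau_f, tau_s):
    """Closed-form creep displacement of the 5-parameter solid under constant load."""
    t = np.asarray(t, dtype=float)
    return load * (1.0 / k_e
                   + (1.0 / k_f) * (1.0 - np.exp(-t / tau_f))
                   + (1.0 / k_s) * (1.0 - np.exp(-t / tau_s)))


# ---------------------------------------------------------------------------
# cyclic traces

def loop_area(x, y) -> float:
    """Orientation-independent shoelace area of a sampled closed loop.

    The loop is closed virtually if the first and last samples differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ReductionError("loop channels must have equal length")
    if x.size < 3:
        raise ReductionError("a loop needs at least 3 points")
    x2 = np.append(x, x[0])
    y2 = np.append(y, y[0])
    return abs(float(np.sum(x2[:-1] * y2[1:] - x2[1:] * y2[:-1])) / 2.0)


def extract_cycle(time, primary, conjugate, cycle_index, frequency_hz, n_cycles):
    """Return the samples of one cycle, windows from the nominal frequency.

    Cycle ``c`` covers ``[(c-1)/f, c/f)`` relative to the first sample.
    """
    if not (1 <= cycle_index <= n_cycles):
        raise ReductionError(
            f"cycle_index {cycle_index} out of range 1..{n_cycles}")
    time = np.asarray(time, dtype=float)
    t0 = time[0]
    lo = t0 + (cycle_index - 1) / frequency_hz
    hi = t0 + cycle_index / frequency_hz
    mask = (time >= lo) & (time < hi)
    if mask.sum() < 3:
        raise ReductionError("cycle window contains fewer than 3 samples")
    return time[mask], np.asarray(primary, float)[mask], np.asarray(conjugate, float)[mask]


def _branch_slope(primary, conjugate, window_mask, direction, deriv):
    """LS slope of conjugate on primary over loading-branch samples in a window."""
    mask = window_mask & (np.sign(deriv) == direction)
    if mask.sum() < 3:
        raise ReductionError("fewer than 3 samples in stiffness fit window")
    return float(np.polyfit(primary[mask], conjugate[mask], 1)[0])


def axial_properties(time, displacement, force, fit_fraction: float = 0.2) -> AxialProperties:
    """Reduce one axial force-displacement cycle.

    Tensile stiffness: slope of the loading branch (force rising) where the
    force lies within the top ``fit_fraction`` of the tensile extreme, i.e.
    ``F >= (1 - fit_fraction) * max(F)``; compressive stiffness mirrors this
    at the compressive extreme.
    """
    d = np.asarray(displacement, float)
    f = np.asarray(force, float)
    t = np.asarray(time, float)
    dfdt = np.gradient(f, t)
    fmax, fmin = f.max(), f.min()
    if fmax <= 0 or fmin >= 0:
        raise ReductionError("axial cycle must cross zero force")
    k_t = _branch_slope(d, f, f >= (1 - fit_fraction) * fmax, +1, dfdt)
    k_c = _branch_slope(d, f, f <= (1 - fit_fraction) * fmin, -1, dfdt)
    return AxialProperties(
        tensile_stiffness=k_t,
        compressive_stiffness=k_c,
        axial_rom=float(d.max() - d.min()),
        axial_hysteresis=loop_area(d, f),
    )


def torsional_properties(time, rotation, torque, fit_fraction: float = 0.2) -> TorsionalProperties:
    """Reduce one torque-rotation cycle.

    Stiffness is the loading-branch slope in the outer ``fit_fraction`` of
    each rotation extreme, averaged over the two directions.  A constant
    torque trace reduces to zero stiffness and zero torque range.
    """
    th = np.asarray(rotation, float)
    tq = np.asarray(torque, float)
    t = np.asarray(time, float)
    dth = np.gradient(th, t)
    thmax, thmin = th.max(), th.min()
    if thmax <= 0 or thmin >= 0 or np.ptp(tq) == 0:
        # degenerate (constant torque or one-sided rotation): no stiffness
        return TorsionalProperties(0.0, float(np.ptp(tq)), loop_area(th, tq))
    k_pos = _branch_slope(th, tq, th >= (1 - fit_fraction) * thmax, +1, dth)
    k_neg = _branch_slope(th, tq, th <= (1 - fit_fraction) * thmin, -1, dth)
    return TorsionalProperties(
        torsional_stiffness=(k_pos + k_neg) / 2.0,
        torque_range=float(tq.max() - tq.min()),
        torsional_hysteresis=loop_area(th, tq),
    )


# ---------------------------------------------------------------------------
# creep fit

_TAU_STARTS = ((2.0, 100.0), (10.0, 600.0), (50.0, 3000.0))


def _initial_stiffnesses(time, displacement, load):
    """Heuristic starts: elastic from the first sample, the rest split evenly."""
    d0 = displacement[0]
    k_e0 = abs(load / d0) if d0 != 0 else 1e3
    resid_compliance = displacement[-1] / load - 1.0 / k_e0
    if resid_compliance <= 0:
        resid_compliance = 0.5 / k_e0
    k0 = 2.0 / resid_compliance  # 1/k_f + 1/k_s split evenly
    return k_e0, k0, k0


def fit_creep_model(time, displacement, load,
                    init: Optional[CreepFitParams] = None) -> CreepFitParams:
    """Nonlinear least-squares fit of the 5-parameter creep model.

    Multi-start over a log-spaced grid of (tau_f, tau_s) initials; parameters
    are optimised in log-space (positivity by construction) and relabelled so
    that tau_f < tau_s.  A fit that fails from every start returns NaN
    parameters with ``converged=False`` rather than raising, so a failed
    animal propagates as a missing trait.
    """
    time = np.asarray(time, dtype=float)
    displacement = np.asarray(displacement, dtype=float)
    if time.size < 50:
        raise ReductionError("creep fit needs at least 50 samples")
    if load == 0:
        raise ReductionError("creep load must be nonzero")

    k_e0, k_f0, k_s0 = _initial_stiffnesses(time, displacement, load)
    starts = [(k_e0, k_f0, k_s0, tf, ts) for tf, ts in _TAU_STARTS]
    if init is not None:
        starts.insert(0, init.as_tuple())

    def resid(logp):
        k_e, k_f, k_s, tf, ts = np.exp(logp)
        return creep_displacement(time, load, k_e, k_f, k_s, tf, ts) - displacement

    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, np.log(np.asarray(p0, float)),
                                method="lm", max_nfev=2000)
        except Exception:
            continue
        rmse = float(np.sqrt(np.mean(sol.fun ** 2)))
        if np.isfinite(rmse) and (best is None or rmse < best[0]):
            best = (rmse, sol)
    if best is None:
        return CreepFitParams(*([math.nan] * 6), rmse=math.nan, converged=False)

    rmse, sol = best
    k_e, k_f, k_s, tf, ts = np.exp(sol.x)
    if tf > ts:  # canonical labelling: fast phase has the smaller time constant
        k_f, k_s, tf, ts = k_s, k_f, ts, tf
    d_end = creep_displacement(time[-1], load, k_e, k_f, k_s, tf, ts)
    return CreepFitParams(
        elastic_stiffness=float(k_e), fast_stiffness=float(k_f),
        slow_stiffness=float(k_s), fast_time_constant=float(tf),
        slow_time_constant=float(ts), total_displacement=float(abs(d_end)),
        rmse=rmse, converged=bool(sol.success),
    )
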