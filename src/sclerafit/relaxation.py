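"""Estimation pipeline: raw load-displacement traces -> per-step (H+A, k).

The pipeline mirrors the experimental protocol: a tare preload flattens
the sample (defining the post-tare thickness against which strains are
measured), then cumulative ramp-hold strain steps are applied.  Each
step is segmented out of the trace and fit independently.  The
equilibrium modulus comes from the equilibrated load in closed form;
the transient pair (H+A, k) is recovered by nonlinear least squares
against the forward model.

Conventions (documented defaults):

* the equilibrium window is the last 10% of each hold; a hold counts as
  equilibrated when the |load slope| is below 0.5% of (peak - equilibrium)
  per 100 s;
* fits use the incremental convention: each step is fit on the strain
  increment and on loads relative to the previous step's equilibrium
  (a ``convention="total"`` switch fits cumulative strain/loads instead);
* parameters are fit in log space (positivity), with a deterministic
  initialization from the 63%-relaxation time and peak/equilibrium
  ratio plus fixed +-1/2-decade multistarts in k; no randomness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress

from .poroelastic import (
    CLEParameters,
    LoadingProgram,
    RelaxationTrace,
    SampleGeometry,
    StrainStep,
    load_history,
    series_roots,
)

__all__ = [
    "TareResult",
    "StepSegment",
    "StepEstimate",
    "detect_tare_and_thickness",
    "segment_steps",
    "fit_step",
    "fit_sample",
]

# equilibration rule: |dF/dt| < EQUIL_SLOPE_FRAC * (peak - equilibrium) / 100 s
EQUIL_SLOPE_FRAC = 0.005
# transient is uninformative below this peak/equilibrium ratio
MIN_PEAK_RATIO = 1.02


class TareResult(NamedTuple):
    thickness: float
    t_tare_end: float
    drift_warning: bool


@dataclass
class StepSegment:
    """One segmented ramp-hold step of a trace."""

    index: int
    target_strain: float
    applied_strain: float  # cumulative, measured from displacement
    strain_increment: float
    ramp_window: tuple[float, float]
    hold_window: tuple[float, float]
    equilibrium_load: float
    prev_equilibrium_load: float
    baseline_displacement: float
    flags: list[str] = field(default_factory=list)


@dataclass
class StepEstimate:
    """Fitted material parameters for one strain step."""

    step: int
    H_plus_A_hat: float = math.nan
    k_hat: float = math.nan
    H_minus_A_hat: float = math.nan
    applied_strain: float = math.nan
    strain_increment: float = math.nan
    rms_residual: float = math.nan
    converged: bool = False
    flags: list[str] = field(default_factory=list)


def _rate(time: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.gradient(y, time)


def detect_tare_and_thickness(
    trace: RelaxationTrace, tare_load: float = 500e-6
) -> TareResult:
    """Locate the end of the tare phase and the post-tare platen gap.

    The post-tare thickness is ``nominal_thickness`` (the gap at first
    platen contact) minus the displacement at tare equilibrium.  A
    residual load drift in the tare hold is flagged but does not abort.
    """
    if trace.nominal_thickness is None:
        raise ValueError("trace has no nominal thickness metadata")
    above = np.flatnonzero(trace.load >= tare_load)
    if above.size == 0:
        raise ValueError(
            f"tare never reached: max load {trace.load.max():.3g} N < "
            f"tare {tare_load:.3g} N"
        )
    i_tare = int(above[0])
    # the first strain ramp after tare shows up as a displacement-rate burst;
    # noise can make the load cross the tare threshold while the approach is
    # still moving, so skip past any ongoing motion first
    rate = _rate(trace.time, trace.displacement)
    n = len(trace.time)
    scale = np.abs(rate[i_tare:]).max()
    if scale <= 0:
        i_ramp = n - 1
    else:
        moving_mask = np.abs(rate) > 0.25 * scale
        i = i_tare
        while i < n and moving_mask[i]:
            i += 1
        i_tare = min(i, n - 1)
        moving = np.flatnonzero(moving_mask[i_tare:])
        i_ramp = (i_tare + moving[0]) if moving.size else n - 1
    lo = i_tare + (i_ramp - i_tare) // 2
    window = slice(max(lo, i_tare), max(i_ramp, i_tare + 1))
    disp_eq = float(np.median(trace.displacement[window]))
    thickness = trace.nominal_thickness - disp_eq

    drift = False
    tw, lw = trace.time[window], trace.load[window]
    if len(tw) >= 3 and np.ptp(tw) > 0:
        slope = linregress(tw, lw).slope
        drift = abs(slope) > EQUIL_SLOPE_FRAC * tare_load / 100.0
    return TareResult(thickness=thickness, t_tare_end=float(trace.time[i_ramp]), drift_warning=drift)


def _detect_ramps(
    time: np.ndarray, disp: np.ndarray, t_start: float, n_expected: int
) -> list[tuple[int, int]]:
    """Contiguous displacement-rate bursts after ``t_start`` (index pairs)."""
    rate = _rate(time, disp)
    active = (np.abs(rate) > 0.25 * np.abs(rate[time >= t_start]).max()) & (
        time >= t_start
    )
    ramps: list[tuple[int, int]] = []
    i = 0
    n = len(time)
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            ramps.append((i, j))
            i = j + 1
        else:
            i += 1
    return ramps


def segment_steps(
    trace: RelaxationTrace,
    program: LoadingProgram,
    *,
    thickness: float | None = None,
    t_tare_end: float | None = None,
    baseline_displacement: float | None = None,
) -> list[StepSegment]:
    """Split a trace into one :class:`StepSegment` per programmed step.

    When tare bookkeeping is not supplied it is detected from the trace
    (if the trace starts below the tare load) or the trace is assumed to
    start post-tare at time zero.
    """
    if thickness is None or t_tare_end is None:
        if trace.load[0] < program.tare_load and np.any(
            trace.load >= program.tare_load
        ):
            tare = detect_tare_and_thickness(trace, program.tare_load)
            thickness = tare.thickness
            t_tare_end = tare.t_tare_end
        else:
            if trace.nominal_thickness is None:
                raise ValueError("thickness unavailable: no metadata and no tare phase")
            thickness = trace.nominal_thickness
            t_tare_end = float(trace.time[0])
    i0 = int(np.searchsorted(trace.time, t_tare_end))
    i0 = min(i0, len(trace.time) - 1)
    if baseline_displacement is None:
        baseline_displacement = float(trace.displacement[i0])
    # loads are measured on top of the tare preload: the baseline for the
    # first step's incremental fit is the load just before its ramp
    baseline_load = float(np.median(trace.load[max(i0 - 5, 0) : i0 + 1]))

    ramps = _detect_ramps(trace.time, trace.displacement, t_tare_end, len(program.steps))
    if len(ramps) < len(program.steps):
        raise ValueError(
            f"detected {len(ramps)} ramps but program has {len(program.steps)} steps"
        )
    ramps = ramps[: len(program.steps)]

    segments: list[StepSegment] = []
    prev_eq = baseline_load
    prev_strain = 0.0
    for idx, (step, (i0, i1)) in enumerate(zip(program.steps, ramps), start=1):
        hold_start = i1 + 1
        hold_end = ramps[idx][0] - 1 if idx < len(ramps) else len(trace.time) - 1
        t_hold0, t_hold1 = trace.time[hold_start], trace.time[hold_end]
        # equilibrium window: last 10% of the hold
        t_eq = t_hold1 - 0.10 * (t_hold1 - t_hold0)
        eq_sl = (trace.time >= t_eq) & (trace.time <= t_hold1)
        eq_load = float(np.mean(trace.load[eq_sl]))
        applied = (
            float(np.mean(trace.displacement[eq_sl])) - baseline_displacement
        ) / thickness

        flags: list[str] = []
        if not (0.5 * step.target_strain <= applied <= 1.5 * step.target_strain):
            flags.append("applied_strain_out_of_band")
        peak = float(np.max(trace.load[i0 : hold_end + 1]))
        tw, lw = trace.time[eq_sl], trace.load[eq_sl]
        if len(tw) >= 3 and np.ptp(tw) > 0:
            slope = linregress(tw, lw).slope
            if abs(slope) > EQUIL_SLOPE_FRAC * max(peak - eq_load, 0.0) / 100.0:
                flags.append("not_equilibrated")
        if eq_load <= prev_eq:
            flags.append("non_increasing_equilibrium")

        segments.append(
            StepSegment(
                index=idx,
                target_strain=step.target_strain,
                applied_strain=applied,
                strain_increment=applied - prev_strain,
                ramp_window=(float(trace.time[i0]), float(trace.time[i1])),
                hold_window=(float(t_hold0), float(t_hold1)),
                equilibrium_load=eq_load,
                prev_equilibrium_load=prev_eq,
                baseline_displacement=baseline_displacement,
                flags=flags,
            )
        )
        prev_eq = eq_load
        prev_strain = applied
    return segments


def _initial_guess(
    t: np.ndarray, y: np.ndarray, eq: float, h_minus: float, geom: SampleGeometry
) -> tuple[float, float]:
    """Deterministic (H+A, k) initialization from the relaxation shape."""
    alpha1 = series_roots(1)[0]
    peak_idx = int(np.argmax(y))
    peak = y[peak_idx]
    ratio = peak / eq if eq > 0 else 2.0
    # finite-ramp peak ~ (H- + H+/2) * eps: invert for H+
    h_plus0 = max(2.0 * (ratio - 1.0) * h_minus, 0.05 * h_minus)
    target = eq + 0.37 * (peak - eq)
    after = np.flatnonzero(y[peak_idx:] <= target)
    t63 = (t[peak_idx + after[0]] - t[peak_idx]) if after.size else (t[-1] - t[peak_idx])
    t63 = max(t63, t[1] - t[0])
    t_g0 = alpha1**2 * t63
    k0 = geom.radius**2 / (h_plus0 * t_g0)
    return h_plus0, k0


def fit_step(
    segment: StepSegment,
    trace: RelaxationTrace,
    geom: SampleGeometry,
    *,
    convention: str = "incremental",
    n_terms: int = 120,
) -> StepEstimate:
    """Fit (H+A, k, H-A) to one segmented ramp-hold step.

    H-A comes from the equilibrium load in closed form; (H+A, k) minimize
    the least-squares load residual of the forward model over ramp+hold
    (first two ramp samples excluded).  Deterministic given the trace.
    """
    if convention not in ("incremental", "total"):
        raise ValueError(f"unknown convention {convention!r}")
    est = StepEstimate(step=segment.index, flags=list(segment.flags))

    t0, t_end = segment.ramp_window[0], segment.hold_window[1]
    sel = (trace.time >= t0) & (trace.time <= t_end)
    t = trace.time[sel] - t0
    load = trace.load[sel]
    if convention == "incremental":
        y = load - segment.prev_equilibrium_load
        strain = segment.strain_increment
        eq = segment.equilibrium_load - segment.prev_equilibrium_load
    else:
        y = load.copy()
        strain = segment.applied_strain
        eq = segment.equilibrium_load
    if not np.all(np.isfinite(y)):
        est.flags.append("non_finite_samples")
        return est
    n_hold = int(np.sum(t > (segment.ramp_window[1] - t0)))
    if n_hold < 30:
        est.flags.append("hold_too_short")
        return est
    if eq <= 0 or strain <= 0:
        est.flags.append("non_positive_equilibrium")
        return est

    est.applied_strain = segment.applied_strain
    est.strain_increment = segment.strain_increment
    est.H_minus_A_hat = eq / (strain * geom.area)

    peak = float(np.max(y))
    if peak / eq < MIN_PEAK_RATIO:
        est.flags.append("insufficient transient")
        return est

    ramp_dur = segment.ramp_window[1] - segment.ramp_window[0]
    hold_dur = t_end - segment.ramp_window[1]
    program = LoadingProgram(
        tare_load=0.0,
        steps=(StrainStep(strain, max(ramp_dur, 1e-6), max(hold_dur, 1e-6)),),
    )
    h_minus = est.H_minus_A_hat
    mask = np.ones(len(t), dtype=bool)
    mask[:2] = False  # actuator transients at ramp start

    def residuals(theta: np.ndarray) -> np.ndarray:
        params = CLEParameters(
            H_plus_A=math.exp(theta[0]), H_minus_A=h_minus, k=math.exp(theta[1])
        )
        model = load_history(params, geom, program, t[mask], n_terms=n_terms)
        return model - y[mask]

    h0, k0 = _initial_guess(t, y, eq, h_minus, geom)
    best = None
    for k_mult in (1.0, 10**-0.5, 10**0.5):
        res = least_squares(
            residuals,
            x0=[math.log(h0), math.log(k0 * k_mult)],
            method="lm",
            xtol=1e-12,
            ftol=1e-12,
        )
        if best is None or res.cost < best.cost:
            best = res

    est.H_plus_A_hat = math.exp(best.x[0])
    est.k_hat = math.exp(best.x[1])
    est.rms_residual = float(np.sqrt(np.mean(best.fun**2)))
    est.converged = bool(best.success)
    if not (1e2 < est.H_plus_A_hat < 1e9) or not (1e-19 < est.k_hat < 1e-9):
        est.flags.append("parameter_at_bound")
        est.converged = False
    return est


def fit_sample(
    trace: RelaxationTrace,
    geom: SampleGeometry,
    program: LoadingProgram,
    *,
    convention: str = "incremental",
) -> list[StepEstimate]:
    """Fit every programmed step of one trace, independently.

    Per-step failures are reported in the returned estimates (with
    ``converged=False`` and a flag) without aborting the other steps.
    """
    segments = segment_steps(trace, program)
    estimates: list[StepEstimate] = []
    for seg in segments:
        try:
            estimates.append(fit_step(seg, trace, geom, convention=convention))
        except Exception as exc:  # keep going; record the failure
            est = StepEstimate(step=seg.index, flags=[f"fit_error: {exc}"])
            estimates.append(est)
    return estimates
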