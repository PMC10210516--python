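"""Forward model of biphasic unconfined-compression stress relaxation.

A saturated cylindrical tissue disc is compressed axially between
impermeable, frictionless platens while interstitial fluid drains
radially through the free lateral edge.  The solid skeleton is
transversely isotropic about the loading axis with different effective
moduli in the (tensile) radial/hoop directions and the (compressive)
axial direction, capturing the tension-compression asymmetry of
fiber-reinforced tissue.

Governing system (axisymmetric, small strain, compression-positive
convention):

    sigma_rr = C11 e_rr + C12 e_tt + C13 e_zz - p
    sigma_tt = C12 e_rr + C11 e_tt + C13 e_zz - p
    sigma_zz = C13 (e_rr + e_tt) + C33 e_zz - p
    dp/dr    = C11 d(phi)/dr                 (radial equilibrium)
    d(phi + e_zz)/dt = k C11 lap_r(phi)      (mixture continuity + Darcy)

with ``phi = (1/r) d(r u)/dr`` the in-plane dilatation of the radial
solid displacement u, ``C11 = H_plus_A``, ``C33 = H_minus_A`` and
``C12 = C13 = lambda_offdiag``.  Boundary conditions: p = 0 and zero
total radial stress at r = a, regularity at r = 0.  The axial load is
``F(t) = 2 pi int sigma_zz r dr``.

With ``lambda_offdiag = 0`` the transient depends on (H_plus_A, k) only
and each hold equilibrates to ``H_minus_A * strain * area``; this is the
configuration used for parameter estimation.  ``simulate_response``
evaluates the semi-analytic Bessel-series solution; ``fd_oracle_response``
is an independent finite-difference reference solver that additionally
supports a nonzero off-diagonal modulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import brentq

__all__ = [
    "SampleGeometry",
    "CLEParameters",
    "StrainStep",
    "LoadingProgram",
    "RelaxationTrace",
    "equilibrium_load",
    "characteristic_time",
    "load_history",
    "simulate_response",
    "fd_oracle_response",
    "series_roots",
    "NumericalStabilityError",
]


class NumericalStabilityError(RuntimeError):
    """Raised when the finite-difference solver produces NaN/Inf."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SampleGeometry:
    """Cylindrical sample geometry (SI units).

    The default radius corresponds to a 1-mm biopsy punch; thickness is
    the post-tare platen gap against which strains are computed.
    """

    radius: float = 0.5e-3
    thickness: float = 200e-6

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not self.thickness > 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")

    @property
    def area(self) -> float:
        """Cross-sectional area pi * radius**2 (m^2)."""
        return math.pi * self.radius**2


@dataclass(frozen=True)
class CLEParameters:
    """Material parameters of the conewise-linear biphasic disc.

    Parameters
    ----------
    H_plus_A:
        In-plane (radial/circumferential) aggregate tensile modulus, Pa.
    H_minus_A:
        Axial aggregate compressive (equilibrium) modulus, Pa.
    k:
        Hydraulic conductivity, m^4 N^-1 s^-1 (== m^2 Pa^-1 s^-1).
    lambda_offdiag:
        Off-diagonal coupling modulus C12 = C13, Pa.  Default 0, which
        decouples the transient (H_plus_A, k) from the equilibrium
        response (H_minus_A).
    """

    H_plus_A: float
    H_minus_A: float
    k: float
    lambda_offdiag: float = 0.0

    def __post_init__(self) -> None:
        for name in ("H_plus_A", "H_minus_A", "k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.lambda_offdiag < 0:
            raise ValueError(f"lambda_offdiag must be >= 0, got {self.lambda_offdiag}")
        if not np.isfinite(self.H_plus_A * self.k):
            raise ValueError("gel diffusivity H_plus_A * k is not finite")


@dataclass(frozen=True)
class StrainStep:
    """One ramp-hold step: ramp to ``target_strain`` (cumulative), then hold."""

    target_strain: float
    ramp_duration: float
    hold_duration: float

    def __post_init__(self) -> None:
        if not 0 < self.target_strain < 0.5:
            raise ValueError(f"target_strain out of range: {self.target_strain}")
        if not self.ramp_duration > 0:
            raise ValueError("ramp_duration must be positive")
        if not self.hold_duration > 0:
            raise ValueError("hold_duration must be positive")


def _default_steps() -> tuple[StrainStep, ...]:
    return tuple(
        StrainStep(target_strain=s, ramp_duration=10.0, hold_duration=1500.0)
        for s in (0.05, 0.10, 0.15)
    )


@dataclass(frozen=True)
class LoadingProgram:
    """Tare preload plus an ordered sequence of cumulative strain steps."""

    tare_load: float = 500e-6
    steps: tuple[StrainStep, ...] = field(default_factory=_default_steps)

    def __post_init__(self) -> None:
        if self.tare_load < 0:
            raise ValueError("tare_load must be >= 0")
        if not self.steps:
            raise ValueError("program must contain at least one step")
        strains = [s.target_strain for s in self.steps]
        if any(b <= a for a, b in zip(strains, strains[1:])):
            raise ValueError(f"step strains must be strictly increasing: {strains}")

    @property
    def duration(self) -> float:
        return sum(s.ramp_duration + s.hold_duration for s in self.steps)

    def ramps(self) -> list[tuple[float, float, float]]:
        """Piecewise-linear strain schedule as (t_start, t_end, rate)."""
        out = []
        t = 0.0
        prev = 0.0
        for s in self.steps:
            rate = (s.target_strain - prev) / s.ramp_duration
            out.append((t, t + s.ramp_duration, rate))
            t += s.ramp_duration + s.hold_duration
            prev = s.target_strain
        return out

    def strain_at(self, t: np.ndarray) -> np.ndarray:
        """Cumulative engineering compressive strain at times ``t``."""
        t = np.asarray(t, dtype=float)
        eps = np.zeros_like(t)
        for t0, t1, rate in self.ramps():
            eps += rate * (np.clip(t, t0, t1) - t0)
        return eps


@dataclass
class RelaxationTrace:
    """Time-stamped load/displacement record of one compression test.

    ``displacement`` is the platen position relative to first platen
    contact (compression positive, meters); ``load`` is the axial force
    in newtons.  ``nominal_thickness`` is the platen gap at first
    contact, used downstream to recover the post-tare thickness.
    """

    time: np.ndarray
    displacement: np.ndarray
    load: np.ndarray
    sample_id: str = "sample"
    nominal_thickness: float | None = None
    radius: float | None = None
    temperature: float = 37.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        if not (len(self.time) == len(self.load) == len(self.displacement)):
            raise ValueError("time, displacement and load must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


# --------------------------------------------------------------------------
# closed forms


def equilibrium_load(params: CLEParameters, strain: float, geom: SampleGeometry) -> float:
    """Equilibrated axial load (N) after full stress relaxation.

    With zero off-diagonal modulus this is ``H_minus_A * strain * area``,
    independent of H_plus_A and k.  A nonzero coupling modulus softens
    the equilibrium through lateral expansion.
    """
    if not 0 < strain < 0.5:
        raise ValueError(f"strain must lie in (0, 0.5), got {strain}")
    c11, c12 = params.H_plus_A, params.lambda_offdiag
    c13, c33 = params.lambda_offdiag, params.H_minus_A
    modulus = c33 - 2.0 * c13**2 / (c11 + c12)
    return modulus * strain * geom.area


def characteristic_time(params: CLEParameters, geom: SampleGeometry) -> float:
    """Gel diffusion time radius**2 / (H_plus_A * k), seconds."""
    return geom.radius**2 / (params.H_plus_A * params.k)


# --------------------------------------------------------------------------
# semi-analytic series solution (lambda_offdiag == 0)

_ROOT_CACHE: dict[int, np.ndarray] = {}


def series_roots(n: int = 120) -> np.ndarray:
    """First ``n`` positive roots of ``alpha*J0(alpha) = J1(alpha)``.

    The m-th root lies strictly between consecutive zeros of J1, which
    gives certain brackets for Brent's method.
    """
    if n in _ROOT_CACHE:
        return _ROOT_CACHE[n]
    j1_zeros = np.concatenate([[1e-9], special.jn_zeros(1, n)])
    f = lambda a: a * special.j0(a) - special.j1(a)
    roots = np.array(
        [brentq(f, j1_zeros[m] + 1e-9, j1_zeros[m + 1] - 1e-9) for m in range(n)]
    )
    _ROOT_CACHE[n] = roots
    return roots


def _phi_integral(tau: np.ndarray, params: CLEParameters, geom: SampleGeometry,
                  n_terms: int) -> np.ndarray:
    """Integral of the unit-strain step-load response over [0, tau].

    The step response per unit strain is
        G(t) = area * (H_minus + H_plus * sum_n c_n exp(-alpha_n^2 t/t_g))
    with c_n = 1/(alpha_n^2 - 1) (sum 1/2: the instantaneous modulus is
    H_minus + H_plus/2); this returns int_0^tau G(s) ds, clipped to zero
    for tau <= 0, which is the Duhamel kernel for piecewise-linear
    strain programs.
    """
    alpha = series_roots(n_terms)
    c = 1.0 / (alpha**2 - 1.0)
    tg = characteristic_time(params, geom)
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, None)
    lam = alpha**2 / tg
    # (tau, n) outer product; terms decay ~ n^-4 so 120 terms is ample
    expm = -np.expm1(-np.outer(tau, lam))
    transient = expm @ (c / lam)
    return geom.area * (params.H_minus_A * tau + params.H_plus_A * transient)


def load_history(
    params: CLEParameters,
    geom: SampleGeometry,
    program: LoadingProgram,
    times: np.ndarray,
    n_terms: int = 120,
) -> np.ndarray:
    """Series-solution axial load (N) at arbitrary times for a strain program.

    Requires ``lambda_offdiag == 0``; use the finite-difference solver
    for the coupled case.
    """
    if params.lambda_offdiag != 0.0:
        raise NotImplementedError(
            "series solution requires lambda_offdiag == 0; use fd_oracle_response"
        )
    t = np.asarray(times, dtype=float)
    load = np.zeros_like(t)
    for t0, t1, rate in program.ramps():
        load += rate * (
            _phi_integral(t - t0, params, geom, n_terms)
            - _phi_integral(t - t1, params, geom, n_terms)
        )
    return load


def simulate_response(
    params: CLEParameters,
    geom: SampleGeometry,
    program: LoadingProgram,
    sampling_rate: float = 2.0,
    n_terms: int = 120,
) -> RelaxationTrace:
    """Semi-analytic axial load history for a ramp-hold strain program.

    Ramps are finite-duration linear displacement ramps superposed by
    Duhamel's principle on the instantaneous-step solution.  Loads are
    relative to the tare baseline (the tare state is the reference
    configuration).
    """
    min_ramp = min(s.ramp_duration for s in program.steps)
    if sampling_rate * min_ramp < 2.0:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz gives fewer than 2 samples over a "
            f"{min_ramp} s ramp"
        )
    n_samples = int(round(program.duration * sampling_rate)) + 1
    t = np.arange(n_samples) / sampling_rate
    load = load_history(params, geom, program, t, n_terms=n_terms)
    strain = program.strain_at(t)
    return RelaxationTrace(
        time=t,
        displacement=strain * geom.thickness,
        load=load,
        nominal_thickness=geom.thickness,
        radius=geom.radius,
    )


# --------------------------------------------------------------------------
# finite-difference oracle


def fd_oracle_response(
    params: CLEParameters,
    geom: SampleGeometry,
    program: LoadingProgram,
    n_radial: int = 120,
    dt: float | None = None,
    sampling_rate: float = 2.0,
    theta: float = 0.5,
) -> RelaxationTrace:
    """Finite-difference reference solution of the same boundary-value problem.

    Solves the radial diffusion equation for the in-plane dilatation
    ``phi`` with a theta-scheme in time (default Crank-Nicolson).  The
    lateral stress-free boundary couples ``phi(a)`` to the radial
    displacement ``u(a) = (1/a) int r phi dr``, implemented as a dense
    boundary row in the otherwise tridiagonal system; the system matrix
    is constant so it is factorized once.

    Supports nonzero ``lambda_offdiag``.
    """
    if n_radial < 50:
        raise ValueError(f"n_radial must be >= 50, got {n_radial}")
    a = geom.radius
    c11, c12 = params.H_plus_A, params.lambda_offdiag
    c13, c33 = params.lambda_offdiag, params.H_minus_A
    diffusivity = c11 * params.k
    tg = a**2 / diffusivity

    if dt is None:
        min_ramp = min(s.ramp_duration for s in program.steps)
        dt = min(tg / 400.0, min_ramp / 50.0)
    n_t = int(math.ceil(program.duration / dt)) + 1
    times = np.arange(n_t) * dt
    eps = program.strain_at(times)

    nr = n_radial
    dr = a / nr
    r = np.arange(nr + 1) * dr

    # trapezoid weights for u(a) = (1/a) * int_0^a r phi dr
    w = np.full(nr + 1, dr)
    w[0] = w[-1] = dr / 2.0
    u_row = w * r / a

    # interior Laplacian rows of L (axisymmetric), L phi ~ (1/r)(r phi')'
    L = np.zeros((nr + 1, nr + 1))
    L[0, 0], L[0, 1] = -4.0 / dr**2, 4.0 / dr**2
    for i in range(1, nr):
        rp, rm = r[i] + dr / 2.0, r[i] - dr / 2.0
        L[i, i - 1] = rm / (r[i] * dr**2)
        L[i, i] = -(rp + rm) / (r[i] * dr**2)
        L[i, i + 1] = rp / (r[i] * dr**2)

    # theta-scheme matrices on interior+center rows; boundary row is algebraic:
    #   phi_N - ((c11-c12)/c11) u(a)/a = -(c13/c11) eps
    A = np.eye(nr + 1) - theta * dt * diffusivity * L
    B = np.eye(nr + 1) + (1.0 - theta) * dt * diffusivity * L
    A[nr, :] = -((c11 - c12) / c11) * u_row / a
    A[nr, nr] += 1.0
    B[nr, :] = 0.0

    lu = lu_factor(A)
    phi = np.zeros(nr + 1)
    # consistent initial boundary value (eps=0 -> phi=0 already)
    loads = np.zeros(n_t)
    sig_w = 2.0 * math.pi * w * r  # quadrature for F = 2 pi int sigma_zz r dr

    def axial_load(phi_vec: np.ndarray, eps_now: float) -> float:
        p = c11 * (phi_vec - phi_vec[-1])
        sigma_zz = c13 * phi_vec + c33 * eps_now - p
        return float(sig_w @ sigma_zz)

    loads[0] = axial_load(phi, eps[0])
    for n in range(1, n_t):
        rhs = B @ phi
        deps = eps[n] - eps[n - 1]
        rhs[: nr] -= deps  # source -d(eps)/dt, integrated over dt
        rhs[nr] = -(c13 / c11) * eps[n]
        phi = lu_solve(lu, rhs)
        if not np.all(np.isfinite(phi)):
            raise NumericalStabilityError(
                f"finite-difference solution diverged at t={times[n]:.3g} s "
                f"(step {n}); reduce dt or refine the mesh"
            )
        loads[n] = axial_load(phi, eps[n])

    n_out = int(round(program.duration * sampling_rate)) + 1
    t_out = np.arange(n_out) / sampling_rate
    load_out = np.interp(t_out, times, loads)
    return RelaxationTrace(
        time=t_out,
        displacement=program.strain_at(t_out) * geom.thickness,
        load=load_out,
        nominal_thickness=geom.thickness,
        radius=geom.radius,
    )
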