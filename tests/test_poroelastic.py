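"""Forward-model unit and property tests (series + finite differences)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclerafit.poroelastic import (
    CLEParameters,
    LoadingProgram,
    SampleGeometry,
    StrainStep,
    characteristic_time,
    equilibrium_load,
    fd_oracle_response,
    load_history,
    series_roots,
    simulate_response,
)
from tests.conftest import rel_rms


class TestTypes:
    def test_geometry_area(self, geometry):
        assert geometry.area == pytest.approx(math.pi * 0.5e-3**2, rel=1e-12)

    @pytest.mark.parametrize("radius,thickness", [(-1e-3, 1e-4), (1e-3, 0.0), (0, 1e-4)])
    def test_geometry_invalid(self, radius, thickness):
        with pytest.raises(ValueError):
            SampleGeometry(radius=radius, thickness=thickness)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(H_plus_A=-1.0, H_minus_A=1e3, k=1e-14),
            dict(H_plus_A=1e3, H_minus_A=0.0, k=1e-14),
            dict(H_plus_A=1e3, H_minus_A=1e3, k=-1e-14),
            dict(H_plus_A=1e3, H_minus_A=1e3, k=1e-14, lambda_offdiag=-1.0),
        ],
    )
    def test_params_invalid(self, kwargs):
        with pytest.raises(ValueError):
            CLEParameters(**kwargs)

    def test_program_strains_must_increase(self):
        with pytest.raises(ValueError):
            LoadingProgram(
                steps=(
                    StrainStep(0.10, 10.0, 100.0),
                    StrainStep(0.05, 10.0, 100.0),
                )
            )

    def test_program_strain_schedule(self, three_step_program):
        t = np.array([0.0, 5.0, 10.0, 1000.0, 1520.0, 4530.0])
        eps = three_step_program.strain_at(t)
        assert eps[0] == 0.0
        assert eps[1] == pytest.approx(0.025)
        assert eps[2] == pytest.approx(0.05)
        assert eps[3] == pytest.approx(0.05)
        assert eps[4] == pytest.approx(0.10)
        assert eps[5] == pytest.approx(0.15)


class TestEquilibriumLoad:
    def test_closed_form(self, geometry):
        p = CLEParameters(H_plus_A=50e3, H_minus_A=100e3, k=1e-14)
        expected = 100e3 * 0.05 * math.pi * 0.5e-3**2
        assert equilibrium_load(p, 0.05, geometry) == pytest.approx(3.927e-3, rel=1e-3)
        assert equilibrium_load(p, 0.05, geometry) == pytest.approx(expected, rel=1e-12)

    def test_zero_strain_limit(self, geometry):
        p = CLEParameters(H_plus_A=50e3, H_minus_A=100e3, k=1e-14)
        assert equilibrium_load(p, 1e-12, geometry) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError):
            equilibrium_load(p, 0.0, geometry)
        with pytest.raises(ValueError):
            equilibrium_load(p, -0.05, geometry)

    def test_linear_in_modulus(self, geometry):
        half = CLEParameters(H_plus_A=50e3, H_minus_A=50e3, k=1e-14)
        full = CLEParameters(H_plus_A=50e3, H_minus_A=100e3, k=1e-14)
        assert equilibrium_load(half, 0.10, geometry) == pytest.approx(
            equilibrium_load(full, 0.10, geometry) / 2.0, rel=1e-12
        )

    def test_independent_of_transient_parameters(self, geometry):
        a = CLEParameters(H_plus_A=50e3, H_minus_A=100e3, k=1e-14)
        b = CLEParameters(H_plus_A=500e3, H_minus_A=100e3, k=1e-12)
        assert equilibrium_load(a, 0.05, geometry) == equilibrium_load(b, 0.05, geometry)


class TestCharacteristicTime:
    def test_arithmetic(self, geometry):
        p = CLEParameters(H_plus_A=100e3, H_minus_A=30e3, k=1e-14)
        assert characteristic_time(p, geometry) == pytest.approx(250.0, rel=1e-12)

    def test_scalings(self, geometry):
        p = CLEParameters(H_plus_A=100e3, H_minus_A=30e3, k=1e-14)
        p2 = CLEParameters(H_plus_A=100e3, H_minus_A=30e3, k=2e-14)
        assert characteristic_time(p2, geometry) == pytest.approx(
            characteristic_time(p, geometry) / 2.0
        )
        big = SampleGeometry(radius=1.0e-3, thickness=geometry.thickness)
        assert characteristic_time(p, big) == pytest.approx(
            4.0 * characteristic_time(p, geometry)
        )


class TestSeriesRoots:
    def test_characteristic_equation(self):
        from scipy import special

        roots = series_roots(50)
        assert np.allclose(roots * special.j0(roots), special.j1(roots), atol=1e-10)
        assert np.all(np.diff(roots) > 0)

    def test_residue_sum_is_half(self):
        # instantaneous-step coefficients must sum to 1/2:
        # the incompressible instantaneous modulus is H_minus + H_plus/2
        roots = series_roots(4000)
        assert np.sum(1.0 / (roots**2 - 1.0)) == pytest.approx(0.5, abs=1e-4)


class TestSimulateResponse:
    def test_fast_drainage_tracks_equilibrium(self, geometry, three_step_program):
        p = CLEParameters(H_plus_A=100e3, H_minus_A=100e3, k=1e-10)
        assert characteristic_time(p, geometry) < 0.1
        trace = simulate_response(p, geometry, three_step_program, sampling_rate=2.0)
        quasi = (
            p.H_minus_A * three_step_program.strain_at(trace.time) * geometry.area
        )
        assert np.max(np.abs(trace.load - quasi)) < 0.01 * quasi.max()

    def test_hold_converges_to_equilibrium(self, treated_params, geometry, single_step_program):
        trace = simulate_response(treated_params, geometry, single_step_program)
        eq = equilibrium_load(treated_params, 0.05, geometry)
        assert trace.load[-1] == pytest.approx(eq, rel=0.01)

    def test_monotone_decay_during_hold(self, single_step_trace):
        hold = single_step_trace.time > 10.0
        dload = np.diff(single_step_trace.load[hold])
        assert np.all(dload <= 1e-12)

    def test_peak_at_least_equilibrium(self, treated_params, geometry, single_step_program):
        trace = simulate_response(treated_params, geometry, single_step_program)
        eq = equilibrium_load(treated_params, 0.05, geometry)
        assert trace.load.max() >= eq

    def test_sampling_rate_too_low(self, treated_params, geometry, single_step_program):
        with pytest.raises(ValueError, match="2 samples"):
            simulate_response(treated_params, geometry, single_step_program, sampling_rate=0.1)

    def test_moduli_scaling_linearity(self, geometry, single_step_program):
        p = CLEParameters(H_plus_A=100e3, H_minus_A=30e3, k=1e-14)
        # scale both moduli by c and k by 1/c: the gel time (hence the
        # transient clock) is unchanged and the load scales by c exactly
        c = 3.0
        ps = CLEParameters(H_plus_A=c * 100e3, H_minus_A=c * 30e3, k=1e-14 / c)
        t = np.linspace(0.0, 1510.0, 500)
        f1 = load_history(p, geometry, single_step_program, t)
        f2 = load_history(ps, geometry, single_step_program, t)
        assert np.allclose(f2, c * f1, rtol=1e-10)

    def test_peak_ratio_monotone_in_modulus_ratio(self, geometry, single_step_program):
        ratios = []
        for hp in [30e3, 60e3, 150e3, 300e3]:
            p = CLEParameters(H_plus_A=hp, H_minus_A=30e3, k=1e-14)
            tr = simulate_response(p, geometry, single_step_program)
            eq = equilibrium_load(p, 0.05, geometry)
            ratios.append(tr.load.max() / eq)
        assert np.all(np.diff(ratios) > 0)

    @settings(max_examples=10, deadline=None)
    @given(
        hp=st.floats(min_value=3e4, max_value=5e5),
        hm=st.floats(min_value=1e4, max_value=1e5),
        logk=st.floats(min_value=-15.0, max_value=-13.0),
    )
    def test_load_positive_and_finite(self, hp, hm, logk, geometry, single_step_program):
        p = CLEParameters(H_plus_A=hp, H_minus_A=hm, k=10**logk)
        tr = simulate_response(p, geometry, single_step_program, sampling_rate=1.0)
        assert np.all(np.isfinite(tr.load))
        assert np.all(tr.load >= -1e-12)


class TestFdOracle:
    def test_zero_strain_zero_load(self, geometry):
        # quasi-zero strain: the smallest admissible program produces
        # loads proportional to the strain (linear model)
        p = CLEParameters(H_plus_A=100e3, H_minus_A=30e3, k=1e-14)
        prog = LoadingProgram(
            tare_load=0.0, steps=(StrainStep(1e-9, 10.0, 100.0),)
        )
        tr = fd_oracle_response(p, geometry, prog, n_radial=60)
        assert np.max(np.abs(tr.load)) < 1e-9

    def test_equilibrium_matches_closed_form(self, treated_params, geometry, single_step_program):
        tr = fd_oracle_response(treated_params, geometry, single_step_program, n_radial=100)
        eq = equilibrium_load(treated_params, 0.05, geometry)
        assert tr.load[-1] == pytest.approx(eq, rel=0.002)

    def test_n_radial_minimum(self, treated_params, geometry, single_step_program):
        with pytest.raises(ValueError, match="n_radial"):
            fd_oracle_response(treated_params, geometry, single_step_program, n_radial=10)

    def test_mesh_refinement_converges(self, treated_params, geometry, single_step_program):
        coarse = fd_oracle_response(
            treated_params, geometry, single_step_program, n_radial=60, dt=0.4
        )
        fine = fd_oracle_response(
            treated_params, geometry, single_step_program, n_radial=120, dt=0.2
        )
        assert rel_rms(fine.load, coarse.load) < 0.005

    def test_k_rescales_time_axis(self, geometry):
        # doubling k halves the transient clock: F_k(t) == F_2k(t/2)
        hold = 2000.0
        p1 = CLEParameters(H_plus_A=100e3, H_minus_A=30e3, k=1e-14)
        p2 = CLEParameters(H_plus_A=100e3, H_minus_A=30e3, k=2e-14)
        prog1 = LoadingProgram(tare_load=0.0, steps=(StrainStep(0.05, 20.0, hold),))
        prog2 = LoadingProgram(tare_load=0.0, steps=(StrainStep(0.05, 10.0, hold / 2),))
        tr1 = fd_oracle_response(p1, geometry, prog1, n_radial=80)
        tr2 = fd_oracle_response(p2, geometry, prog2, n_radial=80, sampling_rate=4.0)
        f2_interp = np.interp(tr1.time / 2.0, tr2.time, tr2.load)
        assert rel_rms(tr1.load, f2_interp) < 0.01

    def test_coupled_equilibrium(self, geometry):
        # nonzero off-diagonal modulus softens equilibrium per closed form
        p = CLEParameters(H_plus_A=100e3, H_minus_A=50e3, k=1e-14, lambda_offdiag=10e3)
        prog = LoadingProgram(tare_load=0.0, steps=(StrainStep(0.05, 10.0, 2500.0),))
        tr = fd_oracle_response(p, geometry, prog, n_radial=100)
        assert tr.load[-1] == pytest.approx(equilibrium_load(p, 0.05, geometry), rel=0.005)


class TestOracleEquivalence:
    @pytest.mark.parametrize(
        "ratio,tg_over_ramp",
        list(itertools.product([1, 2, 5, 10], [0.1, 1, 10])),
    )
    def test_series_matches_fd(self, ratio, tg_over_ramp, geometry):
        hm = 30e3
        hp = ratio * hm
        ramp = 10.0
        tg = tg_over_ramp * ramp
        k = geometry.radius**2 / (hp * tg)
        p = CLEParameters(H_plus_A=hp, H_minus_A=hm, k=k)
        prog = LoadingProgram(
            tare_load=0.0, steps=(StrainStep(0.05, ramp, max(100.0, 8.0 * tg)),)
        )
        ana = simulate_response(p, geometry, prog, sampling_rate=2.0)
        fd = fd_oracle_response(p, geometry, prog, n_radial=100)
        assert rel_rms(ana.load, fd.load) < 0.01
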