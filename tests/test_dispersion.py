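"""Structure factors, radiative quenching and the chain dispersion solver.

The independent oracles are (a) mpmath's Clausen functions clsin/clcos for
the transcendental lattice sums, (b) brute-force truncated series, and
(c) a scalar fixed-point evaluation with the static (u -> 0) sums for the
dispersion solution at the zone edge.
"""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axoplasmon import _clausen as cl
from axoplasmon.dispersion import (LONGITUDINAL, TRANSVERSE, ChainGeometry,
                                   DrivingField, default_k_grid,
                                   driven_response, group_velocity,
                                   light_cone_offsets, solve_dispersion,
                                   static_cosine_sums, structure_factor,
                                   structure_factor_arrays,
                                   truncated_structure_factor)
from axoplasmon.plasma import InvalidParameterError

ZETA3 = float(mpmath.zeta(3))


class TestClosedFormSums:
    """The Bernoulli/Clausen closed forms against series oracles."""

    def test_alternating_cubic_series(self):
        # sum cos(m pi)/m^3 = -(3/4) zeta(3)
        c3, _ = static_cosine_sums(math.pi, 3)
        assert c3 == pytest.approx(-0.75 * ZETA3, abs=1e-12)

    def test_sine_cubic_vanishes_at_pi(self):
        _, s3 = static_cosine_sums(math.pi, 3)
        assert s3 == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_cosine_at_pi(self):
        c2, _ = static_cosine_sums(math.pi, 2)
        assert c2 == pytest.approx(-math.pi**2 / 12.0, abs=1e-12)

    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_against_mpmath_clausen(self, order, rng):
        for x in rng.uniform(0.05, 2 * math.pi - 0.05, size=12):
            c, s = static_cosine_sums(x, order)
            assert c == pytest.approx(float(mpmath.clcos(order, x)), abs=1e-11)
            assert s == pytest.approx(float(mpmath.clsin(order, x)), abs=1e-11)

    def test_against_truncated_series(self, rng):
        for x in rng.uniform(0.3, 2 * math.pi - 0.3, size=6):
            assert cl.cos_sum_m3(x) == pytest.approx(
                cl.truncated_fourier_sum(x, 3, 200_000, "cos"), abs=1e-9)
            assert cl.sin_sum_m2(x) == pytest.approx(
                cl.truncated_fourier_sum(x, 2, 200_000, "sin"), abs=1e-9)

    def test_domain_error_at_multiples_of_two_pi(self):
        with pytest.raises(InvalidParameterError):
            static_cosine_sums(0.0, 2)
        with pytest.raises(InvalidParameterError):
            static_cosine_sums(4 * math.pi, 3)


class TestStructureFactor:
    def test_zone_edge_static_limit(self):
        f = structure_factor(math.pi, 1e-9, LONGITUDINAL)
        assert f.value.real == pytest.approx(-3 * ZETA3, rel=1e-6)
        assert f.value.imag == pytest.approx(0.0, abs=1e-9)

    def test_zone_centre_static_limit(self):
        f = structure_factor(1e-3, 1e-9, LONGITUDINAL)
        assert f.value.real == pytest.approx(4 * ZETA3, rel=1e-3)

    def test_radiative_quenching_on_grid(self):
        """Im F == 0 through the whole subluminal region, both polarizations.

        200 (x, u) pairs with u < min(x, 2 pi - x); the closed-form Fourier
        cancellation must hold to 1e-9 absolute.
        """
        rng = np.random.default_rng(7)
        x = rng.uniform(0.05, 2 * math.pi - 0.05, size=200)
        u = rng.uniform(0.0, 1.0, size=200) * np.minimum(
            x, 2 * math.pi - x) * 0.98
        for pol in (LONGITUDINAL, TRANSVERSE):
            im = structure_factor_arrays(x, u, pol).imag
            assert np.max(np.abs(im)) < 1e-9

    def test_nonzero_radiation_outside_light_cone(self):
        # superluminal point u > x: the lattice sum no longer cancels the
        # Lorentz friction and energy is radiated.
        f = structure_factor_arrays(0.3, 1.2, LONGITUDINAL)
        assert abs(f.imag) > 1e-3

    def test_real_part_even_under_x_reflection(self, rng):
        for _ in range(20):
            x = rng.uniform(0.2, math.pi)
            u = rng.uniform(0.0, 0.5 * x)
            for pol in (LONGITUDINAL, TRANSVERSE):
                a = structure_factor_arrays(x, u, pol)
                b = structure_factor_arrays(2 * math.pi - x, u, pol)
                assert a.real == pytest.approx(b.real, rel=1e-12, abs=1e-12)

    def test_light_cone_flagged_singular(self):
        f = structure_factor(0.5, 0.5, LONGITUDINAL)
        assert f.singular and math.isnan(f.value.real)

    def test_negative_u_rejected(self):
        with pytest.raises(InvalidParameterError):
            structure_factor(1.0, -0.1)


class TestTruncatedStructureFactor:
    def test_single_term_zone_edge(self):
        f = truncated_structure_factor(math.pi, 0.0, LONGITUDINAL, n_terms=1)
        assert f.value == pytest.approx(-4.0)

    def test_ten_segments_close_to_infinite_chain(self):
        """~10 segments already behave like an infinite chain (< 5% in Re F_z)."""
        exact = structure_factor(math.pi, 1e-5, LONGITUDINAL).value.real
        ten = truncated_structure_factor(math.pi, 1e-5, LONGITUDINAL,
                                         n_terms=10).value.real
        assert abs(ten - exact) / abs(exact) < 0.05

    def test_convergence_to_closed_form(self):
        exact = structure_factor(2.0, 0.4, LONGITUDINAL).value
        approx = truncated_structure_factor(2.0, 0.4, LONGITUDINAL,
                                            n_terms=10**6).value
        assert approx.real == pytest.approx(exact.real, abs=1e-9)
        assert approx.imag == pytest.approx(exact.imag, abs=1e-9)

    def test_transverse_also_converges(self):
        # the far-field 1/m terms make the transverse tail ~u^2/(2M sin(x/2)),
        # much slower than the longitudinal 1/m^2 tail
        exact = structure_factor(2.0, 0.4, TRANSVERSE).value
        approx = truncated_structure_factor(2.0, 0.4, TRANSVERSE,
                                            n_terms=10**6).value
        assert approx.real == pytest.approx(exact.real, abs=1e-6)
        assert approx.imag == pytest.approx(exact.imag, abs=1e-6)


class TestDispersionSolver:
    def test_uncoupled_limit_flat_branch(self):
        geo = ChainGeometry(segment_radius=1e-9, period=1e-4, eps=80.0)
        br = solve_dispersion(geo, 4e6, n_points=101)
        assert br.converged.all()
        assert np.max(np.abs(br.omega.real - 4e6)) < 1e-3
        assert np.max(np.abs(br.omega.imag)) < 1e-6

    def test_zone_edge_against_static_fixed_point_oracle(self, solved_branch):
        """Re omega(kd=pi)/omega1 = sqrt(1 + g * 3 zeta(3)) for u << 1."""
        g = solved_branch.geometry.coupling
        expected = math.sqrt(1.0 + g * 3 * ZETA3)
        i = np.argmin(np.abs(solved_branch.k * solved_branch.geometry.period
                             - math.pi))
        assert solved_branch.omega.real[i] / solved_branch.omega1 == \
            pytest.approx(expected, rel=1e-4)

    def test_residual_below_tolerance(self, solved_branch):
        from axoplasmon.dispersion import _residual

        res = _residual(solved_branch.omega,
                        solved_branch.k * solved_branch.geometry.period,
                        solved_branch.geometry, solved_branch.omega1,
                        solved_branch.inv_tau0, solved_branch.polarization)
        assert solved_branch.converged.all()
        assert np.max(np.abs(res)) <= 1e-9 * solved_branch.omega1**2

    def test_branch_parity(self, solved_branch):
        w = solved_branch.omega.real
        assert np.max(np.abs(w - w[::-1])) < 1e-8 * solved_branch.omega1

    def test_perturbative_agreement_at_small_g(self):
        """Static-F perturbative root matches the exact solve as g -> 0."""
        g = 1e-4
        a = 1e-6
        d = a / g ** (1.0 / 3.0)
        geo = ChainGeometry(segment_radius=a, period=d, eps=80.0)
        omega1 = 4e6
        k = np.linspace(0.3, 2 * math.pi - 0.3, 41) / d
        br = solve_dispersion(geo, omega1, k_grid=k)
        u1 = omega1 * d / geo.light_speed_in_medium
        f = structure_factor_arrays(br.k * d, np.full(len(br.k), u1),
                                    LONGITUDINAL)
        pert = omega1 * np.sqrt(1.0 - g * f.real)
        rel_gap = np.max(np.abs(br.omega.real - pert)) / omega1
        assert rel_gap < 1e-6

    def test_damped_branch_has_negative_imaginary_part(self, myelinated_chain):
        br = solve_dispersion(myelinated_chain, 4e6, inv_tau0=1e5,
                              n_points=51)
        assert br.converged.all()
        assert np.all(br.omega.imag < 0)
        # uncoupled pole: Im omega = -1/tau0 at leading order
        assert np.median(br.omega.imag) == pytest.approx(-1e5, rel=0.05)

    def test_transverse_branch_suppressed_flag(self, myelinated_chain):
        br = solve_dispersion(myelinated_chain, 4e6,
                              polarization=TRANSVERSE, n_points=51)
        assert br.physically_suppressed
        assert br.converged.all()


class TestGroupVelocity:
    def test_flat_branch_zero_velocity(self):
        geo = ChainGeometry(segment_radius=1e-9, period=1e-4, eps=80.0)
        br = solve_dispersion(geo, 4e6, n_points=101)
        vg = group_velocity(br)
        assert np.max(np.abs(vg)) < 1e-3

    def test_reaches_100_m_per_s(self, solved_branch):
        assert np.abs(solved_branch.v_g).max() >= 100.0

    def test_antisymmetry(self, solved_branch):
        vg = solved_branch.v_g
        assert np.max(np.abs(vg + vg[::-1])) < 1e-6 * np.abs(vg).max()


class TestDrivenResponse:
    def test_zero_drive_zero_response(self, myelinated_chain):
        drive = DrivingField(0.0, k=math.pi / myelinated_chain.period,
                             omega=3e6)
        assert driven_response(myelinated_chain, 4e6, 0.0, drive) == 0

    def test_static_uncoupled_limit(self):
        geo = ChainGeometry(segment_radius=1e-9, period=1e-4, eps=80.0)
        drive = DrivingField(2.5, k=math.pi / geo.period, omega=0.0)
        d = driven_response(geo, 4e6, 0.0, drive)
        assert d.real == pytest.approx(geo.eps * geo.segment_radius**3 * 2.5,
                                       rel=1e-6)

    def test_resonance_peak_near_branch_frequency(self, solved_branch):
        geo = solved_branch.geometry
        i = len(solved_branch.k) // 2
        k = solved_branch.k[i]
        w_res = solved_branch.omega.real[i]
        omegas = np.linspace(0.5 * w_res, 1.5 * w_res, 301)
        amps = [abs(driven_response(geo, solved_branch.omega1, 1e3,
                                    DrivingField(1.0, k=k, omega=w)))
                for w in omegas]
        w_peak = omegas[int(np.argmax(amps))]
        assert w_peak == pytest.approx(w_res, rel=0.01)


class TestLightCone:
    def test_zero_frequency_offsets(self, myelinated_chain):
        off = light_cone_offsets(myelinated_chain, 0.0)
        assert off["offset_vacuum"] == 0.0
        assert off["offset_medium"] == 0.0

    def test_worked_example_offsets(self, myelinated_chain):
        off = light_cone_offsets(myelinated_chain, 4e6)
        d = myelinated_chain.period
        assert off["offset_vacuum"] == pytest.approx(4e6 * d / 3e8, rel=1e-12)
        assert off["offset_medium"] == pytest.approx(
            off["offset_vacuum"] * math.sqrt(80.0), rel=1e-12)

    @given(scale=st.floats(1.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_offsets_linear_in_period(self, scale):
        a = 50e-6
        g1 = ChainGeometry(segment_radius=a, period=2.01 * a, eps=80.0)
        g2 = ChainGeometry(segment_radius=a, period=2.01 * a * scale, eps=80.0)
        o1 = light_cone_offsets(g1, 4e6)
        o2 = light_cone_offsets(g2, 4e6)
        assert o2["offset_vacuum"] == pytest.approx(
            scale * o1["offset_vacuum"], rel=1e-12)


class TestGeometry:
    def test_overlap_rejected(self):
        with pytest.raises(InvalidParameterError):
            ChainGeometry(segment_radius=1e-4, period=1.5e-4)

    def test_coupling_bound(self, myelinated_chain):
        assert 0 < myelinated_chain.coupling <= 0.125

    def test_finite_chain_dft_grid(self):
        geo = ChainGeometry(segment_radius=50e-6, period=1.05e-4, eps=80.0,
                            count=21)
        k = geo.dft_k_grid()
        assert len(k) == 20
        assert k[-1] * geo.period < 2 * math.pi

    def test_default_grid_excludes_edges(self, myelinated_chain):
        k = default_k_grid(myelinated_chain, 101)
        assert k[0] > 0
        assert k[-1] < 2 * math.pi / myelinated_chain.period
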