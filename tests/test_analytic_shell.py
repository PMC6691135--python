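import math

import numpy as np
import pytest
from scipy.special import spherical_jn

import spinedyn as sd
from spinedyn.analytic_shell import (
    antiperiodic_eigenvalues,
    char_poly,
    find_eigenvalues,
    reference_w_shell,
    series_solve_antiperiodic,
    series_solve_shell,
)


def bisect_roots(f, lo, hi, n_scan, n_roots):
    """Independent dense sign-scan + plain bisection oracle."""
    xs = np.linspace(lo, hi, n_scan)
    fs = np.array([f(x) for x in xs])
    roots = []
    for i in np.nonzero(fs[:-1] * fs[1:] < 0)[0]:
        a, b = xs[i], xs[i + 1]
        for _ in range(200):
            m = 0.5 * (a + b)
            if f(a) * f(m) <= 0:
                b = m
            else:
                a = m
        roots.append(0.5 * (a + b))
        if len(roots) == n_roots:
            break
    return np.array(roots)


class TestCharPoly:
    def test_zero_is_a_root(self):
        for rho in (0.1, 0.5, 0.9):
            assert char_poly(0.0, rho) == 0.0

    @pytest.mark.parametrize("rho", [0.1, 0.5, 0.9])
    def test_roots_match_bisection_oracle(self, rho):
        spec = find_eigenvalues(rho, 6)
        oracle = bisect_roots(
            lambda x: char_poly(x, rho), 1e-3, spec.roots[-1] + 1.0, 40000, 6
        )
        assert np.allclose(spec.roots, oracle, atol=1e-10, rtol=0)

    @pytest.mark.parametrize("rho", [0.3, 0.5, 0.7])
    def test_asymptotic_root_spacing(self, rho):
        spec = find_eigenvalues(rho, 50)
        spacing = np.diff(spec.roots)[-10:]
        assert np.allclose(spacing, math.pi / (1 - rho), rtol=1e-3)

    def test_roots_are_simple_sign_changes(self):
        spec = find_eigenvalues(0.5, 10)
        eps = 1e-4
        for x in spec.roots:
            assert char_poly(x - eps, 0.5) * char_poly(x + eps, 0.5) < 0

    def test_smaller_rho_gives_smaller_first_root(self):
        assert find_eigenvalues(0.1, 1).roots[0] < find_eigenvalues(0.9, 1).roots[0]

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            char_poly(1.0, 1.5)


class TestAntiperiodicEigenvalues:
    def test_even_order_rejected(self):
        with pytest.raises(ValueError, match="anti-symmetry"):
            antiperiodic_eigenvalues([2], 3)

    def test_first_root_matches_scan_oracle(self):
        spec = antiperiodic_eigenvalues([1], 5)
        oracle = bisect_roots(
            lambda x: spherical_jn(1, x, derivative=True), 0.1, 20.0, 20000, 5
        )
        assert np.allclose(spec.roots, oracle, atol=1e-9)

    @pytest.mark.parametrize("m", [1, 3, 5])
    def test_derivative_roots_interlace_function_roots(self, m):
        spec = antiperiodic_eigenvalues([m], 6)
        jroots = bisect_roots(lambda x: spherical_jn(m, x), 0.5, 40.0, 40000, 6)
        # classical interlacing: between consecutive zeros of j_m lies
        # exactly one zero of j_m'
        for a, b in zip(jroots[:-1], jroots[1:]):
            inside = [x for x in spec.roots if a < x < b]
            assert len(inside) == 1


class TestReferenceW:
    def test_zero_fluxes_give_zero(self):
        geom = sd.build_geometry("sphere_shell", 0.25, 0.5)
        flux = sd.FluxModel(gamma_abs=0.0)
        r = np.linspace(0.125, 0.25, 11)
        assert np.all(reference_w_shell(r, 5.0, geom, flux, D=0.1) == 0.0)

    def test_boundary_derivatives_reproduce_fluxes(self):
        geom = sd.build_geometry("sphere_shell", 0.25, 0.5)
        flux = sd.FluxModel()
        D, t = 0.1, 25.0
        h = 1e-7

        def dw(r):
            return (
                reference_w_shell(r + h, t, geom, flux, D)
                - reference_w_shell(r - h, t, geom, flux, D)
            ) / (2 * h)

        # influx-positive convention: D dw/dr = +J_PM at the outer membrane
        # and -J_ER at the inner one (outward normal flips)
        assert D * dw(geom.R_o) == pytest.approx(flux.j_pm(t), rel=1e-7)
        assert D * dw(geom.R_i) == pytest.approx(-flux.j_er(t), rel=1e-7)


class TestShellSeries:
    def test_homogeneous_initial_condition(self, baseline_sphere):
        geom, flux, kinetics, config = baseline_sphere
        ser = series_solve_shell(geom, flux, tau=50.0, D=0.1, n_modes=10,
                                 t_grid=np.array([0.0, 1.0]))
        r = np.linspace(geom.R_i, geom.R_o, 21)
        assert np.max(np.abs(ser.evaluate(r, 0))) < 1e-20

    def test_zero_flux_stays_zero(self):
        geom = sd.build_geometry("sphere_shell", 0.25, 0.5)
        flux = sd.FluxModel(gamma_abs=0.0)
        ser = series_solve_shell(geom, flux, tau=50.0, D=0.1, n_modes=5,
                                 t_grid=np.linspace(0, 10, 51))
        assert np.max(np.abs(ser.coeffs)) == 0.0

    def test_mode_orthogonality_r2_weight(self):
        from scipy.special import spherical_jn, spherical_yn

        geom = sd.build_geometry("sphere_shell", 0.25, 0.5)
        spec = find_eigenvalues(0.5, 12)
        k = spec.roots / geom.R_o
        alpha = spherical_yn(0, k * geom.R_i, derivative=True)
        beta = -spherical_jn(0, k * geom.R_i, derivative=True)
        xg, wg = np.polynomial.legendre.leggauss(500)
        rq = 0.5 * (geom.R_o - geom.R_i) * xg + 0.5 * (geom.R_o + geom.R_i)
        wq = 0.5 * (geom.R_o - geom.R_i) * wg * rq**2
        U = alpha * spherical_jn(0, np.outer(rq, k)) + beta * spherical_yn(
            0, np.outer(rq, k)
        )
        G = (U * wq[:, None]).T @ U
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.abs(np.diag(G)).max()

    def test_truncation_error_decreases_with_modes(self):
        geom = sd.build_geometry("sphere_shell", 0.25, 0.5)
        flux = sd.FluxModel()
        t_grid = np.arange(0.0, 5.0 + 1e-9, 0.05)
        r = np.linspace(geom.R_i, geom.R_o, 200)
        i = len(t_grid) - 1  # boundary layer still steep at 5 ms
        ref = series_solve_shell(geom, flux, tau=50.0, D=0.1, n_modes=48,
                                 t_grid=t_grid).evaluate(r, i)
        errs = []
        for n_modes in (2, 8, 24):
            c = series_solve_shell(geom, flux, tau=50.0, D=0.1,
                                   n_modes=n_modes, t_grid=t_grid).evaluate(r, i)
            errs.append(np.linalg.norm(ref - c) / np.linalg.norm(ref))
        assert errs[0] > errs[1] > errs[2]

    def test_mass_conserved_without_decay_or_outlet(self):
        # tau -> inf and fluxes exhausted: total amount must be constant
        geom = sd.build_geometry("sphere_shell", 0.25, 0.5)
        flux = sd.FluxModel(zeta=0.0)
        t_grid = np.arange(0.0, 80.0 + 1e-9, 0.02)
        ser = series_solve_shell(geom, flux, tau=1e12, D=0.1, n_modes=20,
                                 t_grid=t_grid)
        xg, wg = np.polynomial.legendre.leggauss(200)
        rq = 0.5 * (geom.R_o - geom.R_i) * xg + 0.5 * (geom.R_o + geom.R_i)
        wq = 0.5 * (geom.R_o - geom.R_i) * wg * rq**2
        masses = [
            float(wq @ ser.evaluate(rq, i))
            for i, t in enumerate(t_grid)
            if t > 40.0 and i % 200 == 0
        ]
        assert np.ptp(masses) < 1e-4 * abs(masses[0])


class TestAntiperiodicSeries:
    PHI0 = math.asin(0.4)  # 0.2 um cap on a 0.25 um sphere

    def test_invalid_phi0_rejected(self):
        with pytest.raises(ValueError, match="phi0"):
            series_solve_antiperiodic(0.25, sd.FluxModel(), 2.0, 50.0, 0.01)

    def test_antisymmetry_under_polar_reflection(self):
        ser = series_solve_antiperiodic(
            0.25, sd.FluxModel(), self.PHI0, 50.0, 0.01,
            m_max=15, n_max=6, t_grid=np.linspace(0, 10, 101),
        )
        r = np.full(7, 0.2)
        phi = np.linspace(0.1, 1.2, 7)
        up = ser.evaluate(r, phi, 50)
        down = ser.evaluate(r, math.pi - phi, 50)
        assert np.max(np.abs(up + down)) < 1e-12 * np.max(np.abs(up))

    def test_vanishing_caps_give_uniform_solution(self):
        t_grid = np.linspace(0, 5, 26)
        ser_tiny = series_solve_antiperiodic(
            0.25, sd.FluxModel(), 1e-4, 50.0, 0.01, m_max=9, n_max=4, t_grid=t_grid
        )
        ser_ref = series_solve_antiperiodic(
            0.25, sd.FluxModel(), self.PHI0, 50.0, 0.01, m_max=9, n_max=4,
            t_grid=t_grid,
        )
        # influx scales with the cap area ~ phi0^2; the field follows
        assert np.max(np.abs(ser_tiny.coeffs)) < 1e-6 * np.max(np.abs(ser_ref.coeffs))

    def test_matches_axisymmetric_solver(self):
        """Modal solution vs finite elements on the identical configuration."""
        geom = sd.build_geometry("sphere_solid", 0.25)
        lay = sd.BoundaryLayout(influx="antiperiodic", phi0=self.PHI0)
        mesh = sd.mesh_axisymmetric(geom, lay, n_s=48, n_phi=192)
        flux = sd.FluxModel()
        cfg = sd.SolverConfig(D=0.01, dt=0.05, T=30.0)
        sol = sd.solve_axisymmetric(mesh, flux, sd.KineticsSpec("linear", tau=50.0), cfg)
        ser = series_solve_antiperiodic(0.25, flux, self.PHI0, 50.0, 0.01,
                                        m_max=41, n_max=16, t_grid=sol.times)
        pts = mesh.nodes
        r = np.linalg.norm(pts, axis=1)
        phi = np.arctan2(pts[:, 0], pts[:, 1])
        w = sol.node_weights
        num = den = 0.0
        for i in range(0, len(sol.times), 60):
            if sol.times[i] < 5.0:
                continue
            cs = ser.evaluate(r, phi, i)
            num += np.sum(w * (sol.C[i] - cs) ** 2)
            den += np.sum(w * cs**2)
        assert math.sqrt(num / den) < 0.02
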