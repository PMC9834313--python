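"""Homogeneous and coated Lorenz-Mie efficiencies.

The independent oracle evaluates the same physics through a wholly different
numerical route: Riccati-Bessel functions from scipy's AMOS half-integer-order
Bessel implementation (complex arguments, no recurrences) plugged directly
into the textbook coefficient formulas, versus the package's downward
log-derivative / ratio-stabilized recurrences.
"""

import numpy as np
import pytest
from scipy import special

from irispec import (
    SphereGeometry,
    VoxelDispersion,
    WavenumberGrid,
    qext_coated,
    qext_from_dispersion,
    qext_homogeneous,
    size_parameter,
    truncation_order,
)
from irispec.synthetic_data import random_dispersion


def _amos_psi_chi(n: int, z: complex):
    z = complex(z)
    f = np.sqrt(np.pi * z / 2.0)
    return f * special.jv(n + 0.5, z), -f * special.yv(n + 0.5, z)


def oracle_homogeneous(m: complex, x: float):
    """Direct series evaluation from AMOS Bessel values (oracle)."""
    nmax = truncation_order(x)
    qe = qs = 0.0
    for n in range(1, nmax + 1):
        psi_mx, _ = _amos_psi_chi(n, m * x)
        psi_mx1, _ = _amos_psi_chi(n - 1, m * x)
        dpsi_mx = psi_mx1 - n / (m * x) * psi_mx
        psi_x, chi_x = _amos_psi_chi(n, x)
        psi_x1, chi_x1 = _amos_psi_chi(n - 1, x)
        dpsi_x = psi_x1 - n / x * psi_x
        xi_x, xi_x1 = psi_x - 1j * chi_x, psi_x1 - 1j * chi_x1
        dxi_x = xi_x1 - n / x * xi_x
        a = (m * psi_mx * dpsi_x - psi_x * dpsi_mx) / (m * psi_mx * dxi_x - xi_x * dpsi_mx)
        b = (psi_mx * dpsi_x - m * psi_x * dpsi_mx) / (psi_mx * dxi_x - m * xi_x * dpsi_mx)
        qe += (2 * n + 1) * (a + b).real
        qs += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
    return 2.0 / x**2 * qe, 2.0 / x**2 * qs


def oracle_coated(m1: complex, m2: complex, x: float, y: float):
    """Aden-Kerker coefficients from AMOS Bessel values, unstabilized (oracle)."""
    nmax = truncation_order(y)
    qe = qs = 0.0
    for n in range(1, nmax + 1):
        p2x, c2x = _amos_psi_chi(n, m2 * x)
        p2x1, c2x1 = _amos_psi_chi(n - 1, m2 * x)
        dp2x = p2x1 - n / (m2 * x) * p2x
        dc2x = c2x1 - n / (m2 * x) * c2x
        p1x, _ = _amos_psi_chi(n, m1 * x)
        p1x1, _ = _amos_psi_chi(n - 1, m1 * x)
        dp1x = p1x1 - n / (m1 * x) * p1x
        p2y, c2y = _amos_psi_chi(n, m2 * y)
        p2y1, c2y1 = _amos_psi_chi(n - 1, m2 * y)
        dp2y = p2y1 - n / (m2 * y) * p2y
        dc2y = c2y1 - n / (m2 * y) * c2y
        py, cy = _amos_psi_chi(n, y)
        py1, cy1 = _amos_psi_chi(n - 1, y)
        dpy = py1 - n / y * py
        xiy, xiy1 = py - 1j * cy, py1 - 1j * cy1
        dxiy = xiy1 - n / y * xiy
        # admixture of the irregular shell solution from the core interface
        r_tm = (m2 / m1) * dp1x / p1x
        r_te = (m1 / m2) * dp1x / p1x
        A = (dp2x - r_tm * p2x) / (dc2x - r_tm * c2x)
        B = (dp2x - r_te * p2x) / (dc2x - r_te * c2x)
        fa, dfa = p2y - A * c2y, dp2y - A * dc2y
        fb, dfb = p2y - B * c2y, dp2y - B * dc2y
        a = (m2 * fa * dpy - py * dfa) / (m2 * fa * dxiy - xiy * dfa)
        b = (fb * dpy - m2 * py * dfb) / (fb * dxiy - m2 * xiy * dfb)
        qe += (2 * n + 1) * (a + b).real
        qs += (2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2)
    return 2.0 / y**2 * qe, 2.0 / y**2 * qs


def _grid_for_x(x: float, radius_um: float = 10.0) -> WavenumberGrid:
    return WavenumberGrid(np.array([x / (2 * np.pi * radius_um * 1e-4)]))


class TestPlumbing:
    def test_size_parameter_definition(self):
        assert size_parameter(10.0, 1000.0) == pytest.approx(2 * np.pi, rel=1e-12)
        assert size_parameter(10.0, 4000.0) == pytest.approx(8 * np.pi, rel=1e-12)
        assert size_parameter(0.0, 1000.0) == 0.0
        with pytest.raises(ValueError):
            size_parameter(-1.0, 1000.0)

    def test_truncation_order_wiscombe(self):
        assert truncation_order(2 * np.pi) == 16
        assert truncation_order(0.01) == 3  # lower clamp
        xs = np.linspace(0.01, 50, 300)
        orders = [truncation_order(x) for x in xs]
        assert all(b >= a for a, b in zip(orders, orders[1:]))

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            SphereGeometry(outer_radius=-1.0)
        with pytest.raises(ValueError):
            SphereGeometry(outer_radius=10.0, core_radius=10.0)
        assert SphereGeometry(10.0).J == 1
        assert SphereGeometry(10.0, 5.0).J == 2
        assert SphereGeometry(10.0).geometric_cross_section == pytest.approx(np.pi * 100)


class TestHomogeneous:
    def test_vacuum_sphere_does_not_extinguish(self, midir_grid):
        res = qext_homogeneous(1.0 + 0j, 10.0, midir_grid)
        assert np.allclose(res.q_ext, 0.0, atol=1e-10)

    def test_rayleigh_limit_closed_form(self):
        # Q_sca -> (8/3) x^4 |(m^2-1)/(m^2+2)|^2 for x << 1
        x, m = 0.01, 1.5 + 0j
        res = qext_homogeneous(m, 10.0, _grid_for_x(x))
        expected = 8.0 / 3.0 * x**4 * abs((m**2 - 1) / (m**2 + 2)) ** 2
        assert res.q_sca[0] == pytest.approx(expected, rel=1e-2)

    def test_extinction_paradox_limit(self):
        # Q_ext -> 2 from above as the sphere becomes geometrically large
        q100 = qext_homogeneous(1.5 + 0j, 10.0, _grid_for_x(100.0)).q_ext[0]
        q400 = qext_homogeneous(1.5 + 0j, 10.0, _grid_for_x(400.0)).q_ext[0]
        assert abs(q100 - 2) < 0.2
        assert abs(q400 - 2) < abs(q100 - 2)

    def test_energy_split_and_conservation(self, midir_grid):
        rng = np.random.default_rng(0)
        m = rng.uniform(1.2, 1.7, len(midir_grid)) + 1j * rng.uniform(0, 0.3, len(midir_grid))
        res = qext_homogeneous(m, 10.0, midir_grid)
        assert np.max(np.abs(res.q_ext - res.q_sca - res.q_abs)) < 1e-8
        assert np.all(res.q_sca >= 0)
        assert np.all(res.q_abs >= -1e-12)

    def test_no_absorption_without_imaginary_index(self, midir_grid):
        res = qext_homogeneous(1.4 + 0j, 10.0, midir_grid)
        assert np.max(np.abs(res.q_abs)) < 1e-8

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_independent_amos_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            x = rng.uniform(0.1, 30.0)
            m = rng.uniform(1.1, 1.8) + 1j * rng.uniform(0.0, 0.5)
            res = qext_homogeneous(m, 10.0, _grid_for_x(x))
            qe, qs = oracle_homogeneous(m, x)
            assert res.q_ext[0] == pytest.approx(qe, rel=1e-7)
            assert res.q_sca[0] == pytest.approx(qs, rel=1e-7)

    def test_continuity_under_tiny_radius_perturbation(self, midir_grid):
        m = 1.5 + 0.1j
        q1 = qext_homogeneous(m, 10.0, midir_grid).q_ext
        q2 = qext_homogeneous(m, 10.0 * (1 + 1e-6), midir_grid).q_ext
        assert np.max(np.abs(q1 - q2)) < 1e-3

    def test_negative_imaginary_index_rejected(self, midir_grid):
        with pytest.raises(ValueError, match="absorbing convention"):
            qext_homogeneous(1.5 - 0.1j, 10.0, midir_grid)

    def test_non_finite_index_rejected(self, midir_grid):
        bad = np.full(len(midir_grid), 1.5 + 0.1j)
        bad[3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            qext_homogeneous(bad, 10.0, midir_grid)


class TestCoated:
    def test_equal_indexes_reduce_to_homogeneous(self, layered_10_8, midir_grid):
        m = np.full(len(midir_grid), 1.4 + 0.05j)
        rc = qext_coated(m, m, layered_10_8, midir_grid)
        rh = qext_homogeneous(m, 10.0, midir_grid)
        assert np.max(np.abs(rc.q_ext - rh.q_ext)) < 1e-8
        assert np.max(np.abs(rc.q_sca - rh.q_sca)) < 1e-8

    def test_vanishing_shell_gives_core_material(self, midir_grid):
        geom = SphereGeometry(10.0, 10.0 * (1 - 1e-6))
        m1, m2 = 1.45 + 0.08j, 1.55 + 0.02j
        rc = qext_coated(m1, m2, geom, midir_grid)
        rh = qext_homogeneous(m1, 10.0, midir_grid)
        assert np.max(np.abs(rc.q_ext - rh.q_ext)) < 1e-4

    def test_vanishing_core_gives_shell_material(self, midir_grid):
        geom = SphereGeometry(10.0, 1e-5)
        m1, m2 = 1.45 + 0.08j, 1.55 + 0.02j
        rc = qext_coated(m1, m2, geom, midir_grid)
        rh = qext_homogeneous(m2, 10.0, midir_grid)
        assert np.max(np.abs(rc.q_ext - rh.q_ext)) < 1e-4

    def test_energy_split(self, layered_10_8, midir_grid):
        rng = np.random.default_rng(1)
        L = len(midir_grid)
        m1 = rng.uniform(1.2, 1.7, L) + 1j * rng.uniform(0, 0.3, L)
        m2 = rng.uniform(1.2, 1.7, L) + 1j * rng.uniform(0, 0.3, L)
        res = qext_coated(m1, m2, layered_10_8, midir_grid)
        assert np.max(np.abs(res.q_ext - res.q_sca - res.q_abs)) < 1e-8

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_amos_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(6):
            y = rng.uniform(1.0, 28.0)
            x = y * rng.uniform(0.2, 0.95)
            m1 = rng.uniform(1.1, 1.8) + 1j * rng.uniform(0.0, 0.4)
            m2 = rng.uniform(1.1, 1.8) + 1j * rng.uniform(0.0, 0.4)
            radius = 10.0
            v = y / (2 * np.pi * radius * 1e-4)
            geom = SphereGeometry(radius, radius * x / y)
            res = qext_coated(m1, m2, geom, WavenumberGrid(np.array([v])))
            qe, qs = oracle_coated(m1, m2, x, y)
            assert res.q_ext[0] == pytest.approx(qe, rel=1e-7)
            assert res.q_sca[0] == pytest.approx(qs, rel=1e-7)

    def test_requires_a_core(self, sphere_10um, midir_grid):
        with pytest.raises(ValueError, match="no core"):
            qext_coated(1.5 + 0j, 1.5 + 0j, sphere_10um, midir_grid)


class TestForwardFromDispersion:
    def test_vacuum_dispersion_gives_zero_spectrum(self, sphere_10um, midir_grid):
        model = VoxelDispersion._degenerate(n_infinity=1.0)
        spec = qext_from_dispersion(model, sphere_10um, midir_grid)
        assert spec.kind == "qext"
        assert np.allclose(spec.values, 0.0, atol=1e-10)

    def test_identical_layers_equal_homogeneous(self, layered_10_8, sphere_10um, midir_grid):
        model = random_dispersion(n_bands=3, seed=0)
        two = qext_from_dispersion((model, model), layered_10_8, midir_grid)
        one = qext_from_dispersion(model, sphere_10um, midir_grid)
        assert np.max(np.abs(two.values - one.values)) < 1e-8

    def test_band_center_leaves_a_spectral_feature(self, sphere_10um):
        grid = WavenumberGrid.regular(500.0, 4000.0, 2.0)
        model = VoxelDispersion.from_arrays([1730.0], [0.3], [30.0], n_infinity=1.48)
        with_band = qext_from_dispersion(model, sphere_10um, grid).values
        flat = qext_from_dispersion(
            VoxelDispersion._degenerate(1.48), sphere_10um, grid).values
        near = np.abs(grid.values - 1730.0) < 60
        far = np.abs(grid.values - 1730.0) > 500
        assert np.max(np.abs(with_band - flat)[near]) > 10 * np.median(
            np.abs(with_band - flat)[far])

    def test_model_geometry_arity_checked(self, layered_10_8, midir_grid):
        model = random_dispersion(n_bands=2, seed=1)
        with pytest.raises(ValueError, match="voxel"):
            qext_from_dispersion((model,), layered_10_8, midir_grid)
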