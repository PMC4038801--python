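import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import erf, j1

from sasglobal import form_factors as ff
from sasglobal.errors import ParameterError
from sasglobal.synthetic_data import toy_pdb


def fill_sphere(R, spacing):
    g = np.arange(-R, R + spacing, spacing)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return pts[np.linalg.norm(pts, axis=1) <= R]


def debye_sum(points, weights, q):
    """Brute-force Debye sum in manageable memory chunks."""
    total = 0.0
    for start in range(0, len(points), 1000):
        block = points[start:start + 1000]
        d = np.linalg.norm(block[:, None, :] - points[None, :, :], axis=-1)
        total += np.sum(weights[start:start + 1000, None] * weights[None, :]
                        * np.sinc(q * d / np.pi))
    return total


class TestSphere:
    def test_forward_limit(self):
        R, drho = 30.0, 2e-6
        V = 4.0 / 3.0 * np.pi * R ** 3
        assert ff.sphere_intensity(np.array([0.0]), R, drho)[0] == \
            pytest.approx((drho * V) ** 2)

    def test_first_zero(self):
        # tan(x) = x root, found independently by bracketing
        x0 = brentq(lambda x: np.tan(x) - x, 4.1, 4.6)
        assert x0 == pytest.approx(4.4934, abs=1e-3)
        R = 20.0
        q_zero = brentq(
            lambda q: ff.sphere_intensity(np.array([q]), R, 1.0)[0]
            - 0.0, None, None) if False else None
        amp = lambda q: ff._sphere_amp(np.array([q * R]))[0]  # noqa: E731
        q_zero = brentq(amp, 4.0 / R, 4.8 / R)
        assert q_zero * R == pytest.approx(x0, rel=1e-6)

    def test_against_discretized_debye_oracle(self):
        R, drho, q = 20.0, 2e-6, 0.1
        pts = fill_sphere(R, 1.5)
        V = 4.0 / 3.0 * np.pi * R ** 3
        w = np.full(len(pts), drho * V / len(pts))
        oracle = debye_sum(pts, w, q)
        closed = ff.sphere_intensity(np.array([q]), R, drho)[0]
        assert closed == pytest.approx(oracle, rel=5e-3)

    def test_invalid_radius(self):
        with pytest.raises(ParameterError):
            ff.sphere_intensity(np.array([0.1]), -1.0, 1.0)


class TestSphereDimer:
    def test_zero_q_is_twice_coherent(self):
        R, drho = 17.0, 2e-6
        V = 4.0 / 3.0 * np.pi * R ** 3
        assert ff.sphere_dimer_intensity(np.array([0.0]), R, drho)[0] == \
            pytest.approx(4.0 * (drho * V) ** 2)


class TestCylinder:
    def test_degenerate_shell_matches_uniform_quadrature(self):
        # independent oracle: adaptive quadrature of the closed-form
        # uniform-cylinder orientational average
        R, L, drho = 20.0, 200.0, 1e-6
        q = 0.08
        V = np.pi * R ** 2 * L

        def integrand(alpha):
            qr = q * R * np.sin(alpha)
            qz = q * L * np.cos(alpha) / 2.0
            lam = 2.0 * j1(qr) / qr if qr > 0 else 1.0
            return (drho * V * lam * np.sinc(qz / np.pi)) ** 2 \
                * np.sin(alpha)

        oracle, _ = quad(integrand, 0.0, np.pi / 2.0, limit=200)
        val = ff.core_shell_cylinder_intensity(
            np.array([q]), R, 0.0, L, drho, 0.0, 0.0, n_angles=128)[0]
        assert val == pytest.approx(oracle, rel=1e-5)

    def test_long_rod_q_inverse_regime(self):
        R, L = 20.0, 6000.0
        q = np.geomspace(0.01, 0.03, 12)   # 1 << qL, qR < 1
        intensity = ff.core_shell_cylinder_intensity(q, R, 0.0, L, 1e-6,
                                                     0.0, 0.0, n_angles=256)
        slope = np.polyfit(np.log(q), np.log(intensity), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.08)

    def test_quadrature_convergence(self):
        q = np.linspace(0.01, 0.2, 30)    # q R_core < 5
        args = (20.0, 5.0, 300.0, 3e-6, 1e-6, 0.0)
        i64 = ff.core_shell_cylinder_intensity(q, *args, n_angles=64)
        i128 = ff.core_shell_cylinder_intensity(q, *args, n_angles=128)
        assert np.max(np.abs(i128 - i64) / i64) < 1e-4

    def test_minimum_angles_enforced(self):
        with pytest.raises(ParameterError):
            ff.core_shell_cylinder_intensity(np.array([0.1]), 20, 5, 100,
                                             1, 0, 0, n_angles=8)


class TestLamella:
    def test_sharp_slab_closed_form(self):
        # uniform slab of thickness t: F = 2 drho sin(q t/2)/q
        drho, t = 5e-6, 40.0
        p = ff.LamellaParams(z_hc=t / 2.0, t_polar=0.0, rho_hc=drho,
                             rho_polar=0.0, rho_solv=0.0)
        q = np.linspace(0.01, 0.5, 40)
        np.testing.assert_allclose(ff.lamella_amplitude(q, p),
                                   2.0 * drho * np.sin(q * t / 2.0) / q,
                                   rtol=1e-12)

    def test_amplitude_matches_profile_quadrature(self):
        p = ff.LamellaParams(z_hc=14.0, t_polar=6.0, rho_hc=-2e-6,
                             rho_polar=3e-6, rho_solv=0.0, s_hc=2.0,
                             s_polar=1.5)

        def profile(z):
            # centrosymmetric erf-smoothed steps
            def strip(zb, s):
                if s == 0:
                    return 1.0 * (abs(z) <= zb)
                return 0.5 * (erf((z + zb) / (np.sqrt(2) * s))
                              - erf((z - zb) / (np.sqrt(2) * s)))
            return ((p.rho_hc - p.rho_polar) * strip(p.z_hc, p.s_hc)
                    + (p.rho_polar - p.rho_solv)
                    * strip(p.z_hc + p.t_polar, p.s_polar))

        for q in (0.02, 0.1, 0.31):
            oracle = 2.0 * quad(lambda z: profile(z) * np.cos(q * z),
                                0.0, 60.0, limit=400)[0]
            val = ff.lamella_amplitude(np.array([q]), p)[0]
            assert val == pytest.approx(oracle, rel=1e-6)

    def test_smoothing_zero_recovers_sharp(self):
        q = np.linspace(0.01, 0.4, 30)
        smooth = ff.LamellaParams(15.0, 5.0, -2e-6, 3e-6, 0.0, 1e-9, 1e-9)
        sharp = ff.LamellaParams(15.0, 5.0, -2e-6, 3e-6, 0.0, 0.0, 0.0)
        np.testing.assert_allclose(ff.lamella_intensity(q, smooth),
                                   ff.lamella_intensity(q, sharp), rtol=1e-8)


class TestWormlike:
    def test_chain_factor_normalized(self):
        assert ff.wormlike_chain_factor(np.array([0.0]), 420.0, 4.2)[0] == 1.0

    def test_ideal_variant_matches_debye(self):
        b, n_b = 4.2, 100.0
        L = b * n_b
        rg = np.sqrt(ff.wormlike_rg2(L, b, nu=0.5))
        q = np.linspace(1e-3, 2.0 / rg, 50)
        chain = ff.wormlike_chain_factor(q, L, b, nu=0.5)
        debye = ff._debye_function((q * rg) ** 2)
        assert np.max(np.abs(chain - debye) / debye) < 0.02

    def test_cross_section_normalized_at_zero(self):
        val = ff.wormlike_cross_section(np.array([0.0]), 4.0, 3.0, 0.95,
                                        1.8e-6, 6.38e-6)[0]
        assert val == pytest.approx(1.0)

    def test_forward_intensity_is_total_excess_length(self):
        p = ff.WormlikeParams()
        rho_shell = p.d_w * p.rho_solv
        lin = ((p.rho_core - rho_shell) * np.pi * p.R ** 2
               + (rho_shell - p.rho_solv) * np.pi * (p.R + p.delta) ** 2)
        expected = (lin * p.contour_length) ** 2
        assert ff.wormlike_intensity(np.array([0.0]), p)[0] == \
            pytest.approx(expected)

    def test_segment_count_validated(self):
        with pytest.raises(ParameterError):
            ff.WormlikeParams(N_b=0.5)


@pytest.mark.parametrize("evaluate", [
    lambda q, c: ff.sphere_intensity(q, 30.0, c * 2e-6),
    lambda q, c: ff.sphere_dimer_intensity(q, 30.0, c * 2e-6),
    lambda q, c: ff.core_shell_cylinder_intensity(
        q, 20.0, 5.0, 200.0, c * 3e-6, c * 1e-6, 0.0),
    lambda q, c: ff.lamella_intensity(
        q, ff.LamellaParams(15.0, 5.0, c * -2e-6, c * 3e-6, 0.0)),
], ids=["sphere", "dimer", "cylinder", "lamella"])
def test_contrast_scaling_property(evaluate):
    """Scaling all contrasts by c multiplies intensities by c^2."""
    q = np.linspace(0.02, 0.3, 20)
    np.testing.assert_allclose(evaluate(q, 3.0), 9.0 * evaluate(q, 1.0),
                               rtol=1e-10)


def test_intensities_nonnegative_and_finite_at_zero():
    q = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 50)])
    for intensity in (
            ff.sphere_intensity(q, 30.0, 2e-6),
            ff.sphere_dimer_intensity(q, 30.0, 2e-6),
            ff.core_shell_cylinder_intensity(q, 20.0, 5.0, 200.0, 3e-6,
                                             1e-6, 0.0),
            ff.wormlike_intensity(q, ff.WormlikeParams())):
        assert np.all(np.isfinite(intensity))
        assert np.all(intensity >= 0)


# ---------------------------------------------------------------------------
# atomic structures
# ---------------------------------------------------------------------------

class TestLoadStructure:
    def test_toy_roundtrip(self, tmp_path):
        path = tmp_path / "three.pdb"
        toy_pdb(3, geometry="line", path=path, spacing=5.0)
        s = ff.load_structure(path)
        assert s.n_atoms == 3
        np.testing.assert_allclose(s.positions[:, 0], [0.0, 5.0, 10.0],
                                   atol=1e-3)
        assert s.elements == ["C", "C", "C"]

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60"
            " 10.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40"
            " 10.00           C\n"
            "END\n")
        path = tmp_path / "altloc.pdb"
        path.write_text(text)
        s = ff.load_structure(path)
        assert s.n_atoms == 1
        assert s.positions[0, 0] == pytest.approx(0.0)

    def test_glycine_composition(self, tmp_path):
        lines = [
            ("N", 0.0, 0.0, 0.0), ("CA", 1.45, 0.0, 0.0),
            ("C", 2.0, 1.4, 0.0), ("O", 3.2, 1.5, 0.0),
        ]
        text = ""
        for i, (name, x, y, z) in enumerate(lines, start=1):
            el = name[0]
            text += (f"ATOM  {i:5d}  {name:<3s}GLY A   1    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00 10.00"
                     f"          {el:>2s}\n")
        path = tmp_path / "gly.pdb"
        path.write_text(text + "END\n")
        s = ff.load_structure(path)
        counts = {el: s.elements.count(el) for el in set(s.elements)}
        assert counts == {"C": 2, "N": 1, "O": 1}

    def test_waters_dropped(self, tmp_path):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00"
            " 10.00           C\n"
            "HETATM    2  O   HOH A   2       5.000   0.000   0.000  1.00"
            " 10.00           O\n"
            "END\n")
        path = tmp_path / "wat.pdb"
        path.write_text(text)
        assert ff.load_structure(path).n_atoms == 1

    def test_empty_structure_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ParameterError):
            ff.load_structure(path)


class TestHydrationShell:
    def _single_atom(self):
        return ff.AtomicStructure(["C"], np.zeros((1, 3)), np.ones(1))

    def test_single_atom_matches_brute_force(self):
        s = self._single_atom()
        spacing, tol, r_w = 2.8, 0.5, 1.4
        shell = ff.build_hydration_shell(s, spacing=spacing,
                                         contact_tol=tol, r_w=r_w)
        contact = ff.VDW_RADIUS["C"] + r_w
        pad = ff.VDW_RADIUS["C"] + r_w + tol + spacing
        pts = ff.fcc_lattice_points([-pad] * 3, [pad] * 3, spacing)
        d = np.linalg.norm(pts, axis=1)
        expected = np.sum(np.abs(d - contact) <= tol)
        assert len(shell.hydration_sites) == expected
        assert expected > 0

    def test_zero_tolerance_with_irrational_offset(self):
        s = self._single_atom()
        shell = ff.build_hydration_shell(
            s, contact_tol=0.0, offset=(0.1234567, 0.0712345, 0.0987123))
        assert len(shell.hydration_sites) == 0

    def test_two_distant_atoms_additive(self):
        a = 2.8 * np.sqrt(2.0)
        s1 = self._single_atom()
        pos = np.array([[0.0, 0.0, 0.0], [12 * a, 0.0, 0.0]])
        s2 = ff.AtomicStructure(["C", "C"], pos, np.ones(2))
        n1 = len(ff.build_hydration_shell(s1).hydration_sites)
        n2 = len(ff.build_hydration_shell(s2).hydration_sites)
        assert n2 == 2 * n1

    def test_sites_do_not_overlap_atoms(self):
        rng = np.random.default_rng(4)
        pos = rng.uniform(-6, 6, size=(10, 3))
        s = ff.AtomicStructure(["C"] * 10, pos, np.ones(10))
        shell = ff.build_hydration_shell(s, contact_tol=0.5)
        for site in shell.hydration_sites:
            d = np.linalg.norm(pos - site, axis=1)
            assert np.all(d >= ff.VDW_RADIUS["C"] + ff.WATER_RADIUS - 0.5
                          - 1e-9)

    def test_invalid_spacing(self):
        with pytest.raises(ParameterError):
            ff.build_hydration_shell(self._single_atom(), spacing=0.0)


class TestPdbIntensity:
    def test_single_atom(self):
        s = ff.AtomicStructure(["C"], np.zeros((1, 3)), np.ones(1))
        q = np.array([0.0, 0.1, 0.5])
        f = ff.effective_amplitudes(q, s)
        np.testing.assert_allclose(ff.pdb_intensity(q, s), f[0] ** 2,
                                   rtol=1e-12)

    def test_two_atom_closed_form(self):
        d = 7.0
        s = ff.AtomicStructure(["C", "C"],
                               np.array([[0.0, 0, 0], [d, 0, 0]]),
                               np.ones(2))
        q = np.array([0.05, 0.2, 0.7])
        f = ff.effective_amplitudes(q, s)[0]
        expected = 2.0 * f ** 2 * (1.0 + np.sinc(q * d / np.pi))
        np.testing.assert_allclose(ff.pdb_intensity(q, s), expected,
                                   rtol=1e-12)

    def test_debye_equals_orientational_average(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(-12, 12, size=(50, 3))
        pos = pos[np.linalg.norm(pos, axis=1) <= 12][:50]
        s = ff.AtomicStructure(["C"] * len(pos), pos, np.ones(len(pos)))
        q_values = np.array([0.05, 0.15, 0.4])
        f = ff.effective_amplitudes(q_values, s)
        debye = ff.pdb_intensity(q_values, s)
        # oracle: average |sum f exp(i q.r)|^2 over a dense angular grid
        from numpy.polynomial.legendre import leggauss
        ct, wt = leggauss(30)
        phi = np.linspace(0.0, 2 * np.pi, 40, endpoint=False)
        st_ = np.sqrt(1.0 - ct ** 2)
        dirs = np.stack([np.outer(st_, np.cos(phi)).ravel(),
                         np.outer(st_, np.sin(phi)).ravel(),
                         np.repeat(ct, phi.size)], axis=1)
        w = np.repeat(wt, phi.size) / (2.0 * phi.size)
        for iq, qv in enumerate(q_values):
            phase = np.exp(1j * qv * dirs @ pos.T)
            amp2 = np.abs(phase @ f[:, iq]) ** 2
            oracle = np.sum(w * amp2)
            assert debye[iq] == pytest.approx(oracle, rel=2e-3)

    def test_unit_shell_density_equals_no_shell(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform(-5, 5, size=(8, 3))
        s = ff.AtomicStructure(["C"] * 8, pos, np.ones(8))
        shell = ff.build_hydration_shell(s)
        assert len(shell.hydration_sites) > 0
        q = np.linspace(0.01, 0.5, 10)
        np.testing.assert_allclose(ff.pdb_intensity(q, shell, d_w=1.0),
                                   ff.pdb_intensity(q, s), rtol=1e-12)

    def test_atom_budget(self):
        s = ff.AtomicStructure(["C"] * 10, np.random.default_rng(0)
                               .uniform(-5, 5, (10, 3)), np.ones(10))
        with pytest.raises(ParameterError, match="coarse-grain"):
            ff.pdb_intensity(np.array([0.1]), s, max_scatterers=5)
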