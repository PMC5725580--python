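"""Molecular reference frame, dipole projection, ensemble dipole, tilt scan."""

import numpy as np
import pytest

import polarmic as pm
from polarmic.molframe import (
    GFP_DIPOLE_SLOPE,
    OrientationState,
    ensemble_dipole,
    orient,
    project_dipole,
    tilt_scan,
)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


class TestBuildFrame:
    def test_canonical_points_identity(self):
        fr = pm.build_frame((0, 0, 0), (1, 0, 0), (0, 0, 1))
        pts = np.array([[0.3, -0.2, 0.7], [1, 2, 3]])
        assert np.allclose(fr.apply(pts), pts)

    def test_invariants_on_arbitrary_points(self, rng):
        lig, aj, bj = rng.normal(size=(3, 3)) * 10
        fr = pm.build_frame(lig, aj, bj)
        t_lig, t_aj, t_bj = fr.apply(np.array([lig, aj, bj]))
        assert np.allclose(t_lig, 0, atol=1e-9)
        assert t_aj[0] > 0 and np.allclose(t_aj[1:], 0, atol=1e-9)
        assert abs(t_bj[1]) < 1e-9 and t_bj[2] > 0
        # right-handed orthonormal rotation
        assert np.linalg.det(fr.rotation) == pytest.approx(1.0)

    def test_removes_arbitrary_rigid_motion(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        lig, aj, bj = pts[0], pts[1], pts[2]
        R = random_rotation(rng)
        shift = rng.normal(size=3) * 20
        moved = pts @ R.T + shift
        f1 = pm.build_frame(lig, aj, bj)
        f2 = pm.build_frame(moved[0], moved[1], moved[2])
        assert np.allclose(f1.apply(pts), f2.apply(moved), atol=1e-9)

    def test_frame_idempotent(self, rng):
        lig, aj, bj = rng.normal(size=(3, 3)) * 10
        fr = pm.build_frame(lig, aj, bj)
        framed = fr.apply(np.array([lig, aj, bj]))
        fr2 = pm.build_frame(*framed)
        assert np.allclose(fr2.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(fr2.translation, 0, atol=1e-9)

    def test_swapped_junctions_differ(self, rng):
        lig, aj, bj = rng.normal(size=(3, 3)) * 10
        f1 = pm.build_frame(lig, aj, bj)
        f2 = pm.build_frame(lig, bj, aj)
        assert not np.allclose(f1.rotation, f2.rotation, atol=1e-3)

    def test_collinear_errors(self):
        with pytest.raises(ValueError):
            pm.build_frame((0, 0, 0), (1, 0, 0), (2, 0, 0))


class TestGfpDipoleAxis:
    def test_published_slope_normalized(self):
        v = pm.gfp_dipole_axis(slope=GFP_DIPOLE_SLOPE)
        norm = np.linalg.norm(GFP_DIPOLE_SLOPE)
        assert np.allclose(v, np.asarray(GFP_DIPOLE_SLOPE) / norm)
        assert np.allclose(v, (-0.02665, 0.89267, 0.44992), atol=5e-5)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_atom_based_axis(self):
        v = pm.gfp_dipole_axis(atoms=[(0, 0, 0), (0, 1, 0), (0, 1, 0)])
        assert np.allclose(v, (0, 1, 0))

    def test_atoms_match_slope_on_synthetic_fixture(self):
        u = pm.gfp_dipole_axis(slope=GFP_DIPOLE_SLOPE)
        n112 = np.array([1.0, 2.0, 3.0])
        mid = n112 + 2.5 * u
        v = pm.gfp_dipole_axis(atoms=[n112, mid + (0, 0, 0), mid - (0, 0, 0)])
        assert np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1))) < 1e-6

    def test_sign_convention_positive_y(self):
        v = pm.gfp_dipole_axis(slope=(0.1, -0.9, 0.2))
        assert v[1] > 0

    def test_requires_exactly_one_input(self):
        with pytest.raises(ValueError):
            pm.gfp_dipole_axis()


class TestOrient:
    def test_reference_state_is_identity(self, rng):
        d = rng.normal(size=(5, 3))
        assert np.allclose(orient(d, OrientationState(0.0, 90.0)), d)

    def test_y_dipole_invariant_under_phi_tilt(self):
        for phi in (11.25, 45.0, 67.5):
            out = orient(np.array([0.0, 1.0, 0.0]), OrientationState(0.0, phi))
            assert np.allclose(out, (0, 1, 0), atol=1e-12)

    def test_z_dipole_tilts_into_x(self):
        out = orient(np.array([0.0, 0.0, 1.0]), OrientationState(0.0, 45.0))
        s = np.sin(np.radians(45.0))
        assert np.allclose(out, (s, 0.0, s), atol=1e-12)


class TestProjectDipole:
    @pytest.mark.parametrize("vec, angle, mag", [
        ((0, 1, 0), 90.0, 1.0),
        ((1, 1, 0), 45.0, np.sqrt(2)),
        ((0.5, 0.5, 0.707), 45.0, np.hypot(0.5, 0.5)),
    ])
    def test_examples(self, vec, angle, mag):
        pr = project_dipole(vec)
        assert pr.angle_deg == pytest.approx(angle)
        assert pr.magnitude == pytest.approx(mag)

    def test_axial_vector_flagged(self):
        pr = project_dipole((0, 0, 1))
        assert np.isnan(pr.angle_deg) and pr.magnitude == 0.0

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            project_dipole((0, 0, 0))


class TestEnsembleDipole:
    def test_coherent_limit(self):
        d = np.tile([np.cos(np.radians(35.0)), np.sin(np.radians(35.0)), 0.0], (7, 1))
        th, p = ensemble_dipole(d)
        assert float(pm.circ_dist180(th, 35.0)) < 1e-9
        assert p == pytest.approx(1.0)

    def test_orthogonal_cancellation(self):
        d = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        _, p = ensemble_dipole(d)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_wrapped_normal_monte_carlo(self, rng):
        ang = np.radians(rng.normal(95.0, 10.0, size=2000))
        d = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
        th, p = ensemble_dipole(d)
        assert float(pm.circ_dist180(th, 95.0)) < 1.0
        assert 0.0 < p < 1.0

    def test_p_decreases_with_spread(self, rng):
        ps = []
        for sd in (5.0, 15.0, 30.0, 60.0):
            ang = np.radians(rng.normal(0.0, sd, size=4000))
            d = np.column_stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)])
            ps.append(ensemble_dipole(d)[1])
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_dyad_symmetry_negation(self, rng):
        d = rng.normal(size=(50, 3))
        th1, p1 = ensemble_dipole(d)
        th2, p2 = ensemble_dipole(-d)
        assert th1 == pytest.approx(th2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_all_axial_errors(self):
        with pytest.raises(ValueError):
            ensemble_dipole(np.array([[0.0, 0.0, 1.0]]))


class TestSelection:
    def test_lowest_40_percent_kept_stably(self):
        dips = np.eye(3)[[0, 1, 2, 0, 1]]
        ens = pm.DipoleEnsemble(dipoles=dips, energies=[5.0, 1.0, 1.0, 1.0, 9.0])
        sel = ens.selected()
        # ceil(0.4 * 5) = 2; ties at energy 1.0 broken by input order
        assert sel.shape == (2, 3)
        assert np.allclose(sel, dips[[1, 2]])


class TestTiltScan:
    def test_y_dipoles_consistent_at_all_phi(self):
        # dipoles along y are invariant under the phi tilt -> theta_ens = 90
        ens = pm.DipoleEnsemble(dipoles=np.tile([0.0, 1.0, 0.0], (10, 1)),
                                energies=np.zeros(10))
        table = tilt_scan(ens, measured_theta_d=95.4, measured_sd=10.1)
        assert table["consistent"].all()
        assert np.allclose(table["theta_ens"], 90.0)

    def test_zero_width_band_inconsistent(self):
        ens = pm.DipoleEnsemble(dipoles=np.tile([0.0, 1.0, 0.0], (4, 1)),
                                energies=np.zeros(4))
        table = tilt_scan(ens, measured_theta_d=40.0, measured_sd=0.0)
        assert not table["consistent"].any()

    def test_circular_wraparound(self):
        # theta_ens = 2 deg vs measurement 178 deg: distance 4, within sd 5
        ang = np.radians(2.0)
        ens = pm.DipoleEnsemble(
            dipoles=np.tile([np.cos(ang), np.sin(ang), 0.0], (4, 1)),
            energies=np.zeros(4))
        table = tilt_scan(ens, measured_theta_d=178.0, measured_sd=5.0,
                          phi_grid=[90.0])
        assert table["consistent"].all()

    def test_rigid_motion_invariance_of_scan(self, rng):
        # framing removes any rigid motion applied to the input structure
        pts = rng.normal(size=(8, 3)) * 5
        R = random_rotation(rng)
        shift = rng.normal(size=3) * 10
        moved = pts @ R.T + shift
        f1 = pm.build_frame(pts[0], pts[1], pts[2])
        f2 = pm.build_frame(moved[0], moved[1], moved[2])
        dip_dirs = rng.normal(size=(20, 3))
        e = rng.normal(size=20)
        ens1 = pm.DipoleEnsemble(f1.apply_vector(dip_dirs), e)
        ens2 = pm.DipoleEnsemble(f2.apply_vector(dip_dirs @ R.T), e)
        t1 = tilt_scan(ens1, 95.4, 10.1)
        t2 = tilt_scan(ens2, 95.4, 10.1)
        assert np.allclose(t1["theta_ens"], t2["theta_ens"], atol=1e-6)
        assert np.allclose(t1["p_ens"], t2["p_ens"], atol=1e-9)


class TestEnsembleIO:
    def test_csv_round_trip(self, tmp_path, rng):
        import pandas as pd
        d = rng.normal(size=(12, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        e = rng.normal(size=12)
        path = tmp_path / "ens.csv"
        pd.DataFrame({"dx": d[:, 0], "dy": d[:, 1], "dz": d[:, 2],
                      "energy": e}).to_csv(path, index=False)
        ens = pm.read_ensemble_csv(path)
        assert np.allclose(ens.dipoles, d)
        assert np.allclose(ens.energies, e)

    def test_missing_columns_error(self, tmp_path):
        import pandas as pd
        path = tmp_path / "bad.csv"
        pd.DataFrame({"dx": [1.0], "dy": [0.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            pm.read_ensemble_csv(path)

    def test_multi_model_pdb_dipoles(self, tmp_path):
        # two-model synthetic PDB carrying the three named GFP atoms
        lines = []
        for m, shift in ((1, 0.0), (2, 1.0)):
            lines.append(f"MODEL     {m:4d}")
            lines.append(
                "ATOM      1  N   VAL A 112    "
                f"{0.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           N")
            lines.append(
                "ATOM      2  C   ASN A 146    "
                f"{shift:8.3f}{4.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
            lines.append(
                "ATOM      3  O   SER A 147    "
                f"{shift:8.3f}{4.0:8.3f}{2.0:8.3f}  1.00  0.00           O")
            lines.append("ENDMDL")
        lines.append("END")
        path = tmp_path / "synthetic_gfp_models.pdb"
        path.write_text("\n".join(lines) + "\n")
        from polarmic.molframe import read_ensemble_pdb_dipoles
        ens = read_ensemble_pdb_dipoles(path)
        assert len(ens) == 2
        expected0 = np.array([0.0, 4.0, 1.0])
        expected0 /= np.linalg.norm(expected0)
        assert np.allclose(ens.dipoles[0], expected0, atol=1e-6)
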