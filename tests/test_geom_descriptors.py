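"""Superposition, RMSD/RMSF, average structures and organizational geometry."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import quartersite as qs
from quartersite.errors import SuperpositionError
from quartersite.geom_descriptors import place_by_internal_coordinates

from conftest import apply_rigid, random_rigid

FULL = qs.FrameWindow.tail(1.0)


def quaternion_superposition_rmsd(mobile, reference):
    """Horn's closed-form quaternion method — independent of the SVD path."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    m = mob.T @ ref
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals = np.linalg.eigvalsh(k)
    lam = eigvals[-1]
    e0 = (mob ** 2).sum() + (ref ** 2).sum()
    msd = max((e0 - 2 * lam) / len(mob), 0.0)
    return np.sqrt(msd)


def oracle_dihedral(p1, p2, p3, p4):
    """Normal-vector formulation with triple-product sign — independent path."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cos = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    return ang


class TestKabsch:
    def test_identity_on_identical_sets(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        sp = qs.kabsch(pts, pts)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sp.rotation, np.eye(3), atol=1e-9)

    def test_rigidly_rotated_copy_rmsd_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3)) * 4
        rot, trans = random_rigid(rng)
        moved = pts @ rot.T + trans
        sp = qs.kabsch(moved, pts)
        assert sp.rmsd < 1e-6
        np.testing.assert_allclose(sp.apply(moved), pts, atol=1e-6)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            mob = rng.normal(size=(5, 3)) * 3
            ref = rng.normal(size=(5, 3)) * 3
            sp = qs.kabsch(mob, ref)
            assert sp.rmsd == pytest.approx(
                quaternion_superposition_rmsd(mob, ref), abs=1e-6
            )

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(3)
        mob = rng.normal(size=(4, 3))
        # a mirrored target must still produce det(+1)
        ref = mob.copy()
        ref[:, 0] *= -1
        sp = qs.kabsch(mob, ref)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_or_collinear_atoms_rejected(self):
        with pytest.raises(SuperpositionError):
            qs.kabsch(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(SuperpositionError, match="collinear"):
            qs.kabsch(line, line)


class TestRmsdSeries:
    def test_static_ensemble_is_zero(self, template):
        ens = qs.Ensemble(
            topology=template.ensemble.topology,
            coords=np.repeat(template.ensemble.coords, 4, axis=0),
        )
        sel = qs.SelectionSpec(chain_id="A", atom_name="CA")
        series = qs.rmsd_series(ens, sel, sel)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_measure_equals_fit_reproduces_kabsch_rmsd(self, small_ensemble):
        ens, _ = small_ensemble
        sel = qs.SelectionSpec(chain_id="A", atom_name="CA")
        idx = qs.select(ens, sel)
        series = qs.rmsd_series(ens, sel, sel, reference=0)
        for f in range(ens.n_frames):
            expected = qs.kabsch(ens.coords[f][idx], ens.coords[0][idx]).rmsd
            assert series[f] == pytest.approx(expected, abs=1e-9)

    def test_brute_force_oracle(self, small_ensemble):
        """Superpose-then-measure, re-derived step by step per frame."""
        ens, _ = small_ensemble
        fit = qs.SelectionSpec(chain_id="A", atom_name="CA")
        measure = qs.SelectionSpec(chain_id="A", res_id=120)
        series = qs.rmsd_series(ens, fit, measure, reference=0)
        fit_idx = qs.select(ens, fit)
        meas_idx = qs.select(ens, measure)
        for f in range(5):
            sp = qs.kabsch(ens.coords[f][fit_idx], ens.coords[0][fit_idx])
            moved = ens.coords[f][meas_idx] @ sp.rotation.T + sp.translation
            expected = np.sqrt(((moved - ens.coords[0][meas_idx]) ** 2).sum(1).mean())
            assert series[f] == pytest.approx(expected, abs=1e-12)


class TestRmsf:
    def test_static_ensemble_zero(self, template):
        ens = qs.Ensemble(
            topology=template.ensemble.topology,
            coords=np.repeat(template.ensemble.coords, 6, axis=0),
        )
        prof = qs.rmsf(ens, qs.SelectionSpec(chain_id="A", atom_name="CA"), FULL)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-9)

    def test_single_jittered_atom_closed_form(self, template):
        """One atom jittered with std σ per coordinate → RMSF = σ√3 (±5 %)."""
        sigma = 0.5
        truth = qs.PlantedTruth(
            contacts=[], n_frames=5000, bend_deg=0.0, corr_pair=None,
            fluct_sigma=0.0, sigma_overrides={"A:180:CA": sigma},
        )
        ens, _ = qs.generate(template, truth, seed=7)
        prof = qs.rmsf(ens, qs.SelectionSpec(chain_id="A", atom_name="CA"), FULL)
        values = dict(zip(prof.res_keys, prof.values))
        assert values[("A", 180)] == pytest.approx(sigma * np.sqrt(3), rel=0.05)
        others = [v for k, v in values.items() if k != ("A", 180)]
        assert max(others) < 0.05

    def test_rigid_motion_invariance(self, template):
        truth = qs.PlantedTruth(contacts=[], n_frames=40, bend_deg=0.0, corr_pair=None)
        ens, _ = qs.generate(template, truth, seed=11)
        rng = np.random.default_rng(4)
        rot, trans = random_rigid(rng)
        moved = qs.Ensemble(
            topology=ens.topology, coords=apply_rigid(ens.coords, rot, trans)
        )
        sel = qs.SelectionSpec(chain_id="B", atom_name="CA")
        a = qs.rmsf(ens, sel, FULL, fit_sel=sel)
        b = qs.rmsf(moved, sel, FULL, fit_sel=sel)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_initial_reference_mode_differs(self, template):
        truth = qs.PlantedTruth(contacts=[], n_frames=30, bend_deg=0.0, corr_pair=None)
        ens, _ = qs.generate(template, truth, seed=13)
        sel = qs.SelectionSpec(chain_id="A", atom_name="CA")
        mean_ref = qs.rmsf(ens, sel, FULL, fit_sel=sel, reference="mean")
        init_ref = qs.rmsf(ens, sel, FULL, fit_sel=sel, reference="initial")
        # deviations from a single frame exceed deviations from the mean
        assert init_ref.values.mean() > mean_ref.values.mean()


class TestAverageStructure:
    def test_static_equals_any_frame(self, template):
        ens = qs.Ensemble(
            topology=template.ensemble.topology,
            coords=np.repeat(template.ensemble.coords, 5, axis=0),
        )
        avg = qs.average_structure(ens, FULL)
        np.testing.assert_allclose(avg, ens.coords[0], atol=1e-9)

    def test_two_mirrored_frames_average_to_midpoint(self):
        rng = np.random.default_rng(6)
        fixed = rng.normal(size=(4, 3)) * 5
        free0 = np.array([[1.0, 2.0, 3.0]])
        free1 = np.array([[3.0, 2.0, 1.0]])
        top = qs.Topology.from_records(
            [(i + 1, "CA", "ALA", i + 1, "A", "C") for i in range(5)]
        )
        coords = np.stack(
            [np.vstack([fixed, free0]), np.vstack([fixed, free1])]
        )
        ens = qs.Ensemble(topology=top, coords=coords)
        avg = qs.average_structure(
            ens, FULL, fit_sel=qs.SelectionSpec(res_id=(1, 2, 3, 4))
        )
        np.testing.assert_allclose(avg[:4], fixed, atol=1e-9)
        np.testing.assert_allclose(avg[4], (free0[0] + free1[0]) / 2, atol=1e-9)

    def test_oracle_equality(self, small_ensemble):
        ens, _ = small_ensemble
        fit = qs.SelectionSpec(chain_id="E")
        avg = qs.average_structure(ens, FULL, fit)
        fit_idx = qs.select(ens, fit)
        acc = np.zeros((ens.n_atoms, 3))
        for f in range(ens.n_frames):
            sp = qs.kabsch(ens.coords[f][fit_idx], ens.coords[0][fit_idx])
            acc += ens.coords[f] @ sp.rotation.T + sp.translation
        np.testing.assert_allclose(avg, acc / ens.n_frames, atol=1e-9)


class TestAnglesAndDihedrals:
    def test_collinear_angle_is_180(self):
        assert qs.angle([0, 0, 0], [1, 0, 0], [2, 0, 0]) == pytest.approx(180.0)

    def test_cis_dihedral_is_zero(self):
        assert qs.dihedral(
            [1, 1, 0], [0, 0, 0], [2, 0, 0], [3, 1, 0]
        ) == pytest.approx(0.0, abs=1e-9)

    def test_matches_vector_algebra_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            pts = rng.normal(size=(4, 3)) * 5
            expected = oracle_dihedral(*pts)
            assert qs.dihedral(*pts) == pytest.approx(expected, abs=1e-9)

    def test_matches_mdanalysis_convention(self):
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(4, 3)).astype(np.float64) * 4
        expected = float(np.degrees(calc_dihedrals(*(p[None] for p in pts))[0]))
        assert qs.dihedral(*pts) == pytest.approx(expected, abs=1e-4)

    def test_dihedral_flips_sign_under_mirror(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(4, 3)) * 3
        mirrored = pts.copy()
        mirrored[:, 2] *= -1
        assert qs.dihedral(*mirrored) == pytest.approx(-qs.dihedral(*pts), abs=1e-9)
        assert qs.angle(*pts[:3]) == pytest.approx(qs.angle(*mirrored[:3]), abs=1e-9)

    def test_internal_coordinate_placement_roundtrip(self):
        rng = np.random.default_rng(11)
        b, c, d = rng.normal(size=(3, 3)) * 5
        a = place_by_internal_coordinates(b, c, d, 4.0, 105.0, 25.0)
        assert np.linalg.norm(a - b) == pytest.approx(4.0)
        assert qs.angle(a, b, c) == pytest.approx(105.0, abs=1e-9)
        assert qs.dihedral(a, b, c, d) == pytest.approx(25.0, abs=1e-9)


class TestOrgGeometry:
    def test_template_starts_mid_range(self, template):
        geom = qs.org_geometry(template.ensemble, template.mapping, "Q1", FULL)
        assert geom.avg_structure_angle == pytest.approx(105.0, abs=1e-6)
        assert geom.avg_structure_dihedral == pytest.approx(25.0, abs=1e-6)

    def test_ranges(self, template):
        truth = qs.PlantedTruth(contacts=[], n_frames=30, bend_deg=0.0, corr_pair=None)
        ens, _ = qs.generate(template, truth, seed=15)
        for quarter in ("Q1", "Q2"):
            geom = qs.org_geometry(ens, template.mapping, quarter, FULL)
            assert ((geom.angles >= 0) & (geom.angles <= 180)).all()
            assert ((geom.dihedrals > -180) & (geom.dihedrals <= 180)).all()

    def test_rigid_motion_invariance(self, template):
        truth = qs.PlantedTruth(contacts=[], n_frames=10, bend_deg=0.0, corr_pair=None)
        ens, _ = qs.generate(template, truth, seed=16)
        rng = np.random.default_rng(12)
        rot, trans = random_rigid(rng)
        moved = qs.Ensemble(
            topology=ens.topology, coords=apply_rigid(ens.coords, rot, trans)
        )
        a = qs.org_geometry(ens, template.mapping, "Q1", FULL)
        b = qs.org_geometry(moved, template.mapping, "Q1", FULL)
        np.testing.assert_allclose(a.angles, b.angles, atol=1e-8)
        np.testing.assert_allclose(a.dihedrals, b.dihedrals, atol=1e-8)
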