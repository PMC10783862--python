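import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bbvae.ensemble import BackboneConformation
from bbvae.geometry import (
    DegenerateGeometryError,
    backbone_dihedrals,
    ca_distance_map,
    dihedral,
    kabsch_rmsd,
    local_frame,
    project_to_frame,
    radius_of_gyration,
    residue_frames,
    unproject_from_frame,
)
from bbvae.synthetic import nerf_build

from conftest import random_rigid_transform


def _random_conf(rng, L=5):
    d = {
        "phi": rng.uniform(-170, 170, L - 1),
        "psi": rng.uniform(-170, 170, L - 1),
        "omega": rng.normal(180, 5, L - 1),
    }
    return nerf_build(d, L=L)


class TestLocalFrame:
    def test_hand_worked_example(self):
        # a=(0,0,0), b=(1,0,0), c=(1,1,0): AB=(1,0,0), BC=(0,1,0)
        f = local_frame((0, 0, 0), (1, 0, 0), (1, 1, 0))
        np.testing.assert_allclose(f.origin, [1, 0, 0])
        np.testing.assert_allclose(f.axes[2], [0, 0, 1], atol=1e-12)  # AB x BC
        np.testing.assert_allclose(f.axes[0], [0, 1, 0], atol=1e-12)  # along BC
        np.testing.assert_allclose(f.axes[1], [-1, 0, 0], atol=1e-12)  # z x x

    def test_orthonormal_right_handed_on_random_triples(self, rng):
        for _ in range(200):
            pts = rng.uniform(-10, 10, size=(3, 3))
            try:
                f = local_frame(*pts)
            except DegenerateGeometryError:
                continue
            np.testing.assert_allclose(f.axes @ f.axes.T, np.eye(3), atol=1e-8)
            assert np.linalg.det(f.axes) == pytest.approx(1.0, abs=1e-8)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            local_frame((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_project_roundtrip_and_origin(self, rng):
        f = local_frame((0, 0, 0), (1, 0, 0), (1, 1, 0))
        np.testing.assert_allclose(project_to_frame(f, f.origin), np.zeros(3), atol=1e-12)
        for _ in range(20):
            p = rng.uniform(-5, 5, 3)
            np.testing.assert_allclose(
                unproject_from_frame(f, project_to_frame(f, p)), p, atol=1e-10
            )

    def test_projection_matches_matrix_arithmetic(self):
        f = local_frame((0, 0, 0), (1, 0, 0), (1, 1, 0))
        p = np.array([2.0, 0.0, 0.0])
        expected = f.axes @ (p - np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(project_to_frame(f, p), expected, atol=1e-12)

    def test_residue_frames_equivariant_under_rigid_motion(self, rng):
        conf = _random_conf(rng)
        frames = residue_frames(conf)
        assert len(frames) == conf.n_residues
        R, t = random_rigid_transform(rng)
        moved = residue_frames(conf.transformed(R, t))
        for f0, f1 in zip(frames, moved):
            np.testing.assert_allclose(f1.origin, R @ f0.origin + t, atol=1e-8)
            np.testing.assert_allclose(f1.axes, f0.axes @ R.T, atol=1e-8)


class TestDihedral:
    def test_planar_trans_and_cis(self):
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)) == pytest.approx(180.0)
        assert dihedral((0, 1, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(0.0)

    def test_matches_independent_atan2_oracle(self, rng):
        def oracle(p1, p2, p3, p4):
            # independent formulation: project the outer bonds onto the plane
            # normal to the central bond and measure the angle between them
            b0 = p1 - p2
            b1 = (p3 - p2) / np.linalg.norm(p3 - p2)
            b2 = p4 - p3
            v = b0 - np.dot(b0, b1) * b1
            w = b2 - np.dot(b2, b1) * b1
            x = np.dot(v, w)
            y = np.dot(np.cross(b1, v), w)
            return np.degrees(np.arctan2(y, x))

        for _ in range(300):
            pts = rng.uniform(-5, 5, size=(4, 3))
            try:
                ours = dihedral(*pts)
            except DegenerateGeometryError:
                continue
            assert ours == pytest.approx(oracle(*pts), abs=1e-8)

    def test_rigid_invariance_and_reflection_sign_flip(self, rng):
        pts = rng.uniform(-5, 5, size=(4, 3))
        ref = dihedral(*pts)
        R, t = random_rigid_transform(rng)
        moved = [R @ p + t for p in pts]
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-8)
        mirrored = [p * np.array([1, 1, -1]) for p in pts]
        assert dihedral(*mirrored) == pytest.approx(-ref, abs=1e-8)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBackboneDihedrals:
    def test_counts(self, rng):
        conf = _random_conf(rng, L=6)
        tables = backbone_dihedrals(conf)
        assert {len(tables[k]) for k in ("phi", "psi", "omega")} == {5}

    def test_minimal_chain_counts(self, rng):
        conf = _random_conf(rng, L=2)
        tables = backbone_dihedrals(conf)
        assert all(len(tables[k]) == 1 for k in ("phi", "psi", "omega"))

    def test_helix_build_recovers_basin_angles(self):
        conf = nerf_build({"phi": [-63.0] * 7, "psi": [-43.0] * 7, "omega": [180.0] * 7}, L=8)
        tables = backbone_dihedrals(conf)
        np.testing.assert_allclose(tables["phi"], -63.0, atol=1e-6)
        np.testing.assert_allclose(tables["psi"], -43.0, atol=1e-6)
        np.testing.assert_allclose(np.abs(tables["omega"]), 180.0, atol=1e-6)


class TestKabschRmsd:
    def test_identity_and_rigid_invariance(self, rng):
        x = rng.uniform(-10, 10, size=(12, 3))
        assert kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-12)
        R, t = random_rigid_transform(rng)
        assert kabsch_rmsd(x, x @ R.T + t) == pytest.approx(0.0, abs=1e-8)

    def test_matches_rotation_grid_oracle_on_4_point_toys(self, rng):
        from scipy.optimize import minimize

        def oracle(x, y, n=18):
            # coarse search over Euler angles, then local refinement
            xc = x - x.mean(0)
            yc = y - y.mean(0)

            def cost(angles):
                R = Rotation.from_euler("zyz", angles).as_matrix()
                return np.sqrt(((xc - yc @ R.T) ** 2).sum() / len(x))

            grid = np.linspace(0, 2 * np.pi, n, endpoint=False)
            tilt = np.linspace(0, np.pi, n)
            best = min(
                ((a, b, c) for a in grid for b in tilt for c in grid),
                key=cost,
            )
            res = minimize(cost, best, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            return res.fun

        for _ in range(3):
            x = rng.uniform(-3, 3, size=(4, 3))
            y = rng.uniform(-3, 3, size=(4, 3))
            ours = kabsch_rmsd(x, y)
            ref = oracle(x, y)
            # the search can only overestimate the optimum
            assert ours <= ref + 1e-10
            assert abs(ours - ref) < 1e-4

    def test_pseudo_metric_properties(self, rng):
        pts = [rng.uniform(-5, 5, size=(8, 3)) for _ in range(3)]
        for x, y in [(pts[0], pts[1]), (pts[1], pts[2])]:
            assert kabsch_rmsd(x, y) == pytest.approx(kabsch_rmsd(y, x), abs=1e-8)
        d01 = kabsch_rmsd(pts[0], pts[1])
        d12 = kabsch_rmsd(pts[1], pts[2])
        d02 = kabsch_rmsd(pts[0], pts[2])
        assert d02 <= d01 + d12 + 1e-8

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestScalarDescriptors:
    def test_rg_closed_forms(self):
        assert radius_of_gyration(np.zeros((5, 3))) == 0.0
        two = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(two) == pytest.approx(1.5)

    def test_rg_matches_direct_formula(self, rng):
        conf = _random_conf(rng)
        atoms = conf.atoms()
        direct = np.sqrt(np.mean(np.sum((atoms - atoms.mean(0)) ** 2, axis=1)))
        assert radius_of_gyration(conf) == pytest.approx(direct, abs=1e-10)

    def test_distance_map_symmetric_and_345(self):
        coords = np.zeros((3, 3, 3))
        coords[:, 1] = [[0, 0, 0], [3, 0, 0], [3, 4, 0]]
        coords[:, 0] = coords[:, 1] + [0.5, 1.0, 0.0]
        coords[:, 2] = coords[:, 1] + [0.0, -1.0, 0.5]
        conf = BackboneConformation("AAA", coords)
        dm = ca_distance_map(conf)
        np.testing.assert_allclose(dm, dm.T)
        np.testing.assert_allclose(np.diag(dm), 0)
        assert sorted([dm[0, 1], dm[1, 2], dm[0, 2]]) == pytest.approx([3, 4, 5])

    def test_distance_map_rigid_invariance(self, rng):
        conf = _random_conf(rng)
        R, t = random_rigid_transform(rng)
        np.testing.assert_allclose(
            ca_distance_map(conf), ca_distance_map(conf.transformed(R, t)), atol=1e-8
        )
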