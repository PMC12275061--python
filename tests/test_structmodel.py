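import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from alascreen.site import BindingSite, ReferenceComplex
from alascreen.structmodel import (
    DockingBox,
    InsufficientAnchorError,
    PredictedStructure,
    accept_structure,
    make_docking_box,
    read_predicted_structure,
    site_rmsd,
    superpose_on_site,
    trim_low_plddt,
    write_predicted_structure,
)


def structure_from(coords, plddt=None, positions=None):
    coords = np.asarray(coords, float)
    positions = positions or list(range(1, len(coords) + 1))
    residues = [
        (pos, "ALA", {"CA": c}) for pos, c in zip(positions, coords)
    ]
    p = np.full(len(coords), 90.0) if plddt is None else np.asarray(plddt, float)
    return PredictedStructure(residues, p, provenance="toy")


def site_over(positions):
    return BindingSite(
        residues_pdb=[("A", p) for p in positions],
        cutoff=8.0,
        residues_query=list(positions),
    )


class TestPlddtFilters:
    def test_trim_boundary_strictly_below_50(self):
        s = structure_from(np.zeros((2, 3)), plddt=[49.9, 50.0])
        out = trim_low_plddt(s)
        assert [p for p, _, _ in out.residues] == [2]

    def test_trim_keeps_high_confidence_untouched(self):
        s = structure_from(np.zeros((4, 3)), plddt=[100.0] * 4)
        assert len(trim_low_plddt(s)) == 4

    def test_trim_elementwise(self):
        s = structure_from(np.zeros((3, 3)), plddt=[60, 40, 55])
        assert [p for p, _, _ in trim_low_plddt(s).residues] == [1, 3]

    @pytest.mark.parametrize(
        "plddt,expected",
        [([49.0, 49.0], False), ([50.0, 50.0], True), ([80, 20, 50], True)],
    )
    def test_accept_uses_pre_trim_mean(self, plddt, expected):
        s = structure_from(np.zeros((len(plddt), 3)), plddt=plddt)
        assert accept_structure(s) is expected

    def test_empty_structure_rejected(self):
        s = PredictedStructure([], np.array([]))
        assert accept_structure(s) is False


class TestSuperposition:
    def test_identity_gives_zero_rmsd(self, rng):
        coords = rng.normal(size=(6, 3))
        s = structure_from(coords)
        moved, rmsd = superpose_on_site(s, structure_from(coords), site_over(range(1, 7)))
        assert rmsd < 1e-10

    def test_recovers_known_rigid_transform(self, rng):
        coords = rng.normal(scale=5, size=(8, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved_coords = coords @ R.T + np.array([5.0, 0.0, 0.0])
        s = structure_from(moved_coords)
        ref = structure_from(coords)
        fitted, rmsd = superpose_on_site(s, ref, site_over(range(1, 9)))
        assert rmsd <= 1e-8
        fit_ca = np.array([fitted.ca_coordinates()[i] for i in range(1, 9)])
        assert np.allclose(fit_ca, coords, atol=1e-8)

    def test_matches_quaternion_grid_search_oracle(self, rng):
        """Brute-force search over rotations bounds the minimal RMSD from above."""
        x = rng.normal(size=(4, 3))
        y = x + rng.normal(scale=0.3, size=(4, 3))
        _, rmsd = superpose_on_site(
            structure_from(x), structure_from(y), site_over(range(1, 5))
        )
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        best = np.inf
        qrng = np.random.default_rng(0)
        for q in qrng.normal(size=(20000, 4)):
            R = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
            best = min(best, np.sqrt(np.mean(np.sum((xc @ R.T - yc) ** 2, axis=1))))
        assert rmsd <= best + 1e-9
        assert rmsd >= best - 0.05  # coarse grid overshoots only slightly

    def test_pose_invariance_of_fitted_rmsd(self, rng):
        coords = rng.normal(scale=4, size=(10, 3))
        target = structure_from(coords + rng.normal(scale=0.5, size=(10, 3)))
        site = site_over(range(1, 11))
        _, base = superpose_on_site(structure_from(coords), target, site)
        for seed in range(5):
            R = Rotation.random(random_state=seed).as_matrix()
            t = np.random.default_rng(seed).normal(scale=20, size=3)
            _, moved = superpose_on_site(structure_from(coords @ R.T + t), target, site)
            assert abs(moved - base) < 1e-6

    def test_insufficient_anchors_raise(self, rng):
        coords = rng.normal(size=(2, 3))
        with pytest.raises(InsufficientAnchorError):
            superpose_on_site(
                structure_from(coords), structure_from(coords), site_over([1, 2])
            )


class TestDockingBox:
    def test_default_box_is_20A_cube_on_ligand_centroid(self):
        cx = ReferenceComplex(
            [("A", 1, "GLY", "CA", np.array([50.0, 0, 0]))],
            [("C1", np.array([0.0, 0, 0])), ("C2", np.array([2.0, 0, 0]))],
            "LIG",
        )
        box = make_docking_box(cx)
        assert box.size == (20.0, 20.0, 20.0)
        assert np.allclose(box.center, [1.0, 0.0, 0.0])

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            DockingBox(center=np.zeros(3), size=(0.0, 20.0, 20.0))


class TestSiteRMSD:
    def test_self_rmsd_is_zero(self, rng):
        s = structure_from(rng.normal(size=(5, 3)))
        assert site_rmsd(s, s, site_over(range(1, 6))) < 1e-10

    def test_single_displacement_bounded_by_closed_form(self, rng):
        n = 12
        coords = rng.normal(scale=5, size=(n, 3))
        moved = coords.copy()
        moved[0] += np.array([1.0, 0.0, 0.0])
        site = site_over(range(1, n + 1))
        rmsd = site_rmsd(structure_from(moved), structure_from(coords), site)
        # re-fitting can only reduce the fixed-superposition value sqrt(1/n)
        assert 0 < rmsd <= np.sqrt(1.0 / n) + 1e-12

    def test_symmetry_on_random_pairs(self, rng):
        site = site_over(range(1, 8))
        for _ in range(20):
            a = structure_from(rng.normal(scale=3, size=(7, 3)))
            b = structure_from(rng.normal(scale=3, size=(7, 3)))
            assert site_rmsd(a, b, site) == pytest.approx(site_rmsd(b, a, site), abs=1e-9)


class TestPDBModelIO:
    def test_round_trip_preserves_plddt_and_coords(self, tmp_path, rng):
        s = structure_from(rng.normal(scale=5, size=(6, 3)), plddt=[88.5, 72.25, 49.9, 50.0, 91.0, 60.5])
        path = tmp_path / "model.pdb"
        write_predicted_structure(s, path)
        back = read_predicted_structure(path)
        assert np.allclose(back.plddt, s.plddt, atol=0.005)
        for (p1, _, a1), (p2, _, a2) in zip(s.residues, back.residues):
            assert p1 == p2
            assert np.allclose(a1["CA"], a2["CA"], atol=1e-3)
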