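"""Tests for SASA/BSA, shape complementarity, hydrogen bonds, scoring,
and pose sampling."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import thermobind as tb
from thermobind.structure import (
    DEFAULT_RADIUS,
    compute_asa,
    dot_surface,
    fibonacci_sphere,
    rmsd,
    sc_from_dots,
)


def two_sphere_asa(r1, r2, d, probe=1.4):
    """Analytic exposed area of sphere 1 in a two-sphere system."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * math.pi * R1 ** 2
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    return 4 * math.pi * R1 ** 2 - 2 * math.pi * R1 * (R1 - x1)


def plate_dots(n=21, extent=5.0, z=0.0, normal=+1.0):
    xs, ys = np.meshgrid(np.linspace(-extent, extent, n),
                         np.linspace(-extent, extent, n))
    pts = np.column_stack([xs.ravel(), ys.ravel(),
                           np.full(xs.size, float(z))])
    normals = np.tile([0.0, 0.0, float(normal)], (len(pts), 1))
    return pts, normals


class TestPdbIO:
    def test_single_atom_file(self, tmp_path):
        st = tb.Structure(coords=[[1.0, 2.0, 3.0]], radii=[1.52],
                          elements=["O"])
        path = tmp_path / "one.pdb"
        tb.write_pdb(st, path)
        back = tb.read_pdb(path)
        assert back.n_atoms == 1
        assert back.elements == ["O"]
        assert back.radii[0] == pytest.approx(1.52)

    def test_two_chain_complex_separable(self, tmp_path, sparse_complex):
        rec, lig, _ = sparse_complex
        path = tmp_path / "complex.pdb"
        tb.write_pdb(tb.merge(rec, lig), path)
        back = tb.read_pdb(path)
        chains = np.array(back.chains)
        assert set(chains) == {"A", "B"}
        assert int(np.sum(chains == "A")) == rec.n_atoms
        assert int(np.sum(chains == "B")) == lig.n_atoms

    def test_roundtrip_preserves_coordinates_to_pdb_precision(
            self, tmp_path, sparse_complex):
        rec, lig, _ = sparse_complex
        comp = tb.merge(rec, lig)
        path = tmp_path / "rt.pdb"
        tb.write_pdb(comp, path)
        back = tb.read_pdb(path)
        assert np.abs(back.coords - comp.coords).max() < 1e-3 + 1e-9

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "bad.pdb"
        path.write_text("not a structure at all\n")
        with pytest.raises(ValueError):
            tb.read_pdb(path)

    def test_unknown_element_gets_default_radius(self, tmp_path):
        path = tmp_path / "exotic.pdb"
        path.write_text(
            "HETATM    1 XX   UNK A   1       0.000   0.000   0.000"
            "  1.00  0.00          XX\n"
        )
        with pytest.warns(UserWarning, match="unknown element"):
            st = tb.read_pdb(path)
        assert st.radii[0] == pytest.approx(DEFAULT_RADIUS)


class TestSasa:
    def test_lone_atom_closed_form(self):
        st = tb.Structure(coords=[[0, 0, 0]], radii=[1.9], elements=["C"])
        asa = compute_asa(st, probe=1.4, n_points=960)
        assert asa[0] == pytest.approx(4 * math.pi * 3.3 ** 2, rel=0.005)

    def test_enclosed_atom_has_zero_area(self):
        corners = np.array(
            [[sx, sy, sz] for sx in (-2, 2) for sy in (-2, 2)
             for sz in (-2, 2)], dtype=float)
        coords = np.vstack([[0.0, 0.0, 0.0], corners])
        radii = np.concatenate([[1.0], np.full(8, 3.0)])
        st = tb.Structure(coords=coords, radii=radii, elements=["C"] * 9)
        assert compute_asa(st)[0] == 0.0

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5])
    def test_two_spheres_match_analytic_caps(self, d):
        st = tb.Structure(coords=[[0, 0, 0], [d, 0, 0]],
                          radii=[1.7, 1.7], elements=["C", "C"])
        asa = compute_asa(st, n_points=960)
        expected = two_sphere_asa(1.7, 1.7, d)
        assert asa[0] == pytest.approx(expected, rel=0.02)
        assert asa[1] == pytest.approx(expected, rel=0.02)

    def test_point_count_convergence(self):
        rng = np.random.default_rng(2)
        st = tb.Structure(coords=rng.uniform(-6, 6, (50, 3)),
                          radii=np.full(50, 1.7), elements=["C"] * 50)
        a960 = tb.total_asa(st, n_points=960)
        a1920 = tb.total_asa(st, n_points=1920)
        assert abs(a960 - a1920) / a1920 < 0.01

    def test_cross_check_against_biopython(self):
        """Independent Shrake-Rupley implementation agrees on a random
        20-atom cluster."""
        from Bio.PDB.SASA import ShrakeRupley
        from Bio.PDB.StructureBuilder import StructureBuilder

        rng = np.random.default_rng(0)
        coords = rng.uniform(-5, 5, (20, 3))
        mine = tb.Structure(coords=coords, radii=np.full(20, 1.7),
                            elements=["C"] * 20)
        sb = StructureBuilder()
        sb.init_structure("x")
        sb.init_model(0)
        sb.init_chain("A")
        sb.init_seg(" ")
        for i, c in enumerate(coords):
            sb.init_residue("LIG", " ", i + 1, " ")
            sb.init_atom("C", c, 0.0, 1.0, " ", "C", i + 1, element="C")
        ref = sb.get_structure()
        sr = ShrakeRupley(probe_radius=1.4, n_points=960,
                          radii_dict={"C": 1.7})
        sr.compute(ref, level="S")
        assert tb.total_asa(mine) == pytest.approx(ref.sasa, rel=0.01)

    def test_fibonacci_points_are_unit_vectors(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)


class TestBsa:
    def test_symmetric_in_arguments(self, sparse_complex):
        rec, lig, _ = sparse_complex
        assert tb.buried_surface_area(rec, lig) == pytest.approx(
            tb.buried_surface_area(lig, rec), rel=1e-9)

    def test_nonnegative_for_random_clusters(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = tb.Structure(coords=rng.uniform(-4, 4, (6, 3)),
                             radii=np.full(6, 1.7), elements=["C"] * 6)
            b = tb.Structure(coords=rng.uniform(-4, 4, (6, 3)),
                             radii=np.full(6, 1.7), elements=["C"] * 6)
            assert tb.buried_surface_area(a, b) >= -1e-9


class TestShapeComplementarity:
    def test_mating_plates_score_near_one(self):
        pts_a, n_a = plate_dots(z=0.0, normal=+1)
        pts_b, n_b = plate_dots(z=0.2, normal=-1)
        assert sc_from_dots(pts_a, n_a, pts_b, n_b) >= 0.95

    def test_parallel_normals_score_negative(self):
        pts_a, n_a = plate_dots(z=0.0, normal=+1)
        pts_b, n_b = plate_dots(z=0.2, normal=+1)
        assert sc_from_dots(pts_a, n_a, pts_b, n_b) <= 0.0

    def test_distant_plates_decay_to_zero(self):
        pts_a, n_a = plate_dots(z=0.0, normal=+1)
        pts_b, n_b = plate_dots(z=10.0, normal=-1)
        assert abs(sc_from_dots(pts_a, n_a, pts_b, n_b)) < 0.01

    def test_bounded_and_rigid_motion_invariant(self, dense_complex):
        rec, lig, _ = dense_complex
        sc = tb.shape_complementarity(rec, lig)
        assert -1.0 < sc <= 1.0
        rot = Rotation.from_euler("xyz", [30, -45, 60],
                                  degrees=True).as_matrix()
        shift = np.array([3.0, -2.0, 7.0])
        origin = np.zeros(3)
        rec_t = rec.transformed(rot, shift, about=origin)
        lig_t = lig.transformed(rot, shift, about=origin)
        sc_t = tb.shape_complementarity(rec_t, lig_t)
        # dot lattices are rebuilt in the global frame, so invariance is
        # approximate at finite dot density
        assert sc_t == pytest.approx(sc, abs=0.05)

    def test_no_interface_raises(self):
        a = tb.Structure(coords=[[0, 0, 0]], radii=[1.7], elements=["C"])
        dots_a, n_a = dot_surface(a)
        with pytest.raises(ValueError):
            sc_from_dots(dots_a, n_a, np.empty((0, 3)), np.empty((0, 3)))


class TestHbonds:
    def _pair(self, d, donor_h=None):
        rec = tb.Structure(coords=[[0, 0, 0]], radii=[1.55], elements=["N"],
                           is_donor=[True])
        lig_coords = [[d, 0.0, 0.0]]
        lig_elements = ["O"]
        lig_acc = [True]
        lig = tb.Structure(coords=lig_coords, radii=[1.52],
                           elements=lig_elements, is_acceptor=lig_acc)
        if donor_h is not None:
            rec = tb.Structure(
                coords=[[0, 0, 0], donor_h], radii=[1.55, 1.2],
                elements=["N", "H"], is_donor=[True, False])
        return rec, lig

    def test_short_contact_counts(self):
        rec, lig = self._pair(2.9)
        assert len(tb.detect_hbonds(rec, lig)) == 1

    def test_long_contact_does_not(self):
        rec, lig = self._pair(4.0)
        assert len(tb.detect_hbonds(rec, lig)) == 0

    def test_linear_hydrogen_accepted(self):
        rec, lig = self._pair(2.9, donor_h=[1.0, 0.0, 0.0])
        bonds = tb.detect_hbonds(rec, lig)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)

    def test_bent_hydrogen_rejected(self):
        # hydrogen pointing away: D-H...A angle ~ 0 degrees
        rec, lig = self._pair(2.9, donor_h=[-1.0, 0.0, 0.0])
        assert len(tb.detect_hbonds(rec, lig)) == 0


class TestInterfaceScore:
    def test_separated_molecules_score_zero(self):
        a = tb.Structure(coords=[[0, 0, 0]], radii=[1.7], elements=["C"],
                         charges=[1.0])
        b = tb.Structure(coords=[[50, 0, 0]], radii=[1.7], elements=["C"],
                         charges=[-1.0])
        m = tb.interface_score(a, b, include_surface_metrics=False)
        assert m.score_total == 0.0
        assert all(v == 0.0 for v in m.terms.values())

    def test_opposite_charges_attract(self):
        a = tb.Structure(coords=[[0, 0, 0]], radii=[1.0], elements=["C"],
                         charges=[1.0])
        b = tb.Structure(coords=[[3.0, 0, 0]], radii=[1.0], elements=["C"],
                         charges=[-1.0])
        m = tb.interface_score(a, b, include_surface_metrics=False)
        assert m.terms["elec"] < 0
        assert m.terms["elec"] == pytest.approx(332 * -1 / (4 * 9.0))

    def test_repulsion_grows_as_atoms_interpenetrate(self):
        """Brute-force scan below contact distance: the capped repulsive
        term rises strictly as separation shrinks."""
        reps = []
        for d in np.linspace(3.3, 2.6, 8):
            a = tb.Structure(coords=[[0, 0, 0]], radii=[1.7],
                             elements=["C"])
            b = tb.Structure(coords=[[d, 0, 0]], radii=[1.7],
                             elements=["C"])
            m = tb.interface_score(a, b, include_surface_metrics=False)
            reps.append(m.terms["lj_repulsive"])
        assert all(x < y for x, y in zip(reps, reps[1:]))

    def test_score_total_is_sum_of_terms(self, sparse_complex):
        rec, lig, _ = sparse_complex
        m = tb.interface_score(rec, lig, include_surface_metrics=False)
        assert m.score_total == pytest.approx(sum(m.terms.values()))

    def test_rigid_motion_invariance(self, sparse_complex):
        rec, lig, _ = sparse_complex
        m0 = tb.interface_score(rec, lig, include_surface_metrics=False)
        rot = Rotation.from_euler("zyx", [17, 122, -49],
                                  degrees=True).as_matrix()
        shift = np.array([-4.0, 9.0, 2.0])
        origin = np.zeros(3)
        m1 = tb.interface_score(rec.transformed(rot, shift, about=origin),
                                lig.transformed(rot, shift, about=origin),
                                include_surface_metrics=False)
        assert m1.score_total == pytest.approx(m0.score_total, rel=1e-9)

    def test_surface_metrics_filled_on_request(self, sparse_complex):
        rec, lig, truth = sparse_complex
        m = tb.interface_score(rec, lig, include_surface_metrics=True)
        assert m.bsa == pytest.approx(truth.bsa_analytic, rel=0.05)
        assert m.sc is not None


class TestPoseSampling:
    def test_single_pose_request(self, sparse_complex):
        rec, lig, truth = sparse_complex
        poses = tb.sample_poses(rec, lig, truth.site_center, n_poses=1,
                                max_translation=1.0, seed=0)
        assert len(poses) <= 1

    def test_same_seed_identical_ranking(self, sparse_complex):
        rec, lig, truth = sparse_complex
        a = tb.sample_poses(rec, lig, truth.site_center, n_poses=100, seed=5)
        b = tb.sample_poses(rec, lig, truth.site_center, n_poses=100, seed=5)
        assert len(a) == len(b)
        assert np.array_equal(a.best.ligand.coords, b.best.ligand.coords)
        assert [p.metrics.score_total for p in a.poses] == \
            [p.metrics.score_total for p in b.poses]

    def test_all_clashing_raises(self, sparse_complex):
        rec, lig, _ = sparse_complex
        # centre the ligand on a pocket atom: every draw interpenetrates
        with pytest.raises(RuntimeError):
            tb.sample_poses(rec, lig, rec.coords[0], n_poses=20,
                            max_translation=0.1, seed=1)

    def test_near_native_recovery_across_seeds(self, sparse_complex):
        """The best-scoring pose lands within 2 A RMSD of the generating
        pose in at least 80% of 20 seeded runs."""
        rec, lig, truth = sparse_complex
        hits = 0
        for seed in range(20):
            poses = tb.sample_poses(rec, lig, truth.site_center,
                                    n_poses=2000, seed=seed)
            r = rmsd(poses.best.ligand.coords, truth.true_ligand_coords)
            hits += r <= 2.0
        assert hits >= 16


class TestTopK:
    def test_k_one_is_best_score(self, sparse_complex):
        rec, lig, truth = sparse_complex
        poses = tb.sample_poses(rec, lig, truth.site_center, n_poses=50,
                                seed=2)
        assert tb.top_k_mean(poses, 1) == poses.best.metrics.score_total

    def test_arithmetic_on_known_scores(self):
        scores = [-5.0, -4.0, -3.0, -2.0, -1.0]
        fake = tb.PoseSet(
            poses=[
                tb.structure.Pose(
                    rotation=np.eye(3), translation=np.zeros(3),
                    metrics=tb.InterfaceMetrics(terms={}, score_total=s,
                                                n_hbonds=0),
                    ligand=None)
                for s in scores
            ],
            seed=None, n_requested=5)
        assert tb.top_k_mean(fake, 2) == pytest.approx(-4.5)
        with pytest.raises(ValueError):
            tb.top_k_mean(fake, 6)
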