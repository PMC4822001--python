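"""Featurization: contact maps, distances, torsions, subset RMSD, unfolding rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conformakin import features as ft
from conformakin.synthetic import compact_reference, open_reference, toy_polymer
from conformakin.trajectory import Topology, Trajectory


def _single_atom_chain(positions, elements=None):
    """One single-atom residue per position; residues numbered from 1."""
    n = len(positions)
    top = Topology(np.array(["CA"] * n, dtype=object),
                   np.array(elements or ["C"] * n, dtype=object),
                   np.arange(1, n + 1),
                   np.array(["GLY"] * n, dtype=object))
    return Trajectory(np.asarray(positions, dtype=float)[None], top)


class TestContactFeatures:
    def test_three_four_five_triangle(self):
        traj = _single_atom_chain([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 4, 0]])
        feats = ft.contact_features(traj, min_separation=3)
        assert feats.pair_labels == [(1, 4)]
        assert feats.values[0, 0] == pytest.approx(5.0)

    def test_separation_filter_combinatorics(self):
        traj = _single_atom_chain(np.zeros((5, 3)) + np.arange(5)[:, None])
        feats = ft.contact_features(traj, min_separation=3)
        assert feats.pair_labels == [(1, 4), (1, 5), (2, 5)]

    def test_matches_brute_force_on_polymer_references(self):
        for ref in (open_reference(), compact_reference()):
            traj = _single_atom_chain(ref)
            feats = ft.contact_features(traj, min_separation=3)
            for col, (i, j) in enumerate(feats.pair_labels):
                # single-atom residues: min distance is the bead distance
                expect = np.linalg.norm(ref[i - 1] - ref[j - 1])
                assert feats.values[0, col] == pytest.approx(expect)

    def test_hydrogens_excluded_from_minimum(self):
        # residue 1: heavy atom at origin plus a hydrogen right next to residue 4
        top = Topology(np.array(["CA", "H", "CA", "CA", "CA"], dtype=object),
                       np.array(["C", "H", "C", "C", "C"], dtype=object),
                       np.array([1, 1, 2, 3, 4]),
                       np.array(["GLY"] * 5, dtype=object))
        xyz = np.array([[[0, 0, 0], [9, 0, 0], [1, 0, 0], [2, 0, 0], [10, 0, 0]]],
                       dtype=float)
        feats = ft.contact_features(Trajectory(xyz, top), min_separation=3)
        assert feats.pair_labels == [(1, 4)]
        assert feats.values[0, 0] == pytest.approx(10.0)

    def test_residue_without_heavy_atoms_errors(self):
        top = Topology(np.array(["CA", "H", "CA", "CA", "CA"], dtype=object),
                       np.array(["C", "H", "C", "C", "C"], dtype=object),
                       np.array([1, 2, 3, 4, 5]),
                       np.array(["GLY"] * 5, dtype=object))
        traj = Trajectory(np.zeros((1, 5, 3)), top)
        with pytest.raises(ValueError, match="residue 2"):
            ft.contact_features(traj)

    def test_atom_order_within_residue_is_irrelevant(self):
        rng = np.random.default_rng(0)
        xyz = rng.normal(size=(3, 8, 3)) * 5
        resids = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        top = Topology(np.array(["A", "B"] * 4, dtype=object),
                       np.array(["C"] * 8, dtype=object), resids,
                       np.array(["GLY"] * 8, dtype=object))
        f1 = ft.contact_features(Trajectory(xyz, top), min_separation=3)
        perm = np.array([1, 0, 3, 2, 5, 4, 7, 6])
        top2 = Topology(top.atom_names[perm], top.elements[perm], resids,
                        top.residue_names[perm])
        f2 = ft.contact_features(Trajectory(xyz[:, perm], top2), min_separation=3)
        assert np.allclose(f1.values, f2.values)


class TestPairDistance:
    def test_consistent_with_contact_features(self, polymer_traj):
        traj, _ = polymer_traj
        feats = ft.contact_features(traj.slice_frames(slice(0, 50)), min_separation=3)
        col = feats.pair_labels.index((1, 12))
        d = ft.pair_distance(traj.slice_frames(slice(0, 50)), (1, 12), mode="min_heavy")
        assert np.allclose(d, feats.values[:, col], atol=1e-9)

    def test_c_alpha_distance(self):
        traj = _single_atom_chain([[0, 0, 0], [0, 0, 7.5]])
        assert ft.pair_distance(traj, (1, 2), mode="c_alpha")[0] == pytest.approx(7.5)

    def test_missing_ca_errors(self):
        top = Topology(np.array(["CB"], dtype=object), np.array(["C"], dtype=object),
                       np.array([1]), np.array(["ALA"], dtype=object))
        traj = Trajectory(np.zeros((1, 1, 3)), top)
        with pytest.raises(KeyError):
            ft.pair_distance(traj, (1, 1), mode="c_alpha")


class TestPartialUnfoldingClassifier:
    @pytest.mark.parametrize("d1,d2,expected", [
        (6.0, 9.0, False),      # both well below cutoffs
        (11.5, 9.0, True),      # helix-G distance above its 11 Å cutoff
        (9.0, 15.5, True),      # site-2 distance above its 15 Å cutoff
        (10.9, 15.1, True),     # OR rule: one deformation suffices
        (11.0, 15.0, False),    # strictly-greater cutoffs
    ])
    def test_or_rule(self, d1, d2, expected):
        assert ft.classify_partial_unfolding(d1, d2) is expected

    def test_and_rule_differs_on_single_deformation(self):
        assert ft.classify_partial_unfolding(10.9, 15.1, combine="and") is False
        assert ft.classify_partial_unfolding(11.1, 15.1, combine="and") is True

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ft.classify_partial_unfolding(-1.0, 5.0)

    @given(d1=st.floats(0, 30), d2=st.floats(0, 30),
           inc1=st.floats(0, 10), inc2=st.floats(0, 10))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_both_distances(self, d1, d2, inc1, inc2):
        before = ft.classify_partial_unfolding(d1, d2)
        after = ft.classify_partial_unfolding(d1 + inc1, d2 + inc2)
        assert after or not before  # increasing never flips True -> False


def _dihedral_gram_schmidt(p0, p1, p2, p3):
    """Independent oracle: project bond vectors out of the axis, signed angle."""
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    v = (p0 - p1) - np.dot(p0 - p1, b1) * b1
    w = (p3 - p2) - np.dot(p3 - p2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.arctan2(y, x)


class TestTorsions:
    def test_cis_is_zero(self):
        p = np.array([[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        assert ft.dihedral(*p) == pytest.approx(0.0, abs=1e-12)

    def test_trans_is_pi(self):
        p = np.array([[-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]], dtype=float)
        assert abs(ft.dihedral(*p)) == pytest.approx(np.pi, abs=1e-12)

    @given(arrays(float, (4, 3), elements=st.floats(-5, 5)))
    @settings(max_examples=200, deadline=None)
    def test_matches_gram_schmidt_oracle(self, pts):
        # reject degenerate (near-collinear) quadruples
        b0, b1, b2 = np.diff(pts, axis=0)
        if (np.linalg.norm(b1) < 1e-3
                or np.linalg.norm(np.cross(b0, b1)) < 1e-3
                or np.linalg.norm(np.cross(b1, b2)) < 1e-3):
            return
        a = ft.dihedral(*pts)
        b = _dihedral_gram_schmidt(*pts)
        # compare on the circle: +pi and -pi are the same dihedral
        assert abs(np.angle(np.exp(1j * (a - b)))) < 1e-10

    def test_torsion_series_on_trajectory(self):
        xyz = np.array([
            [[1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]],
            [[-1, 1, 0], [0, 1, 0], [0, 0, 0], [1, 0, 0]],
        ], dtype=float)
        top = Topology(np.array(["C1", "C2", "C3", "C4"], dtype=object),
                       np.array(["C"] * 4, dtype=object), np.array([1, 1, 1, 1]),
                       np.array(["XXX"] * 4, dtype=object))
        out = ft.torsion_angles(Trajectory(xyz, top), [(0, 1, 2, 3)])
        assert out[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert abs(out[1, 0]) == pytest.approx(np.pi, abs=1e-12)

    def test_phi_psi_indices_on_tripeptide(self):
        names = ["N", "CA", "C"] * 3
        top = Topology(np.array(names, dtype=object),
                       np.array(["N", "C", "C"] * 3, dtype=object),
                       np.repeat([1, 2, 3], 3),
                       np.array(["ALA"] * 9, dtype=object))
        traj = Trajectory(np.random.default_rng(0).normal(size=(1, 9, 3)), top)
        labels, quads = ft.phi_psi_indices(traj)
        assert ("phi", 2) in labels and ("psi", 2) in labels
        assert ("phi", 1) not in labels  # no preceding carbonyl
        assert ("psi", 3) not in labels  # no following amide


class TestSubsetRMSD:
    def test_identical_frames_zero(self):
        a = np.random.default_rng(1).normal(size=(6, 3))
        assert ft.subset_rmsd(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        a = np.random.default_rng(2).normal(size=(8, 3)) * 4
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        b = a @ R.T + np.array([5.0, -2.0, 1.0])
        assert ft.subset_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 7, 3))
        assert ft.subset_rmsd(a, b) == pytest.approx(ft.subset_rmsd(b, a), abs=1e-10)

    def test_matches_brute_force_rotation_search(self):
        # 4-point toy configurations; oracle = coarse-to-fine grid over
        # rotations (Euler angles), translations removed by centering
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 4, 3)) * 3
        got = ft.subset_rmsd(a, b)
        ac = a - a.mean(0)
        bc = b - b.mean(0)

        def rmsd_for(rot):
            return np.sqrt(((ac - bc @ rot.T) ** 2).sum() / 4)

        best, best_angles = np.inf, None
        grid = np.linspace(-np.pi, np.pi, 25)
        for ax in grid:
            for ay in np.linspace(-np.pi / 2, np.pi / 2, 13):
                for az in grid:
                    r = rmsd_for(Rotation.from_euler("zyx", [ax, ay, az]).as_matrix())
                    if r < best:
                        best, best_angles = r, (ax, ay, az)
        # local refinement around the best grid point
        from scipy.optimize import minimize

        res = minimize(lambda v: rmsd_for(Rotation.from_euler("zyx", v).as_matrix()),
                       best_angles, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12})
        assert got == pytest.approx(res.fun, abs=1e-6)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b, c = rng.normal(size=(3, 5, 3)) * 2
            dab = ft.subset_rmsd(a, b)
            dbc = ft.subset_rmsd(b, c)
            dac = ft.subset_rmsd(a, c)
            assert dac <= dab + dbc + 1e-9

    def test_mismatched_subsets_error(self):
        with pytest.raises(ValueError, match="differ"):
            ft.subset_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))
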