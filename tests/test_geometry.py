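"""Alignment and similarity kernels: Laplacian, Kabsch, TM-score, weights."""

import numpy as np
import pytest

from holoflow import geometry
from holoflow.geometry import (
    DegenerateGeometryWarning,
    graph_laplacian,
    ligand_proximity_weights,
    tm_d0,
    tm_score,
    weighted_kabsch,
)
from holoflow.structures import InvalidInputError, LigandGraph, ProteinStructure


def rotation_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestGraphLaplacian:
    @pytest.mark.parametrize(
        "elements,bonds,expected",
        [
            (["C", "C", "C"], [(0, 1), (1, 2)], [[1, -1, 0], [-1, 2, -1], [0, -1, 1]]),
            (["C"], [], [[0.0]]),
            (
                ["C", "C", "O", "O"],
                [(0, 1), (2, 3)],
                [[1, -1, 0, 0], [-1, 1, 0, 0], [0, 0, 1, -1], [0, 0, -1, 1]],
            ),
        ],
    )
    def test_examples(self, elements, bonds, expected):
        L = graph_laplacian(LigandGraph.from_bonds(elements, bonds))
        assert np.array_equal(L, np.asarray(expected, float))

    def test_empty_graph_rejected(self):
        with pytest.raises(InvalidInputError):
            LigandGraph.from_bonds([], [])

    @pytest.mark.parametrize("seed", range(5))
    def test_psd_and_zero_modes_count_fragments(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        bonds = []
        # random forest: each atom may attach to an earlier one
        for a in range(1, n):
            if rng.uniform() < 0.7:
                bonds.append((int(rng.integers(a)), a))
        g = LigandGraph.from_bonds(["C"] * n, bonds)
        L = graph_laplacian(g)
        evals = np.linalg.eigvalsh(L)
        assert evals.min() >= -1e-10
        assert int(np.sum(np.abs(evals) < 1e-8)) == g.n_fragments

    def test_bond_crossing_fragments_rejected(self):
        with pytest.raises(InvalidInputError):
            LigandGraph(("C", "C"), ((0, 1),), (0, 1))


class TestWeightedKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        res = weighted_kabsch(pts, pts)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-10)
        assert res.rmsd < 1e-10
        assert res.tm_score == 1.0

    def test_recovers_90_degree_rotation(self):
        rng = np.random.default_rng(1)
        mobile = rng.normal(size=(8, 3))
        R = rotation_z(90)
        t = np.array([1.0, -2.0, 0.5])
        reference = mobile @ R.T + t
        res = weighted_kabsch(mobile, reference)
        assert np.allclose(res.rotation, R, atol=1e-8)
        assert res.rmsd < 1e-8

    def test_weighting_prioritizes_high_weight_points(self):
        # oracle: brute-force axis-angle search over rotations for the
        # 3-point weighted objective, independent of the SVD route
        rng = np.random.default_rng(2)
        mobile = rng.normal(size=(5, 3)) * 3
        R = rotation_z(40)
        shift = np.array([0.5, 1.0, -0.3])
        reference = mobile @ R.T + shift
        reference[3:] += rng.normal(size=(2, 3)) * 2.0  # corrupt low-weight points
        w = np.array([1.0, 1.0, 1.0, 1e-6, 1e-6])

        res_w = weighted_kabsch(mobile, reference, weights=w)
        res_u = weighted_kabsch(mobile, reference)

        def resid3(res):
            return np.linalg.norm(res.apply(mobile[:3]) - reference[:3])

        assert resid3(res_w) <= resid3(res_u) + 1e-9

        # brute-force oracle over axis-angle grid confirms the weighted fit
        best = np.inf
        for ax_seed in range(200):
            axis = np.random.default_rng(ax_seed).normal(size=3)
            axis /= np.linalg.norm(axis)
            for ang in np.linspace(0, 2 * np.pi, 181):
                K = np.array(
                    [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
                )
                Rg = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
                mu_x = np.average(mobile, axis=0, weights=w)
                mu_y = np.average(reference, axis=0, weights=w)
                aligned = (mobile - mu_x) @ Rg.T + mu_y
                obj = np.sum(w[:, None] * (aligned - reference) ** 2)
                best = min(best, obj)
        mu_x = np.average(mobile, axis=0, weights=w)
        mu_y = np.average(reference, axis=0, weights=w)
        aligned = (mobile - mu_x) @ res_w.rotation.T + mu_y
        obj_svd = np.sum(w[:, None] * (aligned - reference) ** 2)
        assert obj_svd <= best + 1e-6

    def test_rmsd_invariant_to_mobile_prerotation(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(7, 3))
        reference = rng.normal(size=(7, 3))
        base = weighted_kabsch(mobile, reference).rmsd
        pre = mobile @ rotation_z(63).T + np.array([4.0, 0, -1])
        assert abs(weighted_kabsch(pre, reference).rmsd - base) < 1e-8

    def test_degenerate_collinear_warns(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.warns(DegenerateGeometryWarning):
            res = weighted_kabsch(line, line + 1.0)
        assert res.degenerate

    def test_too_few_positive_weights(self):
        pts = np.eye(3) * 2.0
        with pytest.raises(InvalidInputError):
            weighted_kabsch(pts, pts, weights=np.array([1.0, 1.0, 0.0]))


class TestTMScore:
    def test_identical_chains_exactly_one(self):
        pts = np.random.default_rng(0).normal(size=(50, 3)) * 10
        assert tm_score(pts, pts) == 1.0

    def test_large_deviation_small_score(self):
        # direct evaluation of the published sum: uniform deviations of
        # 10*d0 give 1/(1+100) per residue
        n = 60
        pts = np.random.default_rng(1).normal(size=(n, 3)) * 10
        d0 = tm_d0(n)
        shifted = pts + np.array([10 * d0, 0, 0])
        expected = (1.0 / (1.0 + 100.0))  # per-residue term
        assert np.isclose(tm_score(pts, shifted, n), expected, rtol=1e-12)
        assert tm_score(pts, shifted, n) < 0.2

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_under_deviation_scaling(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        a = rng.normal(size=(n, 3)) * 8
        dev = rng.normal(size=(n, 3))
        scores = [tm_score(a, a + s * dev, n) for s in np.linspace(0, 5, 11)]
        assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=(30, 3)), rng.normal(size=(30, 3))
        assert tm_score(a, b, 30) == pytest.approx(tm_score(b, a, 30), abs=1e-14)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            tm_score(np.zeros((5, 3)), np.zeros((6, 3)))


class TestProximityWeights:
    def _protein(self, ca):
        ca = np.asarray(ca, float)
        n = len(ca)
        return ProteinStructure(
            sequence="A" * n, ca_coords=ca, heavy_coords=ca, atom_to_residue=np.arange(n)
        )

    def test_equidistant_residues_uniform(self):
        # residues on a circle around a single-atom ligand at the origin
        ang = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ca = np.stack([5 * np.cos(ang), 5 * np.sin(ang), np.zeros(8)], axis=1)
        w = ligand_proximity_weights(self._protein(ca), np.zeros((1, 3)))
        assert np.allclose(w, 1 / 8)

    def test_contact_residue_gets_max_weight(self):
        ca = np.array([[0.0, 0, 0], [5, 0, 0], [9, 0, 0]])
        w = ligand_proximity_weights(self._protein(ca), np.zeros((1, 3)))
        assert np.argmax(w) == 0

    def test_exponential_kernel_ratio(self):
        ca = np.array([[0.0, 0, 0], [4.0, 0, 0], [100.0, 0, 0]])
        w = ligand_proximity_weights(self._protein(ca), np.zeros((1, 3)), scale=4.0)
        assert w[0] / w[1] == pytest.approx(np.e, rel=1e-12)

    def test_normalized_and_monotone(self):
        ca = np.array([[1.0, 0, 0], [2, 0, 0], [4, 0, 0], [8, 0, 0]])
        w = ligand_proximity_weights(self._protein(ca), np.zeros((1, 3)))
        assert w.sum() == pytest.approx(1.0)
        assert all(a >= b for a, b in zip(w, w[1:]))


def test_buried_centroid_inside_cloud():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(200, 3)) * 5
    c = geometry.buried_centroid(pts)
    assert np.linalg.norm(c - pts.mean(axis=0)) < np.sqrt((pts.var(axis=0)).sum())
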