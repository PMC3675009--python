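"""Superposition lRMSD (with brute-force rotation oracle), pharmacophore
dissimilarity and subset enumeration."""

from __future__ import annotations

from math import comb

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ccorps.distance import (
    PharmMatrix,
    Substructure,
    column_subsets,
    default_pharm_matrix,
    distance_matrix,
    enumerate_subsets,
    pairwise_lrmsd,
    pharm_dissimilarity,
    substructure_distance,
    superpose_lrmsd,
)
from ccorps.io_model import ResidueSite, STANDARD_AA


def brute_force_lrmsd(a: np.ndarray, b: np.ndarray, n_starts: int = 512) -> float:
    """Independent oracle: rotation sampling refined by local search.

    Centers both point sets, evaluates the RMSD over a seeded random
    rotation sample, then polishes the best candidates with Nelder-Mead on
    the rotation vector.  No Kabsch/SVD machinery is shared with the
    implementation under test.
    """
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(((a @ r.T - b) ** 2).sum() / len(a)))

    rots = Rotation.random(n_starts, random_state=12345).as_rotvec()
    scores = [rmsd_of(v) for v in rots]
    best = np.inf
    for i in np.argsort(scores)[:8]:
        res = minimize(rmsd_of, rots[i], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


def _sub(coords, types=("A", "A", "A"), subset=(0, 1, 2), sid="s"):
    return Substructure(
        sid, subset,
        [ResidueSite(c, t, np.asarray(xyz, float))
         for c, t, xyz in zip(subset, types, coords)],
    )


class TestLrmsd:
    def test_identity_is_zero(self):
        coords = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        assert superpose_lrmsd(_sub(coords), _sub(coords)) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=(3, 3))
            r = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            b = a @ r.T + rng.uniform(-10, 10, size=3)
            assert superpose_lrmsd(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_translation_only(self):
        a = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0)], float)
        assert superpose_lrmsd(a, a + 5.0) == pytest.approx(0.0, abs=1e-9)

    def test_scaled_triangle_matches_oracle(self):
        # frozen from the brute-force rotation oracle on this exact pair
        a = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0)], float)
        b = np.array([(0, 0, 0), (2, 0, 0), (0, 2, 0)], float)
        expected = brute_force_lrmsd(a, b)
        assert superpose_lrmsd(a, b) == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(2.0 / 3.0, abs=2e-3)

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = rng.normal(scale=3.0, size=(3, 3))
            b = rng.normal(scale=3.0, size=(3, 3))
            assert superpose_lrmsd(a, b) == pytest.approx(
                brute_force_lrmsd(a, b), abs=1e-3
            )

    def test_degenerate_coincident_points(self):
        a = np.zeros((3, 3))
        b = np.array([(0, 0, 0), (1, 0, 0), (0, 1, 0)], float)
        val = superpose_lrmsd(a, b)
        assert np.isfinite(val) and val > 0

    def test_shared_subset_required(self):
        a = _sub([(0, 0, 0), (1, 0, 0), (0, 1, 0)], subset=(0, 1, 2))
        b = _sub([(0, 0, 0), (1, 0, 0), (0, 1, 0)], subset=(0, 1, 3))
        with pytest.raises(ValueError):
            superpose_lrmsd(a, b)

    def test_batched_matches_scalar(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=4.0, size=(8, 3, 3))
        mat = pairwise_lrmsd(coords)
        for i in range(8):
            for j in range(i + 1, 8):
                assert mat[i, j] == pytest.approx(
                    superpose_lrmsd(coords[i], coords[j]), abs=1e-9
                )


class TestPharm:
    def test_zero_diagonal_and_symmetry(self, pharm):
        for t1 in STANDARD_AA:
            assert pharm_dissimilarity(t1, t1, pharm) == 0.0
            for t2 in STANDARD_AA:
                assert pharm_dissimilarity(t1, t2, pharm) == pharm_dissimilarity(t2, t1, pharm)

    def test_similar_types_closer(self, pharm):
        # Asp/Glu share every pharmacophore feature; Asp/Phe share none
        assert pharm_dissimilarity("D", "E", pharm) < pharm_dissimilarity("D", "F", pharm)

    def test_unknown_type_rejected(self, pharm):
        with pytest.raises(KeyError):
            pharm_dissimilarity("Z", "A", pharm)

    def test_invalid_matrix_rejected(self):
        bad = np.ones((20, 20))  # non-zero diagonal
        with pytest.raises(ValueError):
            PharmMatrix(STANDARD_AA, bad)

    def test_csv_round_trip(self, pharm, tmp_path):
        from ccorps.distance import load_pharm_matrix

        path = tmp_path / "m.csv"
        pharm.to_csv(path)
        again = load_pharm_matrix(path)
        assert np.allclose(again.values, pharm.values)


class TestSubstructureDistance:
    def test_identical_is_zero(self, pharm):
        s = _sub([(0, 0, 0), (1, 0, 0), (0, 1, 0)], types=("A", "V", "K"))
        assert substructure_distance(s, s, pharm) == 0.0

    def test_pure_pharm_term(self, pharm):
        coords = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        a = _sub(coords, types=("A", "V", "K"))
        b = _sub(coords, types=("A", "V", "D"))
        expected = 2.5 * pharm.lookup("K", "D")
        assert substructure_distance(a, b, pharm, w_pharm=2.5) == pytest.approx(expected)

    def test_symmetry(self, pharm):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = _sub(rng.normal(size=(3, 3)), types=tuple(rng.choice(list(STANDARD_AA), 3)))
            b = _sub(rng.normal(size=(3, 3)), types=tuple(rng.choice(list(STANDARD_AA), 3)))
            assert substructure_distance(a, b, pharm) == pytest.approx(
                substructure_distance(b, a, pharm)
            )

    def test_negative_weights_rejected(self, pharm):
        s = _sub([(0, 0, 0), (1, 0, 0), (0, 1, 0)])
        with pytest.raises(ValueError):
            substructure_distance(s, s, pharm, w_struct=-1.0)


class TestDistanceMatrix:
    def test_spot_check_against_direct(self, worked_example, pharm):
        from ccorps.distance import substructure

        sset, _ = worked_example
        subset = (0, 2, 4)
        dm = distance_matrix(sset, subset, pharm)
        rng = np.random.default_rng(1)
        n = len(sset)
        for _ in range(5):
            i, j = rng.integers(n, size=2)
            direct = substructure_distance(
                substructure(sset, int(i), subset),
                substructure(sset, int(j), subset),
                pharm,
            )
            assert dm.matrix[i, j] == pytest.approx(direct, abs=1e-6)

    def test_duplicated_structure(self, pharm):
        from ccorps.io_model import AlignedStructure, AlignedStructureSet

        sites = [ResidueSite(c, "A", np.array([float(c), 0, 0])) for c in range(3)]
        sset = AlignedStructureSet(
            [AlignedStructure(f"x{i}", f"x{i}", None, list(sites)) for i in range(2)],
            [0, 1, 2],
        )
        dm = distance_matrix(sset, (0, 1, 2), pharm)
        assert dm.matrix[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(dm.matrix[0], dm.matrix[1])

    def test_symmetry_and_diagonal(self, worked_example, pharm):
        sset, _ = worked_example
        dm = distance_matrix(sset, (0, 1, 2), pharm)
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0.0)
        assert np.all(dm.matrix >= 0)


class TestEnumerateSubsets:
    @pytest.mark.parametrize("P,expected", [(20, 1140), (27, 2925), (3, 1)])
    def test_counts(self, P, expected):
        assert len(enumerate_subsets(P, 3)) == expected

    def test_counts_match_binomial(self):
        for P in range(3, 31):
            assert len(enumerate_subsets(P, 3)) == comb(P, 3)

    def test_lexicographic_and_increasing(self):
        subs = enumerate_subsets(6, 3)
        assert subs == sorted(subs)
        assert all(a < b < c for a, b, c in subs)

    def test_k_larger_than_p_rejected(self):
        with pytest.raises(ValueError):
            enumerate_subsets(2, 3)

    def test_column_subsets_uses_labels(self):
        assert column_subsets([10, 3, 7], 2) == [(3, 7), (3, 10), (7, 10)]
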