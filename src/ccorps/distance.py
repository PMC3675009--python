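"""Substructure dissimilarity: rigid-superposition lRMSD plus a
pharmacophore-feature term.

Two substructures (3 residues drawn from the same alignment columns of two
structures) are compared by

    D(a, b) = w_struct * lRMSD(a, b)
            + w_pharm * sum_i  pharm(type_a_i, type_b_i)

where lRMSD is the least RMSD of the three corresponding side-chain
centroids under optimal proper rigid superposition (correspondence is fixed
by alignment column; reflections are disallowed), and ``pharm`` is a 20x20
symmetric amino-acid dissimilarity.  The default pharmacophore matrix
counts differing binary features (H-bond donor, H-bond acceptor, aromatic,
positively ionizable, negatively ionizable, hydrophobic) between the two
residue types; it is stored as CSV and can be replaced by any matrix with
the same shape and invariants.

Three-residue subsets are the smallest that admit a unique 3-D
superposition, which is why the combinatorial enumeration works on
position triples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_model import AlignedStructureSet, ResidueSite, STANDARD_AA

__all__ = [
    "PharmMatrix",
    "Substructure",
    "DistanceMatrix",
    "PHARM_FEATURES",
    "default_pharm_matrix",
    "load_pharm_matrix",
    "superpose_lrmsd",
    "pairwise_lrmsd",
    "pharm_dissimilarity",
    "substructure_distance",
    "distance_matrix",
    "enumerate_subsets",
    "column_subsets",
]

#: binary pharmacophore features per residue type:
#: (donor, acceptor, aromatic, positive, negative, hydrophobic)
PHARM_FEATURES: dict[str, tuple[int, int, int, int, int, int]] = {
    "A": (0, 0, 0, 0, 0, 1),
    "C": (0, 0, 0, 0, 0, 1),
    "D": (0, 1, 0, 0, 1, 0),
    "E": (0, 1, 0, 0, 1, 0),
    "F": (0, 0, 1, 0, 0, 1),
    "G": (0, 0, 0, 0, 0, 0),
    "H": (1, 1, 1, 1, 0, 0),
    "I": (0, 0, 0, 0, 0, 1),
    "K": (1, 0, 0, 1, 0, 0),
    "L": (0, 0, 0, 0, 0, 1),
    "M": (0, 0, 0, 0, 0, 1),
    "N": (1, 1, 0, 0, 0, 0),
    "P": (0, 0, 0, 0, 0, 1),
    "Q": (1, 1, 0, 0, 0, 0),
    "R": (1, 0, 0, 1, 0, 0),
    "S": (1, 1, 0, 0, 0, 0),
    "T": (1, 1, 0, 0, 0, 1),
    "V": (0, 0, 0, 0, 0, 1),
    "W": (1, 0, 1, 0, 0, 1),
    "Y": (1, 1, 1, 0, 0, 1),
}


@dataclass
class PharmMatrix:
    """Symmetric 20x20 amino-acid dissimilarity with zero diagonal."""

    letters: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._index = {aa: i for i, aa in enumerate(self.letters)}
        if self.values.shape != (len(self.letters), len(self.letters)):
            raise ValueError("matrix shape does not match letters")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    def lookup(self, t1: str, t2: str) -> float:
        try:
            return float(self.values[self._index[t1], self._index[t2]])
        except KeyError as exc:
            raise KeyError(f"unknown residue type {exc.args[0]!r}") from None

    def type_indices(self, types: Sequence[str]) -> np.ndarray:
        return np.array([self._index[t] for t in types])

    def to_csv(self, path: str | Path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["", *self.letters])
            for aa, row in zip(self.letters, self.values):
                w.writerow([aa, *[f"{v:.6g}" for v in row]])


def default_pharm_matrix(scale: float = 1.0) -> PharmMatrix:
    """Feature-difference matrix: count of differing binary features, scaled.

    The scale (default 1.0) sets the weight of one feature difference in the
    same units as the Angstrom-scale structural term.
    """
    feats = np.array([PHARM_FEATURES[aa] for aa in STANDARD_AA], dtype=float)
    diff = np.abs(feats[:, None, :] - feats[None, :, :]).sum(axis=2)
    return PharmMatrix(STANDARD_AA, scale * diff)


def load_pharm_matrix(path: str | Path) -> PharmMatrix:
    """Load a replacement matrix from CSV (residue-letter header row/column)."""
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    letters = tuple(rows[0][1:])
    values = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
    return PharmMatrix(letters, values)


@dataclass
class Substructure:
    """One structure's residues at one strictly-increasing column triple."""

    structure_id: str
    subset: tuple[int, ...]
    residues: list[ResidueSite]

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.subset):
            raise ValueError("one residue per subset column required")
        if any(a >= b for a, b in zip(self.subset, self.subset[1:])):
            raise ValueError("subset columns must be strictly increasing")

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.centroid for r in self.residues])

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(r.residue_type for r in self.residues)


@dataclass
class DistanceMatrix:
    subset: tuple[int, ...]
    matrix: np.ndarray
    structure_ids: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-9):
            raise ValueError("diagonal must be zero")
        if np.any(m < -1e-12):
            raise ValueError("distances must be non-negative")
        self.matrix = np.maximum(m, 0.0)


# ---------------------------------------------------------------------------
# superposition


def _centered(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(coords, dtype=float)
    mean = c.mean(axis=-2, keepdims=True)
    return c - mean, mean


def superpose_lrmsd(a: "Substructure | np.ndarray", b: "Substructure | np.ndarray") -> float:
    """Least RMSD over corresponding points after optimal proper rigid fit.

    Accepts :class:`Substructure` objects sharing a subset, or bare (k, 3)
    coordinate arrays.  The correspondence is positional; no search over
    residue matchings is performed, and reflections are disallowed.
    """
    if isinstance(a, Substructure) or isinstance(b, Substructure):
        if not (isinstance(a, Substructure) and isinstance(b, Substructure)):
            raise TypeError("both arguments must be Substructure or both arrays")
        if a.subset != b.subset:
            raise ValueError("substructures must share the same column subset")
        pa, pb = a.coords, b.coords
    else:
        pa, pb = np.asarray(a, float), np.asarray(b, float)
    if pa.shape != pb.shape:
        raise ValueError("point sets must have equal shape")
    xa, _ = _centered(pa)
    xb, _ = _centered(pb)
    k = pa.shape[0]
    h = xa.T @ xb
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    trace = s[0] + s[1] + sign * s[2] if len(s) == 3 else (s * 1.0).sum()
    sq = (xa**2).sum() + (xb**2).sum() - 2.0 * trace
    return float(np.sqrt(max(sq, 0.0) / k))


def pairwise_lrmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs lRMSD for N point sets of shape (N, k, 3), batched.

    Uses batched SVD of the 3x3 cross-covariance with the proper-rotation
    determinant correction (Kabsch), so it matches :func:`superpose_lrmsd`
    entrywise.
    """
    x, _ = _centered(coords)
    n, k, _ = x.shape
    sq_norm = (x**2).sum(axis=(1, 2))
    iu, ju = np.triu_indices(n, k=1)
    h = np.einsum("pki,pkj->pij", x[iu], x[ju])
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    sq = np.maximum(sq_norm[iu] + sq_norm[ju] - 2.0 * trace, 0.0)
    out = np.zeros((n, n))
    out[iu, ju] = out[ju, iu] = np.sqrt(sq / k)
    return out


# ---------------------------------------------------------------------------
# combined dissimilarity


def pharm_dissimilarity(t1: str, t2: str, matrix: PharmMatrix) -> float:
    """Pharmacophore-feature dissimilarity between two residue types."""
    return matrix.lookup(t1, t2)


def substructure_distance(
    a: Substructure,
    b: Substructure,
    matrix: PharmMatrix,
    w_struct: float = 1.0,
    w_pharm: float = 1.0,
) -> float:
    """Weighted sum of the structural and per-position pharmacophore terms."""
    if w_struct < 0 or w_pharm < 0:
        raise ValueError("weights must be non-negative")
    lrmsd = superpose_lrmsd(a, b)
    pharm = sum(matrix.lookup(ta, tb) for ta, tb in zip(a.types, b.types))
    return w_struct * lrmsd + w_pharm * pharm


def distance_matrix(
    sset: AlignedStructureSet,
    subset: Sequence[int],
    matrix: PharmMatrix,
    w_struct: float = 1.0,
    w_pharm: float = 1.0,
) -> DistanceMatrix:
    """N x N combined dissimilarity over all structure pairs for one subset."""
    if w_struct < 0 or w_pharm < 0:
        raise ValueError("weights must be non-negative")
    subset = tuple(subset)
    if any(c not in sset.position_columns for c in subset):
        raise ValueError("subset columns must be among the set's position columns")
    coords = sset.centroid_array(subset)
    geo = pairwise_lrmsd(coords)
    types = sset.residue_types(subset)
    idx = np.array([matrix.type_indices(t) for t in types])  # (N, k)
    pharm = np.zeros_like(geo)
    for p in range(idx.shape[1]):
        pharm += matrix.values[idx[:, p][:, None], idx[:, p][None, :]]
    total = w_struct * geo + w_pharm * pharm
    np.fill_diagonal(total, 0.0)
    return DistanceMatrix(subset, total, sset.structure_ids)


def substructure(sset: AlignedStructureSet, structure_index: int, subset: Sequence[int]) -> Substructure:
    """Convenience accessor for one structure's substructure at a subset."""
    st = sset.structures[structure_index]
    return Substructure(
        st.structure_id, tuple(subset), [st.site_at(c) for c in subset]
    )


# ---------------------------------------------------------------------------
# subset enumeration


def enumerate_subsets(P: int, k: int = 3) -> list[tuple[int, ...]]:
    """All C(P, k) strictly increasing k-tuples over 0..P-1, lexicographic."""
    if not 1 <= k <= P:
        raise ValueError(f"require 1 <= k <= P, got k={k}, P={P}")
    out = list(combinations(range(P), k))
    assert len(out) == comb(P, k)
    return out


def column_subsets(columns: Sequence[int], k: int = 3) -> list[tuple[int, ...]]:
    """All k-subsets of actual column labels, in lexicographic order."""
    return list(combinations(sorted(columns), k))
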