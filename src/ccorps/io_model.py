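"""Data model and input handling for aligned binding-site substructures.

A binding site is described by a set of master-alignment columns.  Every
protein structure contributes, at each selected column, the residue type and
the centroid of its side-chain heavy atoms.  Labels (e.g. inhibitor binding)
are attached per (sequence, compound) pair and may be true, false or
unknown; unknown is the default for absent pairs.

Structures can come from PDB/mmCIF files (via gemmi) together with an
aligned-FASTA or Stockholm master alignment (via Biopython), or from a plain
CSV "site table" that already lists per-column residue types and centroids
(the format the synthetic generator emits).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "STANDARD_AA",
    "THREE_TO_ONE",
    "ResidueSite",
    "AlignedStructure",
    "AlignedStructureSet",
    "LabelTable",
    "PositionSpec",
    "StructureResidues",
    "MalformedResidueError",
    "extract_sidechain_centroid",
    "select_binding_site_positions",
    "build_structure_set",
    "bin_affinities",
    "read_msa",
    "read_label_csv",
    "read_family_csv",
    "read_site_table",
    "write_site_table",
    "load_structure_residues",
]

#: the 20 standard amino acids, one-letter codes, alphabetical
STANDARD_AA = tuple("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# backbone atoms excluded from the side-chain centroid
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


class MalformedResidueError(ValueError):
    """Residue lacks the atoms needed to define a side-chain centroid."""


@dataclass(frozen=True)
class ResidueSite:
    """One residue at one master-alignment column.

    ``centroid`` is the mean of the side-chain heavy-atom coordinates in
    Angstroms (CA for glycine).
    """

    column_index: int
    residue_type: str
    centroid: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centroid, dtype=float)
        object.__setattr__(self, "centroid", c)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("centroid must be a finite 3-vector")
        if self.residue_type not in STANDARD_AA:
            raise ValueError(f"invalid residue type {self.residue_type!r}")


@dataclass
class AlignedStructure:
    """A structure reduced to its residues at the selected columns."""

    structure_id: str
    sequence_id: str
    family_label: str | None
    sites: list[ResidueSite]

    def __post_init__(self) -> None:
        cols = [s.column_index for s in self.sites]
        if sorted(set(cols)) != cols:
            raise ValueError("sites must be ordered by column with no duplicates")
        self._by_column = {s.column_index: s for s in self.sites}

    def site_at(self, column: int) -> ResidueSite:
        return self._by_column[column]


@dataclass
class AlignedStructureSet:
    """All retained structures plus the binding-site column list."""

    structures: list[AlignedStructure]
    position_columns: list[int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.structure_id for s in self.structures]
        if len(set(ids)) != len(ids):
            raise ValueError("structure_id must be unique within a set")
        self.validate()

    def validate(self) -> None:
        for st in self.structures:
            for col in self.position_columns:
                if col not in st._by_column:
                    raise ValueError(
                        f"structure {st.structure_id} missing column {col}"
                    )

    def __len__(self) -> int:
        return len(self.structures)

    @property
    def structure_ids(self) -> list[str]:
        return [s.structure_id for s in self.structures]

    @property
    def sequence_ids(self) -> list[str]:
        """Per-structure sequence ids (parallel to ``structures``)."""
        return [s.sequence_id for s in self.structures]

    @property
    def unique_sequence_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.structures:
            seen.setdefault(s.sequence_id, None)
        return list(seen)

    def sequence_index(self) -> np.ndarray:
        """Integer index of each structure's sequence (order of unique ids)."""
        order = {sid: i for i, sid in enumerate(self.unique_sequence_ids)}
        return np.array([order[s.sequence_id] for s in self.structures])

    def structure_weights(self) -> np.ndarray:
        """Overrepresentation weights: 1 / (#structures of the sequence)."""
        idx = self.sequence_index()
        counts = np.bincount(idx)
        return 1.0 / counts[idx]

    def centroid_array(self, subset: Sequence[int]) -> np.ndarray:
        """(N, k, 3) side-chain centroids at the given columns."""
        return np.array(
            [[st.site_at(c).centroid for c in subset] for st in self.structures]
        )

    def residue_types(self, subset: Sequence[int]) -> list[tuple[str, ...]]:
        return [
            tuple(st.site_at(c).residue_type for c in subset)
            for st in self.structures
        ]

    def aligned_sequences(self) -> dict[str, str]:
        """Per-sequence residue string over the selected columns.

        Used for identity-based fold construction when no fuller domain
        alignment is supplied.
        """
        out: dict[str, str] = {}
        for st in self.structures:
            out.setdefault(
                st.sequence_id,
                "".join(st.site_at(c).residue_type for c in self.position_columns),
            )
        return out

    def family_map(self) -> dict[str, str | None]:
        fam: dict[str, str | None] = {}
        for st in self.structures:
            fam.setdefault(st.sequence_id, st.family_label)
        return fam


@dataclass
class LabelTable:
    """True/false/unknown labels per (sequence_id, compound_id).

    ``entries`` holds only known labels as booleans; any absent pair is
    unknown.  ``family`` maps sequence_id to its phylogenetic family.
    """

    entries: dict[tuple[str, str], bool] = field(default_factory=dict)
    family: dict[str, str] = field(default_factory=dict)

    def label(self, sequence_id: str, compound_id: str) -> bool | None:
        return self.entries.get((sequence_id, compound_id))

    @property
    def compounds(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, comp in self.entries:
            seen.setdefault(comp, None)
        return list(seen)

    def labels_for(self, compound_id: str) -> dict[str, bool]:
        return {
            seq: lab
            for (seq, comp), lab in self.entries.items()
            if comp == compound_id
        }

    def masked(self, sequence_ids: Iterable[str], compound_id: str) -> "LabelTable":
        """Copy with the given sequences' labels for one compound set unknown."""
        hide = set(sequence_ids)
        entries = {
            (seq, comp): lab
            for (seq, comp), lab in self.entries.items()
            if not (comp == compound_id and seq in hide)
        }
        return LabelTable(entries=entries, family=dict(self.family))


@dataclass
class PositionSpec:
    """How binding-site columns are chosen.

    ``explicit-columns`` takes the column list as given; ``ligand-proximity``
    selects columns whose residue has any atom within ``cutoff`` Å of any
    ligand atom in a reference structure, then drops columns whose alignment
    gap fraction exceeds ``max_gap_fraction``.
    """

    mode: str = "ligand-proximity"
    columns: list[int] | None = None
    reference_structure_id: str | None = None
    ligand_id: str | None = None
    cutoff: float = 5.0
    max_gap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("explicit-columns", "ligand-proximity"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "explicit-columns" and not self.columns:
            raise ValueError("explicit mode requires a non-empty column list")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# side-chain centroid extraction


def extract_sidechain_centroid(
    residue_atoms: Iterable[tuple[str, str, Sequence[float]]],
) -> np.ndarray:
    """Mean coordinate of the side-chain heavy atoms of one residue.

    ``residue_atoms`` yields (atom_name, element, xyz) triples.  Hydrogens
    are ignored; backbone atoms (N, CA, C, O, OXT) are excluded.  A residue
    with no side-chain heavy atoms (glycine) falls back to its CA position.
    """
    side: list[np.ndarray] = []
    ca: np.ndarray | None = None
    for name, element, xyz in residue_atoms:
        if element.upper() in ("H", "D"):
            continue
        if name == "CA":
            ca = np.asarray(xyz, dtype=float)
        if name in _BACKBONE:
            continue
        side.append(np.asarray(xyz, dtype=float))
    if side:
        return np.mean(side, axis=0)
    if ca is not None:
        return ca
    raise MalformedResidueError("residue has neither side-chain heavy atoms nor CA")


# ---------------------------------------------------------------------------
# structure reading (gemmi) and alignment mapping


@dataclass
class StructureResidues:
    """Light record of one chain's polymer residues, in sequence order.

    ``residues`` holds (one_letter_type, centroid-or-None) pairs; None marks
    a residue whose side chain could not be resolved (treated as a gap).
    ``atoms`` optionally keeps the full heavy-atom coordinates for proximity
    queries, as a list parallel to ``residues`` of (M_i, 3) arrays.
    """

    structure_id: str
    sequence_id: str
    residues: list[tuple[str | None, np.ndarray | None]]
    atoms: list[np.ndarray] | None = None

    @property
    def sequence(self) -> str:
        return "".join(t if t is not None else "X" for t, _ in self.residues)


def _pick_altloc(atoms):
    """Keep one conformer per atom name: highest occupancy, then altloc order."""
    best: dict[str, tuple[float, str, object]] = {}
    for a in atoms:
        key = a.name
        rank = (a.occ, "~" if not a.altloc else chr(255 - ord(a.altloc[0])))
        if key not in best or rank > best[key][:2]:
            best[key] = (rank[0], rank[1], a)
    return [v[2] for v in best.values()]


def load_structure_residues(
    path: str | Path,
    structure_id: str | None = None,
    sequence_id: str | None = None,
    chain: str | None = None,
    keep_atoms: bool = False,
) -> StructureResidues:
    """Read a PDB or mmCIF file into a :class:`StructureResidues` record."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = [model[chain]] if chain else list(model)
    residues: list[tuple[str | None, np.ndarray | None]] = []
    atom_coords: list[np.ndarray] = []
    for ch in chains:
        for res in ch:
            one = THREE_TO_ONE.get(res.name)
            if one is None:
                continue  # ligand / water / non-standard
            picked = _pick_altloc(list(res))
            triples = [
                (a.name, a.element.name, (a.pos.x, a.pos.y, a.pos.z))
                for a in picked
            ]
            try:
                centroid = extract_sidechain_centroid(triples)
            except MalformedResidueError:
                centroid = None
            residues.append((one, centroid))
            if keep_atoms:
                atom_coords.append(
                    np.array(
                        [xyz for _, el, xyz in triples if el.upper() not in ("H", "D")]
                    ).reshape(-1, 3)
                )
    sid = structure_id or Path(path).stem
    return StructureResidues(
        structure_id=sid,
        sequence_id=sequence_id or sid,
        residues=residues,
        atoms=atom_coords if keep_atoms else None,
    )


def read_msa(path: str | Path, fmt: str | None = None) -> dict[str, str]:
    """Read an aligned FASTA or Stockholm file as {sequence_id: aligned row}."""
    from Bio import AlignIO

    if fmt is None:
        fmt = "stockholm" if str(path).endswith((".sto", ".stk", ".stockholm")) else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return {rec.id: str(rec.seq).upper() for rec in aln}


def _is_gap(ch: str) -> bool:
    return ch in "-."


def map_sequence_to_columns(sequence: str, aligned_row: str) -> list[int] | None:
    """Alignment column of each residue of ``sequence`` within ``aligned_row``.

    The structure's residue sequence must occur as a contiguous block of the
    row's ungapped sequence (structures often cover only part of the aligned
    domain).  Returns None when it does not.
    """
    cols = [i for i, ch in enumerate(aligned_row) if not _is_gap(ch)]
    ungapped = "".join(aligned_row[i] for i in cols)
    start = ungapped.find(sequence)
    if start < 0:
        return None
    return cols[start : start + len(sequence)]


def ligand_atom_coords(path: str | Path, ligand_id: str) -> np.ndarray:
    """Heavy-atom coordinates of the named ligand in a structure file."""
    import gemmi

    st = gemmi.read_structure(str(path))
    coords = [
        (a.pos.x, a.pos.y, a.pos.z)
        for model in st
        for ch in model
        for res in ch
        if res.name == ligand_id
        for a in res
        if a.element.name.upper() not in ("H", "D")
    ]
    if not coords:
        raise ValueError(f"ligand {ligand_id!r} not found in {path}")
    return np.array(coords, dtype=float)


def select_binding_site_positions(
    reference: StructureResidues,
    ligand_coords: np.ndarray,
    spec: PositionSpec,
    msa: Mapping[str, str],
) -> list[int]:
    """Columns whose reference residue lies within ``spec.cutoff`` of the ligand.

    A residue qualifies when at least one of its heavy atoms is within the
    cutoff of at least one ligand atom.  Columns more gapped than
    ``spec.max_gap_fraction`` across the alignment are then removed.
    """
    if spec.mode == "explicit-columns":
        return sorted(spec.columns)  # type: ignore[arg-type]
    if reference.atoms is None:
        raise ValueError("reference structure must be loaded with keep_atoms=True")
    row = msa.get(reference.sequence_id)
    if row is None:
        raise ValueError(f"reference sequence {reference.sequence_id!r} not in MSA")
    cols = map_sequence_to_columns(reference.sequence, row)
    if cols is None:
        raise ValueError("reference sequence does not map onto its MSA row")
    lig = np.asarray(ligand_coords, dtype=float)
    selected = []
    for res_idx, atoms in enumerate(reference.atoms):
        if atoms.size == 0:
            continue
        d2 = ((atoms[:, None, :] - lig[None, :, :]) ** 2).sum(axis=2)
        if math.sqrt(d2.min()) <= spec.cutoff:
            selected.append(cols[res_idx])
    rows = list(msa.values())
    surviving = []
    for col in sorted(set(selected)):
        gap_frac = sum(_is_gap(r[col]) for r in rows) / len(rows)
        if gap_frac <= spec.max_gap_fraction:
            surviving.append(col)
    if not surviving:
        raise ValueError("no binding-site columns survive selection")
    return surviving


def build_structure_set(
    structures: Iterable[StructureResidues],
    msa: Mapping[str, str],
    columns: Sequence[int],
    families: Mapping[str, str] | None = None,
) -> AlignedStructureSet:
    """Assemble the aligned set, dropping structures gapped at any column.

    A structure is dropped when its sequence cannot be mapped to its MSA
    row, when its row is gapped at a selected column, or when the residue at
    a selected column is unresolved (no usable side-chain centroid).
    Dropped counts are recorded in the returned set's provenance.
    """
    columns = sorted(columns)
    if not columns:
        raise ValueError("empty column list")
    kept: list[AlignedStructure] = []
    dropped = {"unmappable": 0, "gap_at_column": 0, "unresolved_residue": 0}
    families = families or {}
    for rec in structures:
        row = msa.get(rec.sequence_id)
        cols = map_sequence_to_columns(rec.sequence, row) if row is not None else None
        if cols is None:
            dropped["unmappable"] += 1
            continue
        col_to_res = {c: i for i, c in enumerate(cols)}
        sites: list[ResidueSite] = []
        reason = None
        for col in columns:
            if col not in col_to_res:
                reason = "gap_at_column"
                break
            rtype, centroid = rec.residues[col_to_res[col]]
            if rtype is None or centroid is None:
                reason = "unresolved_residue"
                break
            sites.append(ResidueSite(col, rtype, centroid))
        if reason:
            dropped[reason] += 1
            continue
        kept.append(
            AlignedStructure(
                structure_id=rec.structure_id,
                sequence_id=rec.sequence_id,
                family_label=families.get(rec.sequence_id),
                sites=sites,
            )
        )
    prov = {
        "n_input": len(kept) + sum(dropped.values()),
        "n_retained": len(kept),
        "dropped": dropped,
        "columns": list(columns),
    }
    return AlignedStructureSet(kept, list(columns), provenance=prov)


# ---------------------------------------------------------------------------
# labels


def bin_affinities(
    kd_table: Mapping[tuple[str, str], float],
    threshold: float = 10_000.0,
    family: Mapping[str, str] | None = None,
) -> LabelTable:
    """Bin Kd values (nM) into binary binding labels.

    Kd <= threshold (default 10 µM = 10,000 nM) means the compound binds
    (true); larger Kd means it does not (false); missing pairs stay unknown.
    The boundary maps to true: the threshold is the largest Kd still treated
    as meaningful binding.
    """
    entries: dict[tuple[str, str], bool] = {}
    for (seq, comp), kd in kd_table.items():
        if kd is None or (isinstance(kd, float) and math.isnan(kd)):
            continue
        if kd <= 0:
            raise ValueError(f"non-positive Kd for {(seq, comp)}: {kd}")
        entries[(seq, comp)] = kd <= threshold
    return LabelTable(entries=entries, family=dict(family or {}))


def read_label_csv(path: str | Path, threshold: float = 10_000.0) -> LabelTable:
    """Read a label CSV.

    Header either ``sequence_id,compound_id,kd_nm`` (affinities, binned at
    ``threshold``) or ``sequence_id,compound_id,label`` with label in
    {true,false,unknown}.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        if "kd_nm" in fields:
            kd: dict[tuple[str, str], float] = {}
            for row in reader:
                val = row["kd_nm"].strip()
                if val:
                    kd[(row["sequence_id"], row["compound_id"])] = float(val)
            return bin_affinities(kd, threshold)
        if "label" in fields:
            entries: dict[tuple[str, str], bool] = {}
            for row in reader:
                lab = row["label"].strip().lower()
                if lab == "unknown" or not lab:
                    continue
                if lab not in ("true", "false"):
                    raise ValueError(f"invalid label {row['label']!r}")
                entries[(row["sequence_id"], row["compound_id"])] = lab == "true"
            return LabelTable(entries=entries)
    raise ValueError("label CSV must have a kd_nm or label column")


def read_family_csv(path: str | Path) -> dict[str, str]:
    """Read ``sequence_id,family`` CSV into a dict."""
    with open(path, newline="") as fh:
        return {
            row["sequence_id"]: row["family"]
            for row in csv.DictReader(fh)
        }


# ---------------------------------------------------------------------------
# CSV site table (internal coordinate format)

_SITE_FIELDS = [
    "structure_id", "sequence_id", "family", "column", "residue_type",
    "x", "y", "z",
]


def write_site_table(sset: AlignedStructureSet, path: str | Path) -> None:
    """Write the aligned set as a flat per-site CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_SITE_FIELDS)
        for st in sset.structures:
            for site in st.sites:
                w.writerow(
                    [
                        st.structure_id,
                        st.sequence_id,
                        st.family_label or "",
                        site.column_index,
                        site.residue_type,
                        f"{site.centroid[0]:.6f}",
                        f"{site.centroid[1]:.6f}",
                        f"{site.centroid[2]:.6f}",
                    ]
                )


def read_site_table(path: str | Path) -> AlignedStructureSet:
    """Read a per-site CSV back into an :class:`AlignedStructureSet`."""
    by_structure: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rec = by_structure.setdefault(
                row["structure_id"],
                {
                    "sequence_id": row["sequence_id"],
                    "family": row["family"] or None,
                    "sites": [],
                },
            )
            rec["sites"].append(
                ResidueSite(
                    int(row["column"]),
                    row["residue_type"],
                    np.array([float(row["x"]), float(row["y"]), float(row["z"])]),
                )
            )
    structures = [
        AlignedStructure(
            structure_id=sid,
            sequence_id=rec["sequence_id"],
            family_label=rec["family"],
            sites=sorted(rec["sites"], key=lambda s: s.column_index),
        )
        for sid, rec in by_structure.items()
    ]
    columns = sorted({s.column_index for st in structures for s in st.sites})
    return AlignedStructureSet(structures, columns)


def write_provenance(sset: AlignedStructureSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(sset.provenance, fh, indent=2, sort_keys=True)
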