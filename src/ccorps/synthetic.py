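"""Seeded synthetic aligned-structure datasets with planted signal.

The generator emulates the statistical shape of a multi-structure binding
site dataset: many sequences with non-uniform structure counts (geometric),
a shared background geometry at most positions, and a small number of
"signal" position triples where true- and false-labelled sequences adopt
distinct, well-separated geometric/chemical archetypes.  Binding-site
clusterings built on signal subsets therefore contain label-pure clusters
with a provable margin, while background subsets stay uninformative.

Background residue variation is chemically synonymous: each background
position draws letters from within one pharmacophore-equivalence group
(e.g. the hydrophobic set A/C/I/L/M/P/V), so sequences diverge in identity
without the background subsets acquiring chemical structure.  Signal
archetypes instead use chemically distinct residue triples, so both the
geometric and the pharmacophore distance terms carry the planted signal.

Everything is reproducible from the seed; the same config and seed give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distance import superpose_lrmsd
from .io_model import (
    AlignedStructure,
    AlignedStructureSet,
    LabelTable,
    ResidueSite,
    StructureResidues,
    build_structure_set,
    write_site_table,
)

__all__ = ["SynthConfig", "SynthTruth", "generate", "worked_example_fixture", "write_dataset"]

#: pharmacophore-synonymous letter groups used for background positions
_BACKGROUND_GROUPS = [
    tuple("ACILMPV"),  # hydrophobic
    tuple("NQS"),      # H-bond donor + acceptor
]

#: letters available to signal archetypes: distinct but chemically close
#: (pairwise feature differences of 1-2), so the pharmacophore term adds a
#: modest archetype contrast rather than one that dwarfs the geometry
_SIGNAL_LETTERS = tuple("AFWTG")

_FAMILY_NAMES = ("AGC", "CAMK", "CK1", "CMGC", "STE", "TK", "TKL", "Other")


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults describe the standard recovery setting: 60 sequences over a
    27-position site with two planted signal triples, two archetypes per
    label class, 0.1 Å coordinate jitter per structure, a fifth of the
    sequences unlabeled and no label noise.
    """

    n_sequences: int = 60
    mean_structures_per_sequence: float = 2.0
    P: int = 27
    n_families: int = 7
    #: None derives two spread-out triples from P (for P=27: (2,9,17), (5,12,23))
    signal_subsets: tuple[tuple[int, int, int], ...] | None = None
    n_signal_archetypes: int = 2
    geometric_noise_sd: float = 0.1
    label_noise_rate: float = 0.0
    fraction_true: float = 0.5
    fraction_unlabeled: float = 0.2
    compound_id: str = "compound-1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences <= 0 or self.P <= 0 or self.n_families <= 0:
            raise ValueError("counts must be positive")
        if self.signal_subsets is None:
            self.signal_subsets = _derive_signal_subsets(self.P)
        for rate in (self.label_noise_rate, self.fraction_true, self.fraction_unlabeled):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        for sub in self.signal_subsets:
            if any(not 0 <= c < self.P for c in sub) or len(sub) != 3:
                raise ValueError("signal subsets must be column triples within P")
        n_true = round(self.fraction_true * self.n_sequences)
        n_false = self.n_sequences - n_true
        if self.signal_subsets and self.n_signal_archetypes > max(n_true, n_false, 1):
            raise ValueError("more archetypes than sequences per class")


def _derive_signal_subsets(P: int) -> tuple[tuple[int, int, int], ...]:
    """Two spread-out column triples scaled to the site size."""
    if P < 3:
        raise ValueError("need at least three positions for a signal triple")
    fracs = ((2 / 27, 9 / 27, 17 / 27), (5 / 27, 12 / 27, 23 / 27))
    subsets = []
    for f in fracs:
        cols: list[int] = []
        for x in f:
            c = int(x * P)
            if cols and c <= cols[-1]:
                c = cols[-1] + 1
            cols.append(min(c, P - 1))
        if len(set(cols)) == 3:
            subsets.append(tuple(cols))
    if not subsets:
        raise ValueError("site too small to place a signal triple")
    return tuple(dict.fromkeys(subsets))


@dataclass
class SynthTruth:
    """Ground truth before masking and label noise."""

    true_label: dict[str, bool]
    family: dict[str, str]
    #: per signal subset: sequence -> archetype id (true class first:
    #: 0..A-1 true archetypes, A..2A-1 false archetypes)
    archetype: dict[tuple[int, int, int], dict[str, int]] = field(default_factory=dict)

    def planted_members(
        self, subset: tuple[int, int, int]
    ) -> dict[int, frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for seq, a in self.archetype[subset].items():
            groups.setdefault(a, set()).add(seq)
        return {a: frozenset(m) for a, m in groups.items()}


def _sample_constellation(rng, base: np.ndarray, existing: list[np.ndarray], min_sep: float) -> np.ndarray:
    """A 3-point constellation near ``base`` at >= ``min_sep`` lRMSD from others."""
    for _ in range(1000):
        cand = base + rng.normal(0.0, 2.0, size=(3, 3))
        if all(superpose_lrmsd(cand, e) >= min_sep for e in existing):
            return cand
    raise RuntimeError("failed to place a separated archetype constellation")


def _sample_type_triple(rng, existing: set[tuple[str, ...]]) -> tuple[str, ...]:
    for _ in range(1000):
        cand = tuple(rng.choice(_SIGNAL_LETTERS, size=3, replace=True))
        if cand not in existing:
            return cand
    raise RuntimeError("failed to sample a distinct archetype residue triple")


def generate(config: SynthConfig) -> tuple[AlignedStructureSet, LabelTable, SynthTruth]:
    """Build a planted dataset from the config; deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_sequences
    width = max(3, len(str(n - 1)))
    seq_ids = [f"S{i:0{width}d}" for i in range(n)]

    # labels and families
    n_true = round(config.fraction_true * n)
    perm = rng.permutation(n)
    is_true = np.zeros(n, dtype=bool)
    is_true[perm[:n_true]] = True
    fam_names = _FAMILY_NAMES[: config.n_families]
    family = {seq_ids[i]: fam_names[i % config.n_families] for i in range(n)}
    truth = SynthTruth(
        true_label={seq_ids[i]: bool(is_true[i]) for i in range(n)},
        family=family,
    )

    # background geometry and residue types
    base = rng.uniform(0.0, 20.0, size=(config.P, 3))
    group_choice = rng.random(config.P) < 0.7
    bg_groups = [
        _BACKGROUND_GROUPS[0] if g else _BACKGROUND_GROUPS[1] for g in group_choice
    ]
    seq_types = np.empty((n, config.P), dtype="<U1")
    for p in range(config.P):
        seq_types[:, p] = rng.choice(bg_groups[p], size=n)
    seq_coords = np.broadcast_to(base, (n, config.P, 3)).copy()

    # planted archetypes at the signal subsets; the separation floor is
    # 5x the jitter but capped at the constellation sampling scale, so
    # large noise genuinely erodes the planted margin instead of forcing
    # ever-wider archetype spacing
    a_per_class = config.n_signal_archetypes
    min_sep = min(5.0 * config.geometric_noise_sd, 3.0)
    true_rank = np.cumsum(is_true) - 1  # rank of each true sequence
    false_rank = np.cumsum(~is_true) - 1
    for j, sub in enumerate(config.signal_subsets):
        cols = list(sub)
        constellations: list[np.ndarray] = []
        triples: set[tuple[str, ...]] = set()
        arch_geo: list[np.ndarray] = []
        arch_types: list[tuple[str, ...]] = []
        for _ in range(2 * a_per_class):
            geo = _sample_constellation(rng, base[cols], constellations, min_sep)
            constellations.append(geo)
            types = _sample_type_triple(rng, triples)
            triples.add(types)
            arch_geo.append(geo)
            arch_types.append(types)
        assignment: dict[str, int] = {}
        for i in range(n):
            if is_true[i]:
                a = int((true_rank[i] + j) % a_per_class) if n_true else 0
            else:
                a = a_per_class + (
                    int((false_rank[i] + j) % a_per_class) if n - n_true else 0
                )
            assignment[seq_ids[i]] = a
            seq_coords[i, cols] = arch_geo[a]
            seq_types[i, cols] = arch_types[a]
        truth.archetype[tuple(sub)] = assignment

    # structures: geometric counts, per-structure jitter, random rigid frame
    p_geom = min(1.0, 1.0 / config.mean_structures_per_sequence)
    structures: list[AlignedStructure] = []
    for i, seq in enumerate(seq_ids):
        n_st = int(rng.geometric(p_geom))
        for t in range(n_st):
            jitter = rng.normal(0.0, config.geometric_noise_sd, size=(config.P, 3))
            coords = seq_coords[i] + jitter
            # a common rigid motion per structure; the lRMSD term is
            # invariant to it but superposition is genuinely exercised
            q = rng.normal(size=(3, 3))
            r, _ = np.linalg.qr(q)
            if np.linalg.det(r) < 0:
                r[:, 0] = -r[:, 0]
            coords = coords @ r.T + rng.uniform(-50.0, 50.0, size=3)
            sites = [
                ResidueSite(p, str(seq_types[i, p]), coords[p])
                for p in range(config.P)
            ]
            structures.append(
                AlignedStructure(
                    structure_id=f"{seq}_x{t}",
                    sequence_id=seq,
                    family_label=family[seq],
                    sites=sites,
                )
            )
    sset = AlignedStructureSet(
        structures,
        list(range(config.P)),
        provenance={"generator": "synthetic", "seed": config.seed},
    )

    # observed labels: flip noise, then mask a fraction to unknown
    observed = dict(truth.true_label)
    if config.label_noise_rate > 0:
        flips = rng.random(n) < config.label_noise_rate
        for i, seq in enumerate(seq_ids):
            if flips[i]:
                observed[seq] = not observed[seq]
    n_hidden = round(config.fraction_unlabeled * n)
    hidden = set(rng.choice(seq_ids, size=n_hidden, replace=False)) if n_hidden else set()
    entries = {
        (seq, config.compound_id): lab
        for seq, lab in observed.items()
        if seq not in hidden
    }
    labels = LabelTable(entries=entries, family=dict(family))
    return sset, labels, truth


# ---------------------------------------------------------------------------
# hand-written micro fixture


def worked_example_fixture() -> tuple[AlignedStructureSet, LabelTable]:
    """Tiny deterministic dataset exercising every code path.

    Five alignment columns; eleven retained structures plus one structure
    dropped for a gap.  True- and false-labelled sequences sit at two
    well-separated geometries at every column, one sequence has two
    structures, one residue is a glycine, two sequences are unlabeled, and
    one unlabeled outlier structure is so remote that it lands in
    single-member clusters everywhere and receives zero votes.
    """
    true_types = "AVKDG"
    false_types = "LNRES"
    out_types = "WWYYF"
    base_true = np.array(
        [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 3.0, 0.0], [0.0, 0.0, 3.0], [3.0, 3.0, 0.0]]
    )
    base_false = base_true + np.array([12.0, 0.0, 0.0])
    base_out = base_true + np.array([0.0, 500.0, 0.0])

    def rec(structure_id, sequence_id, types, coords, skip_col=None):
        residues = []
        for p in range(5):
            if p == skip_col:
                continue
            residues.append((types[p], np.asarray(coords[p], float)))
        return StructureResidues(structure_id, sequence_id, residues)

    def shifted(base, dx):
        return base + np.array(dx)

    records = [
        rec("T1_a", "T1", true_types, shifted(base_true, [0.05, 0.0, 0.0])),
        rec("T1_b", "T1", true_types, shifted(base_true, [-0.05, 0.02, 0.0])),
        rec("T2_a", "T2", true_types, shifted(base_true, [0.0, 0.05, -0.02])),
        rec("T3_a", "T3", true_types, shifted(base_true, [0.02, -0.04, 0.03])),
        rec("T4_a", "T4", true_types, shifted(base_true, [-0.03, 0.0, 0.05])),
        rec("F1_a", "F1", false_types, shifted(base_false, [0.04, 0.01, 0.0])),
        rec("F2_a", "F2", false_types, shifted(base_false, [-0.02, 0.03, 0.01])),
        rec("F3_a", "F3", false_types, shifted(base_false, [0.0, -0.05, 0.02])),
        rec("F4_a", "F4", false_types, shifted(base_false, [0.03, 0.02, -0.04])),
        # unlabeled sequence adopting the true geometry and chemistry
        rec("U1_a", "U1", true_types, shifted(base_true, [0.01, 0.03, 0.02])),
        # remote outlier: unknown label, zero votes end to end
        rec("X1_a", "X1", out_types, base_out),
        # dropped: gap at column 3
        rec("B1_a", "B1", true_types, shifted(base_true, [0.0, 0.0, 0.1]), skip_col=3),
    ]
    msa = {
        "T1": true_types, "T2": true_types, "T3": true_types, "T4": true_types,
        "F1": false_types, "F2": false_types, "F3": false_types, "F4": false_types,
        "U1": true_types, "X1": out_types,
        "B1": true_types[:3] + "-" + true_types[4],
    }
    families = {
        "T1": "TK", "T2": "TK", "T3": "AGC", "T4": "AGC",
        "F1": "CMGC", "F2": "CMGC", "F3": "CK1", "F4": "STE",
        "U1": "CAMK", "X1": "Other", "B1": "TK",
    }
    sset = build_structure_set(records, msa, [0, 1, 2, 3, 4], families)
    labels = LabelTable(
        entries={
            ("T1", "example-inhibitor"): True,
            ("T2", "example-inhibitor"): True,
            ("T3", "example-inhibitor"): True,
            ("T4", "example-inhibitor"): True,
            ("F1", "example-inhibitor"): False,
            ("F2", "example-inhibitor"): False,
            ("F3", "example-inhibitor"): False,
            ("F4", "example-inhibitor"): False,
        },
        family=families,
    )
    return sset, labels


# ---------------------------------------------------------------------------
# file emission (the formats the reader consumes)


def write_dataset(
    sset: AlignedStructureSet, labels: LabelTable, outdir: str | Path
) -> dict[str, Path]:
    """Emit site table CSV, aligned FASTA, label CSV and family CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / "site_table.csv",
        "alignment": outdir / "alignment.fasta",
        "labels": outdir / "labels.csv",
        "families": outdir / "families.csv",
    }
    write_site_table(sset, paths["sites"])
    aligned = sset.aligned_sequences()
    with open(paths["alignment"], "w") as fh:
        for seq in sorted(aligned):
            fh.write(f">{seq}\n{aligned[seq]}\n")
    with open(paths["labels"], "w") as fh:
        fh.write("sequence_id,compound_id,label\n")
        for (seq, comp), lab in sorted(labels.entries.items()):
            fh.write(f"{seq},{comp},{'true' if lab else 'false'}\n")
    with open(paths["families"], "w") as fh:
        fh.write("sequence_id,family\n")
        fam = dict(sset.family_map())
        fam.update(labels.family)
        for seq in sorted(fam):
            if fam[seq] is not None:
                fh.write(f"{seq},{fam[seq]}\n")
    return paths
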