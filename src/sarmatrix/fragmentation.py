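"""Systematic exocyclic single-bond fragmentation.

Compounds are cut at one, two, or three exocyclic single bonds
(single-/dual-/triple-cut) in the style of the Hussain-Rea matched
molecular pair indexing scheme: every qualifying cut set yields a *key*
(the core fragment, carrying all attachment points) and one *value*
(substituent) fragment per attachment point.  Keys and values are stored
canonically so that identical cores match by string equality across
compounds, which is what makes large-scale MMP and matched-series
detection a dictionary lookup.

Attachment points are dummy atoms with atom map numbers ``1..level``;
``values[i]`` binds at attachment point ``i+1``.  Cutting never touches
hydrogens, ring bonds, or bonds of order greater than one.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdkit import Chem

from .chem_io import CompoundRecord, CompoundSet

logger = logging.getLogger(__name__)


class FragmentError(ValueError):
    pass


@dataclass(frozen=True)
class FragmentationConstraints:
    """Size filters applied to candidate (key, values) decompositions.

    max_value_heavy_atoms: largest substituent fragment admitted.
    min_key_heavy_atoms: smallest admissible core.
    key_must_be_larger: require the core to contain at least half of the
        parent's heavy atoms (the core is the "larger" fragment; values
        are the "smaller" substituents).
    """

    max_value_heavy_atoms: int = 13
    min_key_heavy_atoms: int = 5
    key_must_be_larger: bool = True

    def __post_init__(self) -> None:
        if self.max_value_heavy_atoms <= 0 or self.min_key_heavy_atoms <= 0:
            raise ValueError("constraint thresholds must be positive")


#: fully permissive constraints, used by oracles and small examples
PERMISSIVE = FragmentationConstraints(
    max_value_heavy_atoms=10**6, min_key_heavy_atoms=1, key_must_be_larger=False
)


@dataclass(frozen=True)
class Fragmentation:
    """One cut result: a core (key) plus ordered substituents (values).

    ``key_atoms`` / ``value_atoms`` hold the parent-molecule atom indices
    of each fragment, which lets an independent enumeration oracle check
    the engine cut-by-cut.
    """

    compound_id: str
    level: int
    key: str
    values: tuple[str, ...]
    cut_bonds: tuple[int, ...] = ()
    key_atoms: frozenset[int] = frozenset()
    value_atoms: tuple[frozenset[int], ...] = ()


def cuttable_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of exocyclic single bonds between two heavy atoms."""
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]


def heavy_atoms(fragment: Chem.Mol) -> int:
    """Heavy-atom count ignoring attachment-point dummies."""
    return sum(1 for a in fragment.GetAtoms() if a.GetAtomicNum() > 1)


def _attachment_maps(fragment: Chem.Mol) -> list[int]:
    return sorted(
        a.GetAtomMapNum() for a in fragment.GetAtoms() if a.GetAtomicNum() == 0
    )


def _split_on_bonds(
    mol: Chem.Mol, bond_ids: Sequence[int], first_label: int = 1
) -> list[tuple[Chem.Mol, frozenset[int]]]:
    """Cut ``bond_ids`` and return (piece, parent-atom-index set) pairs.

    The dummy atom replacing bond ``bond_ids[i]`` carries atom map number
    ``first_label + i`` on both sides of the cut.  Attachment points the
    input molecule already had (e.g. when splitting a core fragment)
    keep their labels untouched.
    """
    n_parent = mol.GetNumAtoms()
    frag = Chem.FragmentOnBonds(
        mol, list(bond_ids), addDummies=True,
        dummyLabels=[(first_label + i, first_label + i)
                     for i in range(len(bond_ids))],
    )
    # FragmentOnBonds encodes the label as an isotope; move it to the atom
    # map number, the convention used throughout this package.  Only the
    # freshly added dummies carry a non-zero isotope.
    for atom in frag.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope() > 0:
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)
    mapping: list[tuple[int, ...]] = []
    pieces = Chem.GetMolFrags(frag, asMols=True, sanitizeFrags=True,
                              fragsMolAtomMapping=mapping)
    out = []
    for piece, atom_ids in zip(pieces, mapping):
        # original atoms keep their parent indices; appended dummies do not
        out.append((piece, frozenset(i for i in atom_ids if i < n_parent)))
    return out


def canonical_fragment(fragment: str | Chem.Mol) -> tuple[str, tuple[int, ...]]:
    """Canonicalize a fragment string with labeled attachment points.

    Returns ``(canonical_smiles, perm)`` where ``perm[i]`` is the new
    label assigned to old label ``i + 1``.  For a single attachment point
    the label is forced to 1.  For multi-point keys the labels are
    renumbered so that the canonical SMILES is the lexicographically
    smallest over all label permutations, making the output invariant to
    both input atom order and input label assignment; callers re-order
    the associated values with ``perm``.
    """
    mol = Chem.MolFromSmiles(fragment) if isinstance(fragment, str) else fragment
    if mol is None:
        raise FragmentError(f"unparsable fragment {fragment!r}")
    points = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if not points:
        raise FragmentError("fragment has no attachment point")
    if len(points) == 1:
        points[0].SetAtomMapNum(1)
        return Chem.MolToSmiles(mol), (1,)

    old_labels = sorted(a.GetAtomMapNum() for a in points)
    best: tuple[str, tuple[int, ...]] | None = None
    for new_labels in itertools.permutations(range(1, len(points) + 1)):
        relabel = dict(zip(old_labels, new_labels))
        work = Chem.Mol(mol)
        for a in work.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(relabel[a.GetAtomMapNum()])
        smi = Chem.MolToSmiles(work)
        cand = (smi, new_labels)
        if best is None or cand < best:
            best = cand
    assert best is not None
    return best[0], best[1]


def reassemble(key: str, values: Sequence[str]) -> str:
    """Join a key and its values at matching attachment points.

    ``values[i]`` is bonded at the key's attachment point ``i + 1``.
    Labeled attachment points of the key with no corresponding value
    would be an arity error.  The result is a canonical structure string,
    so this doubles as the round-trip oracle for fragmentation and as the
    virtual-compound generator for matrix cells.
    """
    key_mol = Chem.MolFromSmiles(key)
    if key_mol is None:
        raise FragmentError(f"unparsable key {key!r}")
    n_points = sum(1 for a in key_mol.GetAtoms() if a.GetAtomicNum() == 0)
    if n_points != len(values):
        raise FragmentError(
            f"key has {n_points} attachment points but {len(values)} values given"
        )
    combined = key_mol
    for i, value in enumerate(values):
        vmol = Chem.MolFromSmiles(value)
        if vmol is None:
            raise FragmentError(f"unparsable value {value!r}")
        dummies = [a for a in vmol.GetAtoms() if a.GetAtomicNum() == 0]
        if len(dummies) != 1:
            raise FragmentError(
                f"value {value!r} must carry exactly one attachment point"
            )
        dummies[0].SetAtomMapNum(i + 1)
        combined = Chem.CombineMols(combined, vmol)
    zipped = Chem.molzip(combined)
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


def enumerate_fragmentations(
    compound: CompoundRecord,
    level: int,
    constraints: FragmentationConstraints = FragmentationConstraints(),
) -> list[Fragmentation]:
    """All qualifying ``level``-cut fragmentations of one compound.

    Every ``level``-subset of exocyclic single bonds is tried.  A cut set
    is retained only if exactly one resulting fragment (the key) carries
    all attachment points; the remaining fragments each carry one and
    become the values, ordered by attachment-point index.  For a single
    cut both fragments carry the single attachment point, so the key is
    whichever fragment is at least as large as the other (a tie emits
    both orientations).  ``constraints`` are applied afterwards as plain
    size filters.

    Molecules with no cuttable bond yield an empty list.  Symmetry can
    make distinct cut sets produce identical canonical (key, values)
    pairs; those duplicates are preserved here (each reports its own cut
    bonds) and collapsed in :func:`build_index`.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2, or 3 (got {level})")
    mol = Chem.MolFromSmiles(compound.structure)
    if mol is None:
        raise FragmentError(f"unparsable structure for {compound.compound_id}")
    n_heavy = mol.GetNumAtoms()
    if n_heavy < 2:
        raise FragmentError("compound must have at least 2 heavy atoms")
    bonds = cuttable_bonds(mol)
    results: list[Fragmentation] = []
    for combo in itertools.combinations(bonds, level):
        pieces = _split_on_bonds(mol, combo)
        want = list(range(1, level + 1))
        key_candidates = [i for i, (p, _) in enumerate(pieces)
                          if _attachment_maps(p) == want]
        if level == 1 and len(key_candidates) == 2:
            # both halves qualify structurally; key is the larger half
            a, b = pieces[0][0], pieces[1][0]
            ha, hb = heavy_atoms(a), heavy_atoms(b)
            if ha > hb:
                key_candidates = [0]
            elif hb > ha:
                key_candidates = [1]
            # exact tie: keep both orientations
        for ki in key_candidates:
            key_piece, key_atom_ids = pieces[ki]
            value_pieces = [pieces[i] for i in range(len(pieces)) if i != ki]
            if len(value_pieces) != level or any(
                len(_attachment_maps(p)) != 1 for p, _ in value_pieces
            ):
                continue
            frag = _qualify(compound.compound_id, level, n_heavy, combo,
                            key_piece, key_atom_ids, value_pieces, constraints)
            if frag is not None:
                results.append(frag)
    return results


def _qualify(
    compound_id: str,
    level: int,
    n_heavy: int,
    cut_bonds: Sequence[int],
    key_piece: Chem.Mol,
    key_atom_ids: frozenset[int],
    value_pieces: Sequence[tuple[Chem.Mol, frozenset[int]]],
    constraints: FragmentationConstraints,
) -> Fragmentation | None:
    """Apply size constraints and canonicalize one candidate cut."""
    n_key = heavy_atoms(key_piece)
    if n_key < constraints.min_key_heavy_atoms:
        return None
    if constraints.key_must_be_larger and 2 * n_key < n_heavy:
        return None
    if any(heavy_atoms(p) > constraints.max_value_heavy_atoms
           for p, _ in value_pieces):
        return None

    key_smiles, perm = canonical_fragment(key_piece)
    # by-label lookup of the value fragments, then re-order under perm
    by_label: dict[int, tuple[str, frozenset[int]]] = {}
    for piece, atom_ids in value_pieces:
        label = _attachment_maps(piece)[0]
        smi, _ = canonical_fragment(piece)
        by_label[label] = (smi, atom_ids)
    ordered_values: list[str] = [""] * level
    ordered_atoms: list[frozenset[int]] = [frozenset()] * level
    for old_label, (smi, atom_ids) in by_label.items():
        new_label = perm[old_label - 1]
        ordered_values[new_label - 1] = smi
        ordered_atoms[new_label - 1] = atom_ids
    return Fragmentation(
        compound_id=compound_id,
        level=level,
        key=key_smiles,
        values=tuple(ordered_values),
        cut_bonds=tuple(cut_bonds),
        key_atoms=key_atom_ids,
        value_atoms=tuple(ordered_atoms),
    )


@dataclass
class FragmentIndex:
    """Key -> [(values, compound_id)] table for one cut level."""

    level: int
    constraints: FragmentationConstraints
    entries: dict[str, list[tuple[tuple[str, ...], str]]] = field(default_factory=dict)

    def add(self, frag: Fragmentation) -> bool:
        """Insert a fragmentation; returns False for an exact duplicate
        (same key, values, and compound — e.g. symmetric cut sets)."""
        rows = self.entries.setdefault(frag.key, [])
        row = (frag.values, frag.compound_id)
        if row in rows:
            return False
        rows.append(row)
        return True

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def build_index(
    cset: CompoundSet,
    levels: Iterable[int] = (1, 2, 3),
    constraints: FragmentationConstraints = FragmentationConstraints(),
) -> dict[int, FragmentIndex]:
    """Fragment every compound of a set at each requested level.

    Output ordering is deterministic for a given input ordering: entries
    appear in (compound, enumeration) order under each key.
    """
    if len(cset) == 0:
        raise ValueError("cannot index an empty compound set")
    levels = sorted(set(levels))
    if not levels:
        logger.warning("build_index called with no levels; empty result")
        return {}
    indexes = {lvl: FragmentIndex(level=lvl, constraints=constraints)
               for lvl in levels}
    for rec in cset:
        for lvl in levels:
            for frag in enumerate_fragmentations(rec, lvl, constraints):
                indexes[lvl].add(frag)
    for lvl in levels:
        logger.info("level %d: %d index rows under %d keys",
                    lvl, len(indexes[lvl]), len(indexes[lvl].entries))
    return indexes


def write_index_tsv(indexes: dict[int, FragmentIndex], path) -> None:
    """Serialize fragment indexes as TSV: level, key, value_1..3, compound_id."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("level\tkey\tvalue_1\tvalue_2\tvalue_3\tcompound_id\n")
        for lvl in sorted(indexes):
            index = indexes[lvl]
            for key in sorted(index.entries):
                for values, cid in index.entries[key]:
                    padded = list(values) + [""] * (3 - len(values))
                    fh.write(f"{lvl}\t{key}\t{padded[0]}\t{padded[1]}\t{padded[2]}\t{cid}\n")
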