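"""Compound structure and activity I/O.

Every module in :mod:`sarmatrix` compares molecules by string equality of
their canonical isomeric SMILES.  This module owns that canonicalization
contract and the two standard inputs: structure files (``.smi`` /
``.sdf``) and long-format activity tables (``compound_id, target_id,
pKi``).  Potencies are pKi values (negative decadic log of the inhibition
constant); replicate measurements for the same (compound, target) pair
are aggregated by arithmetic mean on this log scale, consistent with the
logarithmic additivity used for potency prediction downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty on mildly malformed records; parse errors are reported
# through our own warnings instead.
RDLogger.DisableLog("rdApp.error")
RDLogger.DisableLog("rdApp.warning")


class StructureError(ValueError):
    """Raised when a line-notation string cannot be parsed as a molecule."""


def canonical_structure(text: str, *, keep_largest_fragment: bool = True) -> str:
    """Return the canonical isomeric SMILES for ``text``.

    The output is idempotent (canonicalizing a canonical string returns it
    unchanged) and invariant to input atom ordering, so downstream cell
    identity ("each cell represents a unique compound") is decidable by
    plain string equality.

    Multi-fragment inputs (salts, mixtures) are reduced to their largest
    fragment by heavy-atom count with a warning, because fragmentation
    assumes one connected molecule.  Set ``keep_largest_fragment=False``
    to make such inputs an error instead.
    """
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise StructureError(f"unparsable structure: {text!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        if not keep_largest_fragment:
            raise StructureError(f"multi-fragment structure: {text!r}")
        mol = max(frags, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))
        logger.warning("kept largest fragment of multi-fragment input %r", text)
    if mol.GetNumHeavyAtoms() == 0:
        raise StructureError(f"no heavy atoms in structure: {text!r}")
    return Chem.MolToSmiles(mol)


@dataclass
class CompoundRecord:
    """One compound: an opaque id, a canonical structure, and pKi values.

    ``activities`` maps target_id -> mean pKi over all values recorded so
    far; :meth:`add_activity` maintains the running mean so replicate rows
    and later merges aggregate correctly.
    """

    compound_id: str
    structure: str
    aliases: list[str] = field(default_factory=list)
    _acc: dict[str, tuple[float, int]] = field(default_factory=dict, repr=False)

    @property
    def activities(self) -> dict[str, float]:
        return {t: s / n for t, (s, n) in self._acc.items()}

    def add_activity(self, target_id: str, pki: float) -> None:
        pki = float(pki)
        if not pki == pki or pki in (float("inf"), float("-inf")):
            raise ValueError(f"non-finite pKi for {self.compound_id}/{target_id}")
        s, n = self._acc.get(target_id, (0.0, 0))
        self._acc[target_id] = (s + pki, n + 1)

    def merge_from(self, other: "CompoundRecord") -> None:
        """Fold another record for the same structure into this one."""
        self.aliases.append(other.compound_id)
        self.aliases.extend(other.aliases)
        for t, (s, n) in other._acc.items():
            s0, n0 = self._acc.get(t, (0.0, 0))
            self._acc[t] = (s0 + s, n0 + n)


class CompoundSet:
    """Ordered collection of :class:`CompoundRecord` with two uniqueness
    guarantees: no two records share a ``compound_id`` and no two records
    share a canonical structure (structural duplicates are merged, the
    first id becoming primary)."""

    def __init__(self, provenance: str = "") -> None:
        self.provenance = provenance
        self._records: list[CompoundRecord] = []
        self.by_id: dict[str, CompoundRecord] = {}
        self.by_structure: dict[str, CompoundRecord] = {}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self._records)

    @property
    def records(self) -> Sequence[CompoundRecord]:
        return tuple(self._records)

    def add(self, record: CompoundRecord) -> CompoundRecord:
        """Add a record, merging it into an existing one if the canonical
        structure is already present.  Returns the surviving record."""
        if record.compound_id in self.by_id:
            raise ValueError(f"duplicate compound_id {record.compound_id!r}")
        existing = self.by_structure.get(record.structure)
        if existing is not None:
            logger.warning(
                "structure of %s duplicates %s; merging activities",
                record.compound_id, existing.compound_id,
            )
            existing.merge_from(record)
            self.by_id[record.compound_id] = existing
            return existing
        self._records.append(record)
        self.by_id[record.compound_id] = record
        self.by_structure[record.structure] = record
        return record

    def targets(self) -> list[str]:
        """Sorted union of target ids annotated on any record."""
        seen: set[str] = set()
        for rec in self._records:
            seen.update(rec.activities)
        return sorted(seen)


def parse_compounds(
    path: str | Path,
    fmt: str | None = None,
    *,
    id_property: str = "_Name",
    activity_properties: Mapping[str, str] | None = None,
) -> CompoundSet:
    """Read a ``.smi`` or ``.sdf`` file into a :class:`CompoundSet`.

    ``.smi`` is one record per line, ``SMILES<TAB>ID`` (any whitespace
    accepted; a missing id is auto-generated from the line number).
    For SDF, ``activity_properties`` optionally maps target_id -> SD
    property name holding a pKi.  Unreadable records are skipped with a
    warning; a file with no readable record at all is an error.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "smi"
    fmt = fmt.lower()
    cset = CompoundSet(provenance=str(path))
    n_read = n_skipped = 0

    if fmt in ("smi", "smiles", "ism"):
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smiles = parts[0]
                cid = parts[1] if len(parts) > 1 else f"line{lineno}"
                try:
                    structure = canonical_structure(smiles)
                except StructureError:
                    logger.warning("%s line %d: unreadable SMILES %r", path, lineno, smiles)
                    n_skipped += 1
                    continue
                cset.add(CompoundRecord(cid, structure))
                n_read += 1
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                logger.warning("%s record %d: unreadable molfile", path, i)
                n_skipped += 1
                continue
            cid = (mol.GetProp(id_property)
                   if mol.HasProp(id_property) and mol.GetProp(id_property)
                   else f"record{i}")
            rec = CompoundRecord(cid, canonical_structure(Chem.MolToSmiles(mol)))
            rec = cset.add(rec)
            for target_id, prop in (activity_properties or {}).items():
                if mol.HasProp(prop):
                    try:
                        rec.add_activity(target_id, float(mol.GetProp(prop)))
                    except ValueError:
                        logger.warning("%s record %d: bad %s value", path, i, prop)
            n_read += 1
    else:
        raise ValueError(f"unknown format {fmt!r} (expected smi or sdf)")

    logger.info("%s: parsed %d records, skipped %d", path, n_read, n_skipped)
    if n_read == 0:
        raise StructureError(f"no readable records in {path}")
    return cset


def write_smiles(cset: CompoundSet, path: str | Path) -> None:
    """Write a CompoundSet as a tab-separated ``.smi`` file."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in cset:
            fh.write(f"{rec.structure}\t{rec.compound_id}\n")


def write_activities(cset: CompoundSet, path: str | Path) -> None:
    """Write all annotations as a long-format CSV (compound_id,target_id,pKi)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", "target_id", "pKi"])
        for rec in cset:
            for target_id in sorted(rec.activities):
                writer.writerow([rec.compound_id, target_id,
                                 repr(rec.activities[target_id])])


def attach_activities(
    cset: CompoundSet,
    table: str | Path | Iterable[Mapping[str, object]],
) -> CompoundSet:
    """Merge activity rows onto a CompoundSet (in place; returns it).

    ``table`` is either a CSV path with header columns
    ``compound_id,target_id,pKi`` or an iterable of mappings with those
    keys.  Replicates aggregate by arithmetic mean of pKi.  Rows with a
    non-numeric pKi or an unknown compound_id are reported and dropped.
    """
    if isinstance(table, (str, Path)):
        with open(table, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
        missing = {"compound_id", "target_id", "pKi"} - set(rows[0] if rows else {})
        if missing:
            raise ValueError(f"activity table missing columns: {sorted(missing)}")
    else:
        rows = list(table)

    n_unknown = n_bad = 0
    for row in rows:
        cid = str(row["compound_id"])
        target = str(row["target_id"])
        rec = cset.by_id.get(cid)
        if rec is None:
            n_unknown += 1
            logger.warning("activity row references unknown compound %r", cid)
            continue
        try:
            rec.add_activity(target, float(row["pKi"]))  # type: ignore[arg-type]
        except (TypeError, ValueError):
            n_bad += 1
            logger.warning("rejected non-numeric pKi %r for %s/%s",
                           row["pKi"], cid, target)
    if n_unknown or n_bad:
        logger.info("attach_activities: %d unknown-id rows, %d rejected rows",
                    n_unknown, n_bad)
    return cset
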