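"""Compound series matrices (CSMs) over multi-target activity spaces.

A CSM shares the structural skeleton of a SAR matrix — analogous cores
as rows, substituent combinations as columns, real and virtual cells —
but each real cell carries the *target profile* of its compound: the set
of targets it is annotated active against (optionally requiring a
minimum pKi).  The cell's promiscuity degree is the profile size, the
quantity color-coded when CSMs are rendered.  A CSM deconvolutes into
one single-target SARM per target with the identical skeleton; cells
whose compound has no annotation for that target stay real but gray.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem_io import CompoundSet
from .matrices import REAL, VIRTUAL, Cell, SARM, _assemble
from .series import AMMS

logger = logging.getLogger(__name__)


@dataclass
class CsmCell:
    status: str
    structure: str
    compound_id: str | None = None
    target_profile: frozenset[str] = frozenset()
    activities: dict[str, float] = field(default_factory=dict)

    @property
    def is_real(self) -> bool:
        return self.status == REAL


@dataclass
class CSM:
    matrix_id: str
    amms_id: str
    level: int
    second_level_key: str
    activity_threshold: float | None
    rows: tuple[str, ...]
    columns: tuple[tuple[str, ...], ...]
    cells: dict[tuple[int, int], CsmCell] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def iter_cells(self) -> Iterable[tuple[int, int, CsmCell]]:
        for ri in range(self.n_rows):
            for ci in range(self.n_columns):
                yield ri, ci, self.cells[(ri, ci)]

    @property
    def n_real(self) -> int:
        return sum(1 for _, _, c in self.iter_cells() if c.is_real)

    @property
    def targets(self) -> list[str]:
        """Sorted union of per-cell target profiles."""
        seen: set[str] = set()
        for _, _, cell in self.iter_cells():
            seen.update(cell.target_profile)
        return sorted(seen)

    def summary(self) -> dict:
        """Matrix composition and target profile, as displayed in a CSM
        header: dimensions, real-cell count, targets covered, and the
        per-target compound counts."""
        per_target = {
            t: sum(1 for _, _, c in self.iter_cells()
                   if t in c.target_profile)
            for t in self.targets
        }
        return {
            "matrix_id": self.matrix_id,
            "n_rows": self.n_rows,
            "n_columns": self.n_columns,
            "n_real": self.n_real,
            "n_targets": len(per_target),
            "per_target_compounds": per_target,
        }


def promiscuity_degree(cell: CsmCell) -> int | None:
    """Number of targets the cell's compound is active against; 0 for an
    unannotated real cell, ``None`` (undefined) for a virtual cell."""
    if not cell.is_real:
        return None
    return len(cell.target_profile)


def build_csm(
    amms_list: Sequence[AMMS],
    cset: CompoundSet,
    activity_threshold: float | None = None,
    min_rows: int = 2,
    min_real: int = 3,
) -> list[CSM]:
    """Build one CSM per A_MMS over the full multi-target annotation.

    ``activity_threshold`` restricts "active against" to targets with
    pKi at or above the threshold; by default mere presence of an
    annotation counts.  Requires at least two distinct targets — for a
    single target a potency-colored SARM is the right object.
    """
    targets = cset.targets()
    if len(targets) < 2:
        raise ValueError(
            f"CSMs need >= 2 targets (found {targets}); use build_sarms "
            "for single-target data"
        )
    out: list[CSM] = []
    for amms in amms_list:
        skeleton = _assemble(amms, cset, target_id=None)
        if skeleton.n_rows < min_rows or skeleton.n_real < min_real:
            continue
        csm = CSM(
            matrix_id=f"{amms.amms_id}:CSM",
            amms_id=amms.amms_id,
            level=amms.level,
            second_level_key=amms.second_level_key,
            activity_threshold=activity_threshold,
            rows=skeleton.rows,
            columns=skeleton.columns,
        )
        for (ri, ci), cell in skeleton.cells.items():
            if cell.is_real:
                acts = dict(cset.by_id[cell.compound_id].activities)
                profile = frozenset(
                    t for t, p in acts.items()
                    if activity_threshold is None or p >= activity_threshold
                )
                csm.cells[(ri, ci)] = CsmCell(
                    status=REAL, structure=cell.structure,
                    compound_id=cell.compound_id,
                    target_profile=profile, activities=acts,
                )
            else:
                csm.cells[(ri, ci)] = CsmCell(status=VIRTUAL,
                                              structure=cell.structure)
        out.append(csm)
    logger.info("built %d CSMs over %d targets", len(out), len(targets))
    return out


def deconvolute_csm(csm: CSM) -> dict[str, SARM]:
    """Split a CSM into single-target SARMs with the identical skeleton.

    For each target in the CSM's profile union, every real cell keeps its
    compound; the pKi is attached only where the target is in the cell's
    profile (threshold semantics preserved), otherwise the cell is real
    but unannotated (gray).  Virtual cells stay virtual.
    """
    out: dict[str, SARM] = {}
    for target in csm.targets:
        sarm = SARM(
            matrix_id=f"{csm.amms_id}:{target}",
            amms_id=csm.amms_id,
            level=csm.level,
            target_id=target,
            second_level_key=csm.second_level_key,
            rows=csm.rows,
            columns=csm.columns,
        )
        for (ri, ci), cell in csm.cells.items():
            if cell.is_real:
                pki = cell.activities.get(target) if target in cell.target_profile else None
                sarm.cells[(ri, ci)] = Cell(
                    status=REAL, structure=cell.structure,
                    compound_id=cell.compound_id, pki=pki,
                )
            else:
                sarm.cells[(ri, ci)] = Cell(status=VIRTUAL,
                                            structure=cell.structure)
        out[target] = sarm
    return out


def rebuild_profiles(sarms: dict[str, SARM]) -> dict[tuple[int, int], frozenset[str]]:
    """Recover per-cell target profiles from deconvoluted SARMs (the
    inverse check of :func:`deconvolute_csm`)."""
    profiles: dict[tuple[int, int], set[str]] = {}
    for target, sarm in sarms.items():
        for (ri, ci), cell in sarm.cells.items():
            if cell.annotated:
                profiles.setdefault((ri, ci), set()).add(target)
    return {k: frozenset(v) for k, v in profiles.items()}


def skeleton_hash(rows: Sequence[str], columns: Sequence[Sequence[str]],
                  real_cells: Iterable[tuple[int, int]]) -> str:
    """Stable digest of (rows, columns, real/virtual pattern), shared by a
    CSM and its deconvoluted SARMs for cross-checking exports."""
    payload = json.dumps(
        [list(rows), [list(c) for c in columns], sorted(real_cells)],
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()


def csm_to_dict(csm: CSM) -> dict:
    return {
        "matrix_id": csm.matrix_id,
        "amms_id": csm.amms_id,
        "level": csm.level,
        "second_level_key": csm.second_level_key,
        "activity_threshold": csm.activity_threshold,
        "rows": list(csm.rows),
        "columns": [list(c) for c in csm.columns],
        "skeleton_hash": skeleton_hash(
            csm.rows, csm.columns,
            [(r, c) for r, c, cell in csm.iter_cells() if cell.is_real],
        ),
        "cells": [
            {
                "row": ri, "column": ci, "status": cell.status,
                "structure": cell.structure,
                "compound_id": cell.compound_id,
                "target_profile": sorted(cell.target_profile),
                "activities": {t: cell.activities[t]
                               for t in sorted(cell.activities)},
            }
            for ri, ci, cell in csm.iter_cells()
        ],
        "summary": csm.summary(),
    }


def csm_from_dict(data: dict) -> CSM:
    csm = CSM(
        matrix_id=data["matrix_id"], amms_id=data["amms_id"],
        level=data["level"], second_level_key=data["second_level_key"],
        activity_threshold=data["activity_threshold"],
        rows=tuple(data["rows"]),
        columns=tuple(tuple(c) for c in data["columns"]),
    )
    for c in data["cells"]:
        csm.cells[(c["row"], c["column"])] = CsmCell(
            status=c["status"], structure=c["structure"],
            compound_id=c["compound_id"],
            target_profile=frozenset(c["target_profile"]),
            activities=dict(c["activities"]),
        )
    return csm


def write_csms_json(csms: Sequence[CSM], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([csm_to_dict(c) for c in csms], fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_csms_json(path) -> list[CSM]:
    with open(path, encoding="utf-8") as fh:
        return [csm_from_dict(d) for d in json.load(fh)]
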