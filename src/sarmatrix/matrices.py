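"""SAR matrix construction and the overlap/coverage statistics.

Each A_MMS becomes one SAR matrix (SARM): structurally analogous cores
as rows, substituent combinations (the union over all member series) as
columns.  Every (row, column) cell corresponds to a unique compound —
either *real* (present in the data set, potency-annotated where a pKi is
known for the chosen target) or *virtual* (an unexplored core/substituent
combination whose structure is generated by reassembly).  Virtual cells
are the design candidates; the union of virtual structures over all
matrices is the data set's chemical space envelope.

Two per-matrix statistics describe how the analog series relate:

* row overlap of a column, ``RO = (n_col - 1) / (#rows - 1)`` where
  ``n_col`` counts the real compounds in the column — 0 means the
  substituent occurs in a single series, 1 in every series; matrix
  overlap is the mean of RO over columns.
* coverage ``C = n_matrix / (#rows * #columns)``, the proportion of
  cells populated with real compounds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .chem_io import CompoundSet
from .fragmentation import reassemble
from .series import AMMS

logger = logging.getLogger(__name__)

REAL = "real"
VIRTUAL = "virtual"


@dataclass
class Cell:
    """One matrix cell.  Real cells carry a compound id and, when the
    compound is annotated for the matrix's target, a pKi; virtual cells
    carry only the reassembled structure."""

    status: str
    structure: str
    compound_id: str | None = None
    pki: float | None = None
    known_elsewhere: bool = False

    @property
    def is_real(self) -> bool:
        return self.status == REAL

    @property
    def annotated(self) -> bool:
        return self.status == REAL and self.pki is not None


@dataclass
class SARM:
    """A SAR matrix: cores x substituent combinations with one activity
    column (``target_id``).  ``columns[j]`` is the ordered tuple of value
    fragments bound at attachment points 1..level."""

    matrix_id: str
    amms_id: str
    level: int
    target_id: str
    second_level_key: str
    rows: tuple[str, ...]
    columns: tuple[tuple[str, ...], ...]
    cells: dict[tuple[int, int], Cell] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def cell(self, ri: int, ci: int) -> Cell:
        return self.cells[(ri, ci)]

    def iter_cells(self) -> Iterable[tuple[int, int, Cell]]:
        for ri in range(self.n_rows):
            for ci in range(self.n_columns):
                yield ri, ci, self.cells[(ri, ci)]

    def real_cells(self) -> list[tuple[int, int, Cell]]:
        return [(r, c, cell) for r, c, cell in self.iter_cells() if cell.is_real]

    def virtual_cells(self) -> list[tuple[int, int, Cell]]:
        return [(r, c, cell) for r, c, cell in self.iter_cells()
                if not cell.is_real]

    @property
    def n_real(self) -> int:
        return len(self.real_cells())


@dataclass(frozen=True)
class MatrixStats:
    """Overlap/coverage summary of one matrix."""

    matrix_id: str
    n_rows: int
    n_columns: int
    n_matrix: int                  # real cells
    row_overlaps: tuple[float, ...]
    matrix_overlap: float
    coverage: float
    n_col: tuple[int, ...]         # real compounds per column


def build_sarms(
    amms_list: Sequence[AMMS],
    cset: CompoundSet,
    target_id: str,
    min_rows: int = 2,
    min_real: int = 3,
) -> list[SARM]:
    """Turn each A_MMS into a SARM for one activity column.

    Rows are ordered by canonical core string and columns by canonical
    value combination, so the layout is deterministic and diffable.
    Matrices with fewer than ``min_rows`` rows or ``min_real`` real cells
    are dropped.  Real compounds lacking a pKi for ``target_id`` stay
    real but unannotated (rendered gray on export), they are not demoted
    to virtual.
    """
    available = cset.targets()
    if target_id not in available:
        raise ValueError(
            f"unknown target {target_id!r}; available targets: {available}"
        )
    out: list[SARM] = []
    for amms in amms_list:
        sarm = _assemble(amms, cset, target_id)
        if sarm.n_rows < min_rows or sarm.n_real < min_real:
            continue
        out.append(sarm)
    logger.info("built %d matrices for target %s (of %d A_MMS)",
                len(out), target_id, len(amms_list))
    return out


def _assemble(amms: AMMS, cset: CompoundSet, target_id: str | None) -> SARM:
    """Lay out one A_MMS as a matrix; shared by SARM and CSM builders."""
    rows = tuple(sorted({e.core for e in amms.entries}))
    col_set: set[tuple[str, ...]] = set()
    placements: dict[tuple[str, tuple[str, ...]], str] = {}
    for entry in amms.entries:
        for member in entry.series.members:
            col_set.add(member.values)
            placements[(entry.core, member.values)] = member.compound_id
    columns = tuple(sorted(col_set))
    sarm = SARM(
        matrix_id=f"{amms.amms_id}" + (f":{target_id}" if target_id else ""),
        amms_id=amms.amms_id,
        level=amms.level,
        target_id=target_id or "",
        second_level_key=amms.second_level_key,
        rows=rows,
        columns=columns,
    )
    for ri, core in enumerate(rows):
        for ci, values in enumerate(columns):
            cid = placements.get((core, values))
            if cid is not None:
                rec = cset.by_id[cid]
                pki = rec.activities.get(target_id) if target_id else None
                cell = Cell(status=REAL, structure=rec.structure,
                            compound_id=rec.compound_id, pki=pki)
            else:
                cell = Cell(status=VIRTUAL,
                            structure=reassemble(core, list(values)))
            sarm.cells[(ri, ci)] = cell
    return sarm


def enumerate_virtuals(
    sarm: SARM, cset: CompoundSet | None = None
) -> list[tuple[int, int, Cell]]:
    """All virtual cells of a matrix, with generated structures.

    When ``cset`` is given, virtual structures that match a real data-set
    compound elsewhere (i.e. the compound exists but fell outside this
    matrix's series) are flagged ``known_elsewhere``; they remain virtual
    in this matrix.
    """
    virtuals = sarm.virtual_cells()
    if cset is not None:
        for _, _, cell in virtuals:
            cell.known_elsewhere = cell.structure in cset.by_structure
    return virtuals


def row_overlap(sarm: SARM, column: int) -> float:
    """RO = (n_col - 1) / (#rows - 1) for one column: 0 when the column's
    substituent occurs in a single row, 1 when it occurs in every row."""
    if sarm.n_rows < 2:
        raise ValueError("row overlap is undefined for a single-row matrix")
    n_col = sum(1 for ri in range(sarm.n_rows)
                if sarm.cells[(ri, column)].is_real)
    return (n_col - 1) / (sarm.n_rows - 1)


def matrix_overlap(sarm: SARM) -> float:
    """Mean row overlap over all columns."""
    ros = [row_overlap(sarm, ci) for ci in range(sarm.n_columns)]
    return sum(ros) / len(ros)


def matrix_coverage(sarm: SARM) -> float:
    """C = n_matrix / (#rows * #columns), the real-cell proportion."""
    return sarm.n_real / (sarm.n_rows * sarm.n_columns)


def matrix_stats(sarm: SARM) -> MatrixStats:
    ros = tuple(row_overlap(sarm, ci) for ci in range(sarm.n_columns))
    n_col = tuple(
        sum(1 for ri in range(sarm.n_rows) if sarm.cells[(ri, ci)].is_real)
        for ci in range(sarm.n_columns)
    )
    return MatrixStats(
        matrix_id=sarm.matrix_id,
        n_rows=sarm.n_rows,
        n_columns=sarm.n_columns,
        n_matrix=sarm.n_real,
        row_overlaps=ros,
        matrix_overlap=sum(ros) / len(ros),
        coverage=sarm.n_real / (sarm.n_rows * sarm.n_columns),
        n_col=n_col,
    )


@dataclass
class EnvelopeEntry:
    structure: str
    sources: list[str]


def space_envelope(matrices: Sequence[SARM]) -> list[EnvelopeEntry]:
    """Union of virtual structures over all matrices — the chemical space
    envelope of the data set — deduplicated by canonical structure, each
    entry listing the matrices it occurs in."""
    seen: dict[str, EnvelopeEntry] = {}
    for sarm in matrices:
        for _, _, cell in sarm.virtual_cells():
            entry = seen.get(cell.structure)
            if entry is None:
                seen[cell.structure] = EnvelopeEntry(cell.structure,
                                                     [sarm.matrix_id])
            elif sarm.matrix_id not in entry.sources:
                entry.sources.append(sarm.matrix_id)
    return [seen[s] for s in sorted(seen)]


# --- serialization ---------------------------------------------------------

def sarm_to_dict(sarm: SARM) -> dict:
    return {
        "matrix_id": sarm.matrix_id,
        "amms_id": sarm.amms_id,
        "level": sarm.level,
        "target_id": sarm.target_id,
        "second_level_key": sarm.second_level_key,
        "rows": list(sarm.rows),
        "columns": [list(c) for c in sarm.columns],
        "cells": [
            {
                "row": ri, "column": ci, "status": cell.status,
                "structure": cell.structure,
                "compound_id": cell.compound_id, "pKi": cell.pki,
                "known_elsewhere": cell.known_elsewhere,
            }
            for ri, ci, cell in sarm.iter_cells()
        ],
        "stats": matrix_stats(sarm).__dict__ | {
            "row_overlaps": list(matrix_stats(sarm).row_overlaps),
            "n_col": list(matrix_stats(sarm).n_col),
        },
    }


def sarm_from_dict(data: dict) -> SARM:
    sarm = SARM(
        matrix_id=data["matrix_id"],
        amms_id=data["amms_id"],
        level=data["level"],
        target_id=data["target_id"],
        second_level_key=data["second_level_key"],
        rows=tuple(data["rows"]),
        columns=tuple(tuple(c) for c in data["columns"]),
    )
    for c in data["cells"]:
        sarm.cells[(c["row"], c["column"])] = Cell(
            status=c["status"], structure=c["structure"],
            compound_id=c["compound_id"], pki=c["pKi"],
            known_elsewhere=c.get("known_elsewhere", False),
        )
    return sarm


def write_matrices_json(matrices: Sequence[SARM], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([sarm_to_dict(m) for m in matrices], fh, indent=1,
                  sort_keys=True)
        fh.write("\n")


def read_matrices_json(path) -> list[SARM]:
    with open(path, encoding="utf-8") as fh:
        return [sarm_from_dict(d) for d in json.load(fh)]


def write_matrix_tsv(sarm: SARM, path) -> None:
    """Flat cell listing: row, column, core, values, status, compound, pKi."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("row\tcolumn\tcore\tvalues\tstatus\tcompound_id\tpKi\n")
        for ri, ci, cell in sarm.iter_cells():
            values = ".".join(sarm.columns[ci])
            pki = "" if cell.pki is None else repr(cell.pki)
            fh.write(f"{ri}\t{ci}\t{sarm.rows[ri]}\t{values}\t{cell.status}\t"
                     f"{cell.compound_id or ''}\t{pki}\n")
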