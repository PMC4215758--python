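"""SAR pattern detection and matrix ranking.

Large data sets yield far more matrices than anyone inspects one by one,
so matrices are scored by the SAR information they carry and consumed as
a ranked list.  The scores all derive from *analog pairs*: two annotated
real cells sharing a row (same core, different substituent) or a column
(same substituent, different core) — exactly the matched-pair
relationships the matrix layout encodes.

* discontinuity — mean absolute pKi difference over analog pairs; high
  values flag rough local SAR, low values smooth (continuous) SAR.
  Continuity ranking simply negates it.
* activity cliffs — analog pairs whose potency difference reaches a
  threshold (default 2 pKi units, i.e. 100-fold).
* SAR transfer — two rows whose potencies progress in parallel over
  shared columns (rank correlation above a threshold).
* preferred cores — rows whose annotated compounds are all potent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from scipy import stats

from .matrices import SARM, Cell

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalogPair:
    """Two annotated real cells differing in exactly one coordinate."""

    matrix_id: str
    axis: str                  # "row" if the cells share a row, else "column"
    coords_a: tuple[int, int]
    coords_b: tuple[int, int]
    compound_a: str
    compound_b: str
    pki_a: float
    pki_b: float

    @property
    def delta_p(self) -> float:
        return abs(self.pki_a - self.pki_b)


@dataclass(frozen=True)
class MatrixScore:
    matrix_id: str
    criterion: str
    score: float


@dataclass(frozen=True)
class TransferEvent:
    """Parallel potency progression between two analog series (rows)."""

    matrix_id: str
    row_a: int
    row_b: int
    columns: tuple[int, ...]
    correlation: float
    mean_offset: float         # mean(pKi row_b - pKi row_a) over shared columns


def analog_pairs(sarm: SARM) -> list[AnalogPair]:
    """All unordered pairs of annotated real cells sharing a row or a
    column, each listed once."""
    pairs: list[AnalogPair] = []

    def emit(axis: str, cells: list[tuple[tuple[int, int], Cell]]) -> None:
        for (ca, cell_a), (cb, cell_b) in combinations(cells, 2):
            pairs.append(AnalogPair(
                matrix_id=sarm.matrix_id, axis=axis,
                coords_a=ca, coords_b=cb,
                compound_a=cell_a.compound_id, compound_b=cell_b.compound_id,
                pki_a=cell_a.pki, pki_b=cell_b.pki,
            ))

    for ri in range(sarm.n_rows):
        emit("row", [((ri, ci), sarm.cells[(ri, ci)])
                     for ci in range(sarm.n_columns)
                     if sarm.cells[(ri, ci)].annotated])
    for ci in range(sarm.n_columns):
        emit("column", [((ri, ci), sarm.cells[(ri, ci)])
                        for ri in range(sarm.n_rows)
                        if sarm.cells[(ri, ci)].annotated])
    return pairs


def discontinuity_score(sarm: SARM) -> float:
    """Mean |delta pKi| over analog pairs (pKi log units).

    Raises ``ValueError`` when the matrix has no analog pair; such
    matrices carry no pairwise SAR signal and are excluded from ranking.
    """
    pairs = analog_pairs(sarm)
    if not pairs:
        raise ValueError(f"matrix {sarm.matrix_id} has no analog pair")
    return sum(p.delta_p for p in pairs) / len(pairs)


def continuity_score(sarm: SARM) -> float:
    """Negated discontinuity, so that higher = smoother SAR."""
    return -discontinuity_score(sarm)


def find_activity_cliffs(sarm: SARM, threshold: float = 2.0) -> list[AnalogPair]:
    """Analog pairs with |delta pKi| >= ``threshold`` (inclusive), sorted
    by decreasing potency difference.  The 2-log-unit default is the
    prevailing 100-fold convention for activity cliffs."""
    cliffs = [p for p in analog_pairs(sarm) if p.delta_p >= threshold]
    cliffs.sort(key=lambda p: (-p.delta_p, p.coords_a, p.coords_b))
    return cliffs


def detect_sar_transfer(
    sarm: SARM, min_shared: int = 3, min_corr: float = 0.8
) -> list[TransferEvent]:
    """Row pairs with parallel potency progression.

    For each unordered row pair with at least ``min_shared`` columns
    annotated in both rows, the Spearman rank correlation of the paired
    potencies is computed; pairs at or above ``min_corr`` are reported.
    Rank correlation (not product-moment) is used because the pattern of
    interest is a shared potency *ordering* across corresponding analogs,
    not linearity.  Constant rows have no defined ordering and are
    skipped.
    """
    events: list[TransferEvent] = []
    for ra, rb in combinations(range(sarm.n_rows), 2):
        shared = [ci for ci in range(sarm.n_columns)
                  if sarm.cells[(ra, ci)].annotated
                  and sarm.cells[(rb, ci)].annotated]
        if len(shared) < min_shared:
            continue
        pa = [sarm.cells[(ra, ci)].pki for ci in shared]
        pb = [sarm.cells[(rb, ci)].pki for ci in shared]
        if len(set(pa)) < 2 or len(set(pb)) < 2:
            continue
        rho = stats.spearmanr(pa, pb).statistic
        if rho != rho:  # NaN guard
            continue
        if rho >= min_corr:
            events.append(TransferEvent(
                matrix_id=sarm.matrix_id, row_a=ra, row_b=rb,
                columns=tuple(shared), correlation=float(rho),
                mean_offset=sum(b - a for a, b in zip(pa, pb)) / len(shared),
            ))
    return events


def preferred_cores(sarm: SARM, potency_cut: float) -> list[int]:
    """Rows that consistently produce potent compounds: all annotated
    cells at or above ``potency_cut``, with at least two annotated cells
    (a single measurement is not "consistent")."""
    rows = []
    for ri in range(sarm.n_rows):
        pkis = [sarm.cells[(ri, ci)].pki for ci in range(sarm.n_columns)
                if sarm.cells[(ri, ci)].annotated]
        if len(pkis) >= 2 and all(p >= potency_cut for p in pkis):
            rows.append(ri)
    return rows


CRITERIA = ("discontinuity", "continuity", "transfer", "preferred_core")


def rank_matrices(
    matrices: Sequence[SARM],
    criterion: str = "discontinuity",
    top_k: int | None = None,
    potency_cut: float = 7.0,
    min_shared: int = 3,
    min_corr: float = 0.8,
) -> list[MatrixScore]:
    """Score every matrix under one criterion and return a stable ranked
    list (descending score, ties broken by matrix_id).

    ``transfer`` scores by the number of transfer events and
    ``preferred_core`` by the number of preferred rows at
    ``potency_cut`` (default pKi 7, i.e. 100 nM — a conventional potency
    bar).  Matrices whose score is undefined (no analog pair) are
    excluded with a notice.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    scores: list[MatrixScore] = []
    for sarm in matrices:
        try:
            if criterion == "discontinuity":
                score = discontinuity_score(sarm)
            elif criterion == "continuity":
                score = continuity_score(sarm)
            elif criterion == "transfer":
                score = float(len(detect_sar_transfer(sarm, min_shared, min_corr)))
            else:
                score = float(len(preferred_cores(sarm, potency_cut)))
        except ValueError:
            logger.info("matrix %s excluded from ranking (no analog pair)",
                        sarm.matrix_id)
            continue
        scores.append(MatrixScore(sarm.matrix_id, criterion, score))
    scores.sort(key=lambda s: (-s.score, s.matrix_id))
    return scores[:top_k] if top_k is not None else scores


def write_ranking_tsv(
    matrices: Sequence[SARM], scores: Sequence[MatrixScore], path,
    cliff_threshold: float = 2.0,
) -> None:
    """Ranked list TSV: rank, matrix_id, criterion, score, n_real,
    n_virtual, n_cliffs."""
    by_id = {m.matrix_id: m for m in matrices}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tmatrix_id\tcriterion\tscore\tn_real\tn_virtual\tn_cliffs\n")
        for rank, score in enumerate(scores, start=1):
            sarm = by_id[score.matrix_id]
            n_virtual = sarm.n_rows * sarm.n_columns - sarm.n_real
            n_cliffs = len(find_activity_cliffs(sarm, cliff_threshold))
            fh.write(f"{rank}\t{score.matrix_id}\t{score.criterion}\t"
                     f"{score.score:.6g}\t{sarm.n_real}\t{n_virtual}\t{n_cliffs}\n")
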