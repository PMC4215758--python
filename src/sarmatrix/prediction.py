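"""Neighborhood-based potency prediction for virtual compounds.

A *neighborhood* (NBH) of a virtual cell X at (r, c) consists of three
adjacent real, annotated cells: E at (r', c) sharing X's substituent,
G at (r, c') sharing X's core, and D at (r', c') combining E's core with
G's substituent.  Under the Free-Wilson additivity assumption — potency
decomposes into independent core and substituent contributions on the
log scale — the unknown potency follows from the one-step "mini-QSAR"

    pX = pE + pG - pD

(the core swap E→D measures the substituent-independent core effect,
which transfers to X).  For each candidate, qualifying NBHs are
collected across *all* matrices containing that virtual structure;
the spread of the per-NBH predictions measures their consistency, and
candidates with several mutually consistent NBHs from matrices with
smooth (continuous) local SAR are the ones worth synthesizing.

Virtual compounds near activity cliffs fall outside this additive
formalism, but are attractive for hit finding precisely because the
local SAR is volatile; :func:`guilt_by_association` selects them without
attaching a numeric prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from .analytics import discontinuity_score, find_activity_cliffs
from .matrices import SARM

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Neighborhood:
    """One (E, G, D) completion of a virtual cell X."""

    matrix_id: str
    x: tuple[int, int]
    e: tuple[int, int]
    g: tuple[int, int]
    d: tuple[int, int]
    e_id: str
    g_id: str
    d_id: str
    pe: float
    pg: float
    pd: float

    @property
    def prediction(self) -> float:
        return self.pe + self.pg - self.pd

    @property
    def triple(self) -> frozenset[str]:
        return frozenset((self.e_id, self.g_id, self.d_id))


@dataclass
class PredictionSummary:
    """Aggregated per-NBH predictions for one virtual structure."""

    vc_structure: str
    predictions: tuple[float, ...]
    mean_pred: float
    sd_pred: float | None          # sample sd; undefined below 2 NBHs
    n_nbh: int
    source_matrices: tuple[str, ...] = ()


def find_neighborhoods(
    vc_structure: str, matrices: Sequence[SARM]
) -> list[Neighborhood]:
    """All NBHs of a virtual structure, collected across all matrices.

    The same three real compounds can surround the same virtual compound
    in several overlapping matrices; those repeats are one piece of
    evidence, not three, so NBHs are deduplicated by the unordered
    (E, G, D) compound-id triple.  Iteration order is deterministic, so
    the retained representative is too.
    """
    out: list[Neighborhood] = []
    seen: set[frozenset[str]] = set()
    for sarm in matrices:
        for (r, c), cell in sorted(sarm.cells.items()):
            if cell.is_real or cell.structure != vc_structure:
                continue
            for r2 in range(sarm.n_rows):
                if r2 == r or not sarm.cells[(r2, c)].annotated:
                    continue
                e = sarm.cells[(r2, c)]
                for c2 in range(sarm.n_columns):
                    if c2 == c or not sarm.cells[(r, c2)].annotated:
                        continue
                    g = sarm.cells[(r, c2)]
                    d = sarm.cells[(r2, c2)]
                    if not d.annotated:
                        continue
                    nbh = Neighborhood(
                        matrix_id=sarm.matrix_id, x=(r, c),
                        e=(r2, c), g=(r, c2), d=(r2, c2),
                        e_id=e.compound_id, g_id=g.compound_id,
                        d_id=d.compound_id,
                        pe=e.pki, pg=g.pki, pd=d.pki,
                    )
                    if nbh.triple not in seen:
                        seen.add(nbh.triple)
                        out.append(nbh)
    return out


def predict_from_neighborhood(nbh: Neighborhood) -> float:
    """The Free-Wilson estimate pX = pE + pG - pD, exactly."""
    return nbh.pe + nbh.pg - nbh.pd


def aggregate_predictions(
    vc_structure: str, nbhs: Sequence[Neighborhood]
) -> PredictionSummary:
    """Mean and sample standard deviation over per-NBH predictions."""
    preds = tuple(predict_from_neighborhood(n) for n in nbhs)
    if not preds:
        raise ValueError(f"no neighborhood for {vc_structure!r}")
    mean = sum(preds) / len(preds)
    sd = None
    if len(preds) >= 2:
        sd = math.sqrt(sum((p - mean) ** 2 for p in preds) / (len(preds) - 1))
    sources = tuple(dict.fromkeys(n.matrix_id for n in nbhs))
    return PredictionSummary(
        vc_structure=vc_structure, predictions=preds, mean_pred=mean,
        sd_pred=sd, n_nbh=len(preds), source_matrices=sources,
    )


def predict_virtuals(matrices: Sequence[SARM]) -> list[PredictionSummary]:
    """Aggregate predictions for every virtual structure that has at
    least one NBH anywhere in ``matrices``."""
    structures: list[str] = []
    seen: set[str] = set()
    for sarm in matrices:
        for _, _, cell in sarm.virtual_cells():
            if cell.structure not in seen:
                seen.add(cell.structure)
                structures.append(cell.structure)
    out = []
    for structure in structures:
        nbhs = find_neighborhoods(structure, matrices)
        if nbhs:
            out.append(aggregate_predictions(structure, nbhs))
    return out


def prioritize_candidates(
    summaries: Sequence[PredictionSummary],
    matrices: Sequence[SARM],
    min_nbh: int = 3,
    max_sd: float = 0.5,
    continuity_limit: float = 1.0,
) -> list[PredictionSummary]:
    """Design-candidate selection with an applicability domain.

    Keeps virtual compounds with at least ``min_nbh`` qualifying NBHs
    whose predictions agree (sample sd at most ``max_sd``) and that occur
    in at least one matrix representing a continuous local SAR
    (discontinuity score at most ``continuity_limit``).  A matrix whose
    discontinuity is undefined cannot certify continuity and does not
    qualify.  Survivors are ranked by predicted potency (descending),
    then by consistency (sd ascending).
    """
    disc: dict[str, float | None] = {}
    for sarm in matrices:
        try:
            disc[sarm.matrix_id] = discontinuity_score(sarm)
        except ValueError:
            disc[sarm.matrix_id] = None
    kept = []
    for s in summaries:
        if s.n_nbh < min_nbh:
            continue
        if s.sd_pred is None or s.sd_pred > max_sd:
            continue
        source_disc = [disc.get(m) for m in s.source_matrices]
        if not any(d is not None and d <= continuity_limit
                   for d in source_disc):
            continue
        kept.append(s)
    kept.sort(key=lambda s: (-s.mean_pred, s.sd_pred, s.vc_structure))
    return kept


@dataclass
class CliffNeighborCandidate:
    """A virtual compound adjacent to the potent partner of an activity
    cliff; selected by proximity, deliberately without a predicted
    potency (the additive formalism does not hold near cliffs)."""

    vc_structure: str
    provenances: list[dict] = field(default_factory=list)

    @property
    def best_partner_potency(self) -> float:
        return max(p["partner_potency"] for p in self.provenances)


def guilt_by_association(
    matrices: Sequence[SARM], cliff_threshold: float = 2.0
) -> list[CliffNeighborCandidate]:
    """Virtual compounds in the row or column of potent cliff partners.

    For every activity cliff in every matrix, the virtual cells sharing
    a row or a column with the cliff's more potent partner are emitted.
    A structure adjacent to several cliffs (or the same cliff in several
    matrices) appears once, with every provenance listed.  Result sorted
    by best adjacent partner potency (descending), then structure.
    """
    candidates: dict[str, CliffNeighborCandidate] = {}
    for sarm in matrices:
        for cliff in find_activity_cliffs(sarm, cliff_threshold):
            if cliff.pki_a >= cliff.pki_b:
                partner, partner_id, potency = cliff.coords_a, cliff.compound_a, cliff.pki_a
            else:
                partner, partner_id, potency = cliff.coords_b, cliff.compound_b, cliff.pki_b
            pr, pc = partner
            for r, c, cell in sarm.virtual_cells():
                if r != pr and c != pc:
                    continue
                cand = candidates.setdefault(
                    cell.structure, CliffNeighborCandidate(cell.structure))
                prov = {
                    "matrix_id": sarm.matrix_id,
                    "cliff_delta": cliff.delta_p,
                    "partner_potency": potency,
                    "partner_id": partner_id,
                }
                if prov not in cand.provenances:
                    cand.provenances.append(prov)
    out = list(candidates.values())
    out.sort(key=lambda c: (-c.best_partner_potency, c.vc_structure))
    return out


def write_predictions_tsv(summaries: Sequence[PredictionSummary], path) -> None:
    """Prediction report: vc_structure, mean_pred, sd_pred, n_nbh,
    source_matrices."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("vc_structure\tmean_pred\tsd_pred\tn_nbh\tsource_matrices\n")
        for s in summaries:
            sd = "" if s.sd_pred is None else f"{s.sd_pred:.4f}"
            fh.write(f"{s.vc_structure}\t{s.mean_pred:.4f}\t{sd}\t{s.n_nbh}\t"
                     f"{','.join(s.source_matrices)}\n")


def write_gba_tsv(candidates: Sequence[CliffNeighborCandidate], path) -> None:
    """Cliff-neighbor report: vc_structure, cliff_delta, partner_potency,
    matrix_id (one line per provenance)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("vc_structure\tcliff_delta\tpartner_potency\tmatrix_id\n")
        for cand in candidates:
            for prov in cand.provenances:
                fh.write(f"{cand.vc_structure}\t{prov['cliff_delta']:.4f}\t"
                         f"{prov['partner_potency']:.4f}\t{prov['matrix_id']}\n")
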