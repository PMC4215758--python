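"""Matched molecular series and structurally analogous series (A_MMS).

First level: all compounds indexed under the same core (key) form a
matched molecular series; any two members are a matched molecular pair
because they differ only at the cut site(s).  Second level: the cores
themselves are single-cut fragmented, and cores sharing a second-level
sub-key — i.e. cores distinguished only by a structural modification at
one site — group their series into a *structurally analogous matched
molecular series* (A_MMS).  Each A_MMS later becomes one SAR matrix:
analog series as rows, substituent combinations as columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem

from .chem_io import CompoundSet
from .fragmentation import (
    FragmentIndex,
    FragmentationConstraints,
    canonical_fragment,
    cuttable_bonds,
    heavy_atoms,
    _attachment_maps,
    _split_on_bonds,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeriesMember:
    values: tuple[str, ...]
    compound_id: str


@dataclass
class MatchedSeries:
    """All compounds sharing one canonical core, differing only in the
    substituent(s) at the attachment point(s)."""

    key: str
    level: int
    members: list[SeriesMember]

    def n_pairs(self) -> int:
        n = len(self.members)
        return n * (n - 1) // 2


def matched_series(index: FragmentIndex) -> list[MatchedSeries]:
    """One series per index key, ordered by key.

    Single-member series are retained: they cannot form a pair on their
    own but still contribute a sparsely populated matrix row, and the
    virtual cells of such rows are exactly the design candidates the
    matrices exist to expose.
    """
    out = []
    for key in sorted(index.entries):
        members = [SeriesMember(values, cid) for values, cid in index.entries[key]]
        out.append(MatchedSeries(key=key, level=index.level, members=members))
    return out


def implied_pairs(series_list: list[MatchedSeries]) -> set[frozenset[str]]:
    """The set of compound MMPs implied by series membership (unordered
    id pairs over all series)."""
    pairs: set[frozenset[str]] = set()
    for s in series_list:
        ids = [m.compound_id for m in s.members]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if ids[i] != ids[j]:
                    pairs.add(frozenset((ids[i], ids[j])))
    return pairs


def second_level_cuts(
    core: str,
    level: int,
    constraints: FragmentationConstraints = FragmentationConstraints(),
) -> list[tuple[str, str]]:
    """Single-cut fragmentations of a core fragment.

    Returns ``(sub_key, distinguishing_value)`` pairs.  A cut qualifies
    only if the sub-key retains *all* of the core's original attachment
    points (labels ``1..level``) — the distinguishing substructure is a
    peripheral modification carrying none of them — and the removed
    fragment respects ``max_value_heavy_atoms``.  The second-level
    attachment point is labeled ``level + 1`` on both sides so the core
    reassembles from (sub_key, distinguishing_value).

    Cores with no qualifying cut (e.g. a bare ring with one attachment
    point) return an empty list.
    """
    mol = Chem.MolFromSmiles(core)
    if mol is None:
        raise ValueError(f"unparsable core {core!r}")
    new_label = level + 1
    results: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    original = set(range(1, level + 1))
    for bond_id in cuttable_bonds(mol):
        pieces = _split_on_bonds(mol, [bond_id], first_label=new_label)
        labeled = [(p, set(_attachment_maps(p))) for p, _ in pieces]
        subs = [p for p, labels in labeled if original <= labels]
        others = [p for p, labels in labeled if not (original & labels)]
        if len(subs) != 1 or len(others) != 1:
            continue  # original attachment points split across fragments
        sub_piece, dist_piece = subs[0], others[0]
        if heavy_atoms(dist_piece) > constraints.max_value_heavy_atoms:
            continue
        sub_key = Chem.MolToSmiles(sub_piece)
        dist_value = Chem.MolToSmiles(dist_piece)
        if (sub_key, dist_value) not in seen:
            seen.add((sub_key, dist_value))
            results.append((sub_key, dist_value))
    return results


def reattach_core(sub_key: str, distinguishing_value: str) -> str:
    """Rebuild a core from a second-level sub-key and its distinguishing
    fragment (the inverse of :func:`second_level_cuts` for one cut).

    Only the second-level attachment point is merged; the core's own
    labeled attachment points survive into the output, which therefore
    compares equal to the original core fragment string.
    """
    key_mol = Chem.MolFromSmiles(sub_key)
    val_mol = Chem.MolFromSmiles(distinguishing_value)
    if key_mol is None or val_mol is None:
        raise ValueError("unparsable sub-key or distinguishing value")
    zipped = Chem.molzip(Chem.CombineMols(key_mol, val_mol))
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


def core_second_level_index(
    series_list: list[MatchedSeries],
    constraints: FragmentationConstraints = FragmentationConstraints(),
) -> dict[str, list[tuple[str, str, MatchedSeries]]]:
    """Index series by the second-level sub-keys of their cores.

    Maps ``sub_key -> [(core, distinguishing_value, series), ...]``.
    Two cores landing under the same sub-key form a core MMP: they are
    distinguished by a single-site modification (the two distinguishing
    values).
    """
    if not series_list:
        raise ValueError("no series to index")
    out: dict[str, list[tuple[str, str, MatchedSeries]]] = {}
    for series in series_list:
        for sub_key, dist in second_level_cuts(series.key, series.level, constraints):
            out.setdefault(sub_key, []).append((series.key, dist, series))
    return out


@dataclass(frozen=True)
class AmmsEntry:
    core: str
    distinguishing_value: str
    series: MatchedSeries


@dataclass
class AMMS:
    """A group of matched series whose cores are structural analogs
    (every pair of member cores shares ``second_level_key``)."""

    amms_id: str
    level: int
    second_level_key: str
    entries: list[AmmsEntry] = field(default_factory=list)

    @property
    def cores(self) -> list[str]:
        return [e.core for e in self.entries]


def identify_amms(
    series_list: list[MatchedSeries],
    constraints: FragmentationConstraints = FragmentationConstraints(),
    min_series: int = 1,
) -> list[AMMS]:
    """Group series into A_MMS by shared second-level sub-key.

    A series belongs to as many A_MMS as its core has qualifying
    second-level cuts, so compounds and series can (and routinely do)
    appear in multiple groups.  Output is deterministic: groups ordered
    by sub-key, entries by core.  ``min_series`` keeps groups with at
    least that many member series; matrix-level population minimums are
    enforced later by the matrix builder.
    """
    if not series_list:
        return []
    level = series_list[0].level
    grouped = core_second_level_index(series_list, constraints)
    out: list[AMMS] = []
    n = 0
    for sub_key in sorted(grouped):
        rows = sorted(grouped[sub_key], key=lambda t: t[0])
        if len(rows) < min_series:
            continue
        n += 1
        amms = AMMS(amms_id=f"L{level}-{n:04d}", level=level,
                    second_level_key=sub_key)
        for core, dist, series in rows:
            amms.entries.append(AmmsEntry(core, dist, series))
        out.append(amms)
    logger.info("level %d: %d A_MMS from %d series", level, len(out),
                len(series_list))
    return out


def write_amms_tsv(amms_list: list[AMMS], path) -> None:
    """Serialize A_MMS membership: amms_id, level, second_level_key,
    core, distinguishing_value, compound_id."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("amms_id\tlevel\tsecond_level_key\tcore\t"
                 "distinguishing_value\tcompound_id\n")
        for amms in amms_list:
            for entry in amms.entries:
                for member in entry.series.members:
                    fh.write(f"{amms.amms_id}\t{amms.level}\t"
                             f"{amms.second_level_key}\t{entry.core}\t"
                             f"{entry.distinguishing_value}\t"
                             f"{member.compound_id}\n")
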