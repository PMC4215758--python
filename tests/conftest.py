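"""Shared fixtures and independent oracles.

``oracle_fragmentations`` re-derives cut enumeration from graph first
principles (bridges + connected components via networkx), without going
through the fragmentation engine, so engine-vs-oracle comparisons are a
genuine two-route check at the atom-partition level.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest
from rdkit import Chem

from sarmatrix import (
    CompoundRecord,
    CompoundSet,
    FragmentationConstraints,
    build_matrices,
    canonical_structure,
)
from sarmatrix.matrices import REAL, VIRTUAL, Cell, SARM


# --- hand-built matrices for analytics/prediction unit tests --------------

def make_matrix(grid, matrix_id="M1", target_id="T1") -> SARM:
    """Build a SARM directly from a potency grid.

    ``grid[r][c]`` is a number (real annotated cell), the string "NA"
    (real but unannotated), or None (virtual).  Structures are synthetic
    placeholders encoding the coordinates, unique per cell.
    """
    n_rows, n_cols = len(grid), len(grid[0])
    sarm = SARM(
        matrix_id=matrix_id, amms_id=matrix_id, level=1, target_id=target_id,
        second_level_key="K",
        rows=tuple(f"core{r}" for r in range(n_rows)),
        columns=tuple((f"val{c}",) for c in range(n_cols)),
    )
    for r in range(n_rows):
        for c in range(n_cols):
            entry = grid[r][c]
            structure = f"{matrix_id}-struct-r{r}c{c}"
            if entry is None:
                sarm.cells[(r, c)] = Cell(status=VIRTUAL, structure=structure)
            elif entry == "NA":
                sarm.cells[(r, c)] = Cell(status=REAL, structure=structure,
                                          compound_id=f"{matrix_id}-r{r}c{c}")
            else:
                sarm.cells[(r, c)] = Cell(status=REAL, structure=structure,
                                          compound_id=f"{matrix_id}-r{r}c{c}",
                                          pki=float(entry))
    return sarm


# --- small real-chemistry sets ---------------------------------------------

def two_site_set(cells: list[tuple[str, str]],
                 pki: dict[tuple[str, str], float] | None = None,
                 target="T1") -> CompoundSet:
    """Disubstituted-pyridine compounds for (X, Y) in ``cells``; X plays
    the core-variant role, Y the substituent role.  The two ring
    positions are inequivalent, so the variant-side and substituent-side
    series groupings stay in separate matrices."""
    cset = CompoundSet(provenance="pyridine two-site fixture")
    for i, (x, y) in enumerate(cells):
        smiles = f"{x}c1ccc({y})cn1"
        rec = CompoundRecord(f"c{i}-{x}-{y}", canonical_structure(smiles))
        if pki is not None:
            rec.add_activity(target, pki[(x, y)])
        cset.add(rec)
    return cset


def variant_cores(variants) -> frozenset[str]:
    """Canonical cores of the two-site template with the substituent
    position opened (X fixed, attachment at Y)."""
    from sarmatrix import canonical_fragment
    return frozenset(canonical_fragment(f"{x}c1ccc([*:1])cn1")[0]
                     for x in variants)


def matrix_with_rows(matrices, cores: frozenset[str]):
    """The unique built matrix whose row set equals ``cores``."""
    hits = [m for m in matrices if frozenset(m.rows) == cores]
    assert len(hits) == 1, f"expected one matrix with rows {sorted(cores)}"
    return hits[0]


@pytest.fixture(scope="session")
def permissive():
    from sarmatrix import PERMISSIVE
    return PERMISSIVE


@pytest.fixture()
def small_pipeline():
    """Compounds -> level-1 matrices with permissive-ish thresholds
    suitable for handfuls of small molecules."""
    def run(cset, target="T1", min_rows=2, min_real=2,
            constraints=FragmentationConstraints(
                max_value_heavy_atoms=13, min_key_heavy_atoms=3,
                key_must_be_larger=True)):
        return build_matrices(cset, target, levels=(1,),
                              constraints=constraints,
                              min_rows=min_rows, min_real=min_real)
    return run


# --- independent fragmentation oracle --------------------------------------

def oracle_fragmentations(smiles: str, level: int):
    """Brute-force cut enumeration on the molecular graph.

    Eligible bonds are single-order bridges between heavy atoms.  For
    every ``level``-subset, remove the edges and inspect components: a
    cut qualifies if one component (the key) touches every removed edge;
    at level 1 the key is any component at least as large as the other
    (a tie yields both orientations).  Returns a set of
    ``(key_atoms, frozenset_of_value_atom_sets)`` partitions.
    """
    mol = Chem.MolFromSmiles(smiles)
    graph = nx.Graph()
    graph.add_nodes_from(range(mol.GetNumAtoms()))
    for bond in mol.GetBonds():
        graph.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
            single=bond.GetBondType() == Chem.BondType.SINGLE,
        )
    bridges = {frozenset(e) for e in nx.bridges(graph)}
    eligible = [
        (u, v) for u, v, d in graph.edges(data=True)
        if d["single"] and frozenset((u, v)) in bridges
    ]
    partitions = set()
    for combo in itertools.combinations(eligible, level):
        pruned = graph.copy()
        pruned.remove_edges_from(combo)
        comps = [frozenset(c) for c in nx.connected_components(pruned)]
        def touches(comp, edge):
            return edge[0] in comp or edge[1] in comp
        full = [c for c in comps if all(touches(c, e) for e in combo)]
        if level == 1:
            a, b = comps
            if len(a) >= len(b):
                partitions.add((a, frozenset([b])))
            if len(b) >= len(a):
                partitions.add((b, frozenset([a])))
        elif len(full) == 1:
            key = full[0]
            values = frozenset(c for c in comps if c != key)
            # each value component must touch exactly one cut edge
            if all(sum(touches(c, e) for e in combo) == 1 for c in values):
                partitions.add((key, values))
    return partitions


def engine_partitions(frags):
    """Project engine output onto the oracle's partition representation."""
    return {
        (f.key_atoms, frozenset(f.value_atoms)) for f in frags
    }
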