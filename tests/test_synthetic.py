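"""Synthetic library generator: determinism, ground-truth alignment,
grid recovery through the pipeline, cliff seeding, and the random
molecule sampler."""

import numpy as np
import pytest
from rdkit import Chem

from sarmatrix import (
    build_matrices,
    canonical_fragment,
    find_activity_cliffs,
    reassemble,
)
from sarmatrix.fragmentation import cuttable_bonds
from sarmatrix.synthetic import (
    SCAFFOLDS, SUBSTITUENTS, VARIANTS,
    LibraryConfig, generate_library, multi_target_library,
    random_molecules, seed_cliffs,
)


class TestTemplates:
    def test_fragment_sets_disjoint(self):
        assert not set(VARIANTS) & set(SUBSTITUENTS)

    def test_variants_and_substituents_internally_uncuttable(self):
        """No fragment contributes cut sites of its own, so library
        compounds cut only at the two scaffold junctions and the additive
        decomposition transfers to every derived matrix."""
        for smi in VARIANTS + SUBSTITUENTS:
            mol = Chem.MolFromSmiles(smi)
            internal = [
                b for b in mol.GetBonds()
                if b.GetBondType() == Chem.BondType.SINGLE
                and not b.IsInRing()
                and b.GetBeginAtom().GetAtomicNum() > 1
                and b.GetEndAtom().GetAtomicNum() > 1
            ]
            assert internal == [], smi

    def test_compounds_have_exactly_two_cut_sites(self):
        for scaffold in SCAFFOLDS:
            smi = reassemble(scaffold, [VARIANTS[0], SUBSTITUENTS[0]])
            assert len(cuttable_bonds(Chem.MolFromSmiles(smi))) == 2


class TestGenerateLibrary:
    def test_same_seed_identical_output(self):
        cfg = LibraryConfig(n_scaffolds=2, n_core_variants=3,
                            n_substituents=4, noise_sd=0.2,
                            holdout_fraction=0.1, seed=17)
        a_set, a_gt = generate_library(cfg)
        b_set, b_gt = generate_library(cfg)
        assert [(r.compound_id, r.structure, r.activities)
                for r in a_set] == \
               [(r.compound_id, r.structure, r.activities) for r in b_set]
        assert a_gt.observed_pki == b_gt.observed_pki

    def test_additive_decomposition_recorded(self):
        cset, gt = generate_library(LibraryConfig(
            n_scaffolds=1, n_core_variants=3, n_substituents=3, seed=2))
        for cid, rec in cset.by_id.items():
            d = gt.decomposition[cid]
            assert gt.true_pki[cid] == pytest.approx(
                6.5 + d["core_effect"] + d["substituent_effect"])
            assert rec.activities["T1"] == pytest.approx(gt.true_pki[cid])

    def test_holdout_cells_missing_from_set_but_recorded(self):
        cfg = LibraryConfig(n_scaffolds=1, n_core_variants=3,
                            n_substituents=4, holdout_fraction=0.25, seed=8)
        cset, gt = generate_library(cfg)
        assert len(gt.held_out) == int(0.25 * 12)
        assert len(cset) == 12 - len(gt.held_out)
        for cid, cell in gt.held_out.items():
            assert cid not in cset.by_id
            assert cell.structure not in cset.by_structure

    def test_holdout_cells_surface_as_virtual_cells(self):
        cfg = LibraryConfig(n_scaffolds=1, n_core_variants=4,
                            n_substituents=5, holdout_fraction=0.15, seed=8)
        cset, gt = generate_library(cfg)
        matrices = build_matrices(cset, "T1")
        virtuals = {c.structure for m in matrices
                    for _, _, c in m.virtual_cells()}
        for cell in gt.held_out.values():
            assert cell.structure in virtuals

    def test_intended_grid_recovered_per_scaffold(self):
        """For every scaffold, some matrix embeds the full core-variant x
        substituent grid with all cells real (no holdout)."""
        cfg = LibraryConfig(n_scaffolds=len(SCAFFOLDS), n_core_variants=3,
                            n_substituents=4, seed=13)
        cset, gt = generate_library(cfg)
        matrices = build_matrices(cset, "T1")
        recovered = 0
        for si in range(cfg.n_scaffolds):
            scaffold = SCAFFOLDS[si]
            cores = {
                canonical_fragment(
                    reassemble_key(scaffold, VARIANTS[vi]))[0]
                for vi in range(cfg.n_core_variants)
            }
            ids = {f"S{si}-V{vi}-R{ri}"
                   for vi in range(cfg.n_core_variants)
                   for ri in range(cfg.n_substituents)}
            for m in matrices:
                real_ids = {c.compound_id for _, _, c in m.real_cells()}
                if cores <= set(m.rows) and ids <= real_ids:
                    recovered += 1
                    break
        assert recovered == cfg.n_scaffolds

    def test_non_additive_mode_has_no_structure(self):
        cfg = LibraryConfig(n_scaffolds=1, n_core_variants=3,
                            n_substituents=3, additive=False, seed=3)
        _, gt = generate_library(cfg)
        # decomposition is still recorded, but cells draw independently:
        # same variant, different substituent => different core effect draw
        effects = {}
        for cid, d in gt.decomposition.items():
            effects.setdefault(d["variant"], set()).add(d["core_effect"])
        assert any(len(v) > 1 for v in effects.values())

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            LibraryConfig(n_scaffolds=99)
        with pytest.raises(ValueError):
            LibraryConfig(holdout_fraction=1.0)
        with pytest.raises(ValueError):
            LibraryConfig(noise_sd=-0.1)


def reassemble_key(scaffold: str, variant: str) -> str:
    """Core of a scaffold with the variant attached and the substituent
    position left open, built independently of the fragment engine's
    second-level machinery."""
    from rdkit import Chem
    key_mol = Chem.MolFromSmiles(scaffold)
    var_mol = Chem.MolFromSmiles(variant)
    for a in var_mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomMapNum(1)
    combined = Chem.CombineMols(key_mol, var_mol)
    zipped = Chem.molzip(combined)
    Chem.SanitizeMol(zipped)
    # remaining dummy (map 2) becomes the single attachment point
    return Chem.MolToSmiles(zipped)


class TestSeedCliffs:
    def test_seeded_cells_recovered_as_cliffs(self):
        cset, gt = generate_library(LibraryConfig(
            n_scaffolds=2, n_core_variants=3, n_substituents=4, seed=6))
        seed_cliffs(cset, gt, n_cliffs=2, delta=3.0, seed=60)
        matrices = build_matrices(cset, "T1")
        cliff_ids = {
            cid
            for m in matrices
            for pair in find_activity_cliffs(m, threshold=2.0)
            for cid in (pair.compound_a, pair.compound_b)
        }
        for entry in gt.cliffs:
            assert entry["compound_id"] in cliff_ids

    def test_zero_cliffs_is_identity(self):
        cset, gt = generate_library(LibraryConfig(
            n_scaffolds=1, n_core_variants=3, n_substituents=3, seed=6))
        before = {cid: r.activities["T1"] for cid, r in cset.by_id.items()}
        seed_cliffs(cset, gt, n_cliffs=0)
        assert {cid: r.activities["T1"]
                for cid, r in cset.by_id.items()} == before
        assert gt.cliffs == []

    def test_ground_truth_tracks_jump(self):
        cset, gt = generate_library(LibraryConfig(
            n_scaffolds=1, n_core_variants=3, n_substituents=3, seed=6))
        reference = dict(gt.true_pki)
        seed_cliffs(cset, gt, n_cliffs=1, delta=3.0, seed=61)
        (entry,) = gt.cliffs
        cid = entry["compound_id"]
        assert gt.true_pki[cid] == pytest.approx(reference[cid] + 3.0)
        assert cset.by_id[cid].activities["T1"] == pytest.approx(
            gt.true_pki[cid])


class TestMultiTargetLibrary:
    def test_probability_profile_annotates_subset(self):
        cset, _ = multi_target_library(
            LibraryConfig(n_scaffolds=1, n_core_variants=3,
                          n_substituents=4, seed=10),
            n_targets=4, promiscuity_profile=0.5)
        counts = [len(r.activities) for r in cset]
        assert min(counts) < 4  # not everything annotated everywhere
        assert all(0 <= c <= 4 for c in counts)

    def test_per_target_truth_recorded_for_every_cell(self):
        cset, gt = multi_target_library(
            LibraryConfig(n_scaffolds=1, n_core_variants=2,
                          n_substituents=3, seed=10),
            n_targets=2)
        for cid in gt.true_pki:
            assert set(gt.true_pki[cid]) == {"T1", "T2"}

    def test_requires_two_targets(self):
        with pytest.raises(ValueError):
            multi_target_library(LibraryConfig(seed=1), n_targets=1)


class TestRandomMolecules:
    def test_deterministic_and_bounded(self):
        a = random_molecules(20, max_heavy=25, seed=3)
        b = random_molecules(20, max_heavy=25, seed=3)
        assert a == b
        for smi in a:
            mol = Chem.MolFromSmiles(smi)
            assert mol is not None
            assert 2 <= mol.GetNumAtoms() <= 25

    def test_population_is_structurally_diverse(self):
        from rdkit.Chem import rdMolDescriptors
        mols = random_molecules(40, max_heavy=25, seed=5)
        assert len(set(mols)) > 30
        with_ring = sum(
            rdMolDescriptors.CalcNumRings(Chem.MolFromSmiles(s)) > 0
            for s in mols)
        assert 0 < with_ring < 40
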