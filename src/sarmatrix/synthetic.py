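"""Synthetic combinatorial libraries with known ground truth.

The generator emulates the combinatorial structure the matrix method
assumes: per scaffold, a grid of analogous cores (scaffold + variant
group, differing at one site) crossed with substituents.  Observed
potency is Free-Wilson additive, ``pKi = mu + a_variant + b_substituent``
plus optional Gaussian noise; held-out grid cells are omitted from the
compound set (they surface as virtual cells downstream) but recorded in
the ground truth together with their true and observed values, and
activity cliffs can be seeded by adding a potency jump to chosen cells.

Template choice matters more than it looks: variant and substituent
fragments are picked to contain *no* cuttable (exocyclic single) bond of
their own — halogens, small rings, multiple-bond groups — so the only
cut sites in a library compound are the two scaffold junctions.  Every
matrix the fragmenter can derive then splits a compound along fragment
boundaries, the additive decomposition transfers to every matrix layout,
and held-out cells are exactly recoverable wherever they appear.  The
fixtures test mechanics, not chemistry; no attempt is made at realistic
property distributions.

All randomness flows from the single integer seed in the config through
one named generator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem

from .chem_io import CompoundRecord, CompoundSet
from .fragmentation import reassemble

logger = logging.getLogger(__name__)

#: two-attachment scaffold templates: point 1 takes the core-variant
#: group, point 2 the substituent
SCAFFOLDS: tuple[str, ...] = (
    "[*:1]c1ccc([*:2])cc1",          # benzene-1,4
    "[*:1]c1ccc([*:2])s1",           # thiophene-2,5
    "[*:1]C1CCC([*:2])CC1",          # cyclohexane-1,4
    "[*:1]c1cccc([*:2])n1",          # pyridine-2,6
    "[*:1]c1ccc2ccc([*:2])cc2c1",    # naphthalene-2,6
)

#: core-variant groups (single site distinguishing analogous cores);
#: none contains a cuttable internal bond
VARIANTS: tuple[str, ...] = (
    "[*]F", "[*]Cl", "[*]Br", "[*]I", "[*]O", "[*]N", "[*]S", "[*]C#N",
)

#: substituent groups; disjoint from VARIANTS and likewise internally
#: uncuttable (rings, multiple bonds, or a single atom)
SUBSTITUENTS: tuple[str, ...] = (
    "[*]C", "[*]C=C", "[*]C#C", "[*]C=O", "[*]C1CC1", "[*]C1CCC1",
    "[*]C1CCCC1", "[*]c1ccccc1", "[*]c1ccco1", "[*]C1CCCCC1",
)


@dataclass(frozen=True)
class LibraryConfig:
    """Study conditions for one synthetic library.

    Effects are drawn uniformly from the given (low, high) ranges in pKi
    units.  The defaults give a moderately potent series (baseline pKi
    6.5) with up to one log unit of core and substituent variation —
    enough SAR texture to rank matrices while keeping ordinary analog
    pair differences well below the 2-log-unit cliff convention, so only
    deliberately seeded cliffs cross it.
    """

    n_scaffolds: int = 3
    n_core_variants: int = 4
    n_substituents: int = 6
    additive: bool = True
    mu: float = 6.5
    core_effects: tuple[float, float] = (0.0, 1.0)
    substituent_effects: tuple[float, float] = (0.0, 1.0)
    noise_sd: float = 0.0
    holdout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_scaffolds <= len(SCAFFOLDS)):
            raise ValueError(f"n_scaffolds must be in [1, {len(SCAFFOLDS)}]")
        if not (1 <= self.n_core_variants <= len(VARIANTS)):
            raise ValueError(f"n_core_variants must be in [1, {len(VARIANTS)}]")
        if not (1 <= self.n_substituents <= len(SUBSTITUENTS)):
            raise ValueError(f"n_substituents must be in [1, {len(SUBSTITUENTS)}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in [0, 1)")


@dataclass
class HeldOutCell:
    compound_id: str
    structure: str
    true_pki: float
    observed_pki: float


@dataclass
class GroundTruth:
    """Per-compound truth for a generated library.

    ``true_pki``/``observed_pki`` cover every grid cell, held out or not
    (values are per-target dicts for multi-target libraries);
    ``decomposition`` records the (scaffold, variant, substituent) and
    effect split of each cell; ``held_out`` lists cells omitted from the
    compound set; ``cliffs`` the seeded potency jumps.
    """

    true_pki: dict = field(default_factory=dict)
    observed_pki: dict = field(default_factory=dict)
    decomposition: dict = field(default_factory=dict)
    held_out: dict[str, HeldOutCell] = field(default_factory=dict)
    cliffs: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "true_pki": self.true_pki,
            "observed_pki": self.observed_pki,
            "decomposition": self.decomposition,
            "held_out": {k: asdict(v) for k, v in self.held_out.items()},
            "cliffs": self.cliffs,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _grid(config: LibraryConfig):
    """Yield (compound_id, scaffold_idx, variant_idx, sub_idx, structure)."""
    for si in range(config.n_scaffolds):
        scaffold = SCAFFOLDS[si]
        for vi in range(config.n_core_variants):
            for ri in range(config.n_substituents):
                cid = f"S{si}-V{vi}-R{ri}"
                structure = reassemble(
                    scaffold, [VARIANTS[vi], SUBSTITUENTS[ri]])
                yield cid, si, vi, ri, structure


def generate_library(
    config: LibraryConfig, target_id: str = "T1"
) -> tuple[CompoundSet, GroundTruth]:
    """Build one single-target library and its ground truth.

    Each scaffold gets its own draw of core-variant effects ``a`` and
    substituent effects ``b``; with ``additive`` (the default) the true
    potency of cell (scaffold, variant, substituent) is
    ``mu + a[variant] + b[substituent]``, otherwise each cell draws both
    contributions independently (no transferable structure).  Observed
    potency adds ``N(0, noise_sd)``.  ``holdout_fraction`` of the cells
    (rounded down, chosen uniformly) are excluded from the CompoundSet.
    """
    rng = np.random.default_rng(config.seed)
    cset = CompoundSet(provenance=f"synthetic library seed={config.seed}")
    gt = GroundTruth()

    a = rng.uniform(*config.core_effects,
                    size=(config.n_scaffolds, config.n_core_variants))
    b = rng.uniform(*config.substituent_effects,
                    size=(config.n_scaffolds, config.n_substituents))

    cells = list(_grid(config))
    n_holdout = int(config.holdout_fraction * len(cells))
    held_idx = set(rng.choice(len(cells), size=n_holdout, replace=False)
                   ) if n_holdout else set()

    for idx, (cid, si, vi, ri, structure) in enumerate(cells):
        if config.additive:
            ae, be = float(a[si, vi]), float(b[si, ri])
        else:
            ae = float(rng.uniform(*config.core_effects))
            be = float(rng.uniform(*config.substituent_effects))
        true = config.mu + ae + be
        noise = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd else 0.0
        observed = true + noise
        gt.true_pki[cid] = true
        gt.observed_pki[cid] = observed
        gt.decomposition[cid] = {
            "scaffold": si, "variant": VARIANTS[vi],
            "substituent": SUBSTITUENTS[ri],
            "core_effect": ae, "substituent_effect": be,
        }
        if idx in held_idx:
            gt.held_out[cid] = HeldOutCell(cid, structure, true, observed)
            continue
        rec = CompoundRecord(cid, structure)
        rec.add_activity(target_id, observed)
        added = cset.add(rec)
        if added is not rec:  # template guarantee: grid cells are distinct
            raise RuntimeError(f"duplicate structure for {cid}")
    return cset, gt


def seed_cliffs(
    cset: CompoundSet,
    gt: GroundTruth,
    n_cliffs: int,
    delta: float = 3.0,
    seed: int = 0,
) -> tuple[CompoundSet, GroundTruth]:
    """Add a potency jump ``delta`` to ``n_cliffs`` randomly chosen real
    (non-held-out) cells, in place; the affected cells are recorded in
    ``gt.cliffs``.  With the default effect ranges (width <= 1 pKi unit)
    a delta of 3 guarantees every analog pair involving a seeded cell
    clears the 2-log-unit cliff threshold."""
    if n_cliffs == 0:
        return cset, gt
    rng = np.random.default_rng(seed)
    candidates = sorted(cset.by_id)
    chosen = rng.choice(len(candidates), size=n_cliffs, replace=False)
    for i in sorted(int(c) for c in chosen):
        cid = candidates[i]
        rec = cset.by_id[cid]
        for t in list(rec._acc):
            s, n = rec._acc[t]
            rec._acc[t] = (s + delta * n, n)
        if isinstance(gt.true_pki.get(cid), dict):
            for t in gt.true_pki[cid]:
                gt.true_pki[cid][t] += delta
                gt.observed_pki[cid][t] += delta
        else:
            gt.true_pki[cid] += delta
            gt.observed_pki[cid] += delta
        gt.cliffs.append({"compound_id": cid, "delta": delta})
    return cset, gt


ProfileSpec = (
    str | float
    | Mapping[str, Iterable[str]]
    | Callable[[np.random.Generator, str, Sequence[str]], Iterable[str]]
)


def multi_target_library(
    config: LibraryConfig,
    n_targets: int,
    promiscuity_profile: ProfileSpec = "all",
) -> tuple[CompoundSet, GroundTruth]:
    """Library with per-target additive effects drawn independently.

    Targets are named ``T1..Tn``.  ``promiscuity_profile`` decides which
    targets each compound is annotated against: ``"all"``, a probability
    per (compound, target), an explicit mapping compound_id -> targets,
    or a callable ``(rng, compound_id, targets) -> targets``.  Ground
    truth stores per-target dicts for every cell regardless of the
    annotation profile.
    """
    if n_targets < 2:
        raise ValueError("multi-target library needs n_targets >= 2")
    rng = np.random.default_rng(config.seed)
    targets = [f"T{i + 1}" for i in range(n_targets)]
    cset = CompoundSet(
        provenance=f"synthetic multi-target library seed={config.seed}")
    gt = GroundTruth()

    a = rng.uniform(*config.core_effects,
                    size=(n_targets, config.n_scaffolds, config.n_core_variants))
    b = rng.uniform(*config.substituent_effects,
                    size=(n_targets, config.n_scaffolds, config.n_substituents))

    cells = list(_grid(config))
    n_holdout = int(config.holdout_fraction * len(cells))
    held_idx = set(rng.choice(len(cells), size=n_holdout, replace=False)
                   ) if n_holdout else set()

    for idx, (cid, si, vi, ri, structure) in enumerate(cells):
        true = {}
        observed = {}
        for ti, t in enumerate(targets):
            v = config.mu + float(a[ti, si, vi]) + float(b[ti, si, ri])
            true[t] = v
            observed[t] = v + (float(rng.normal(0.0, config.noise_sd))
                               if config.noise_sd else 0.0)
        gt.true_pki[cid] = true
        gt.observed_pki[cid] = observed
        gt.decomposition[cid] = {
            "scaffold": si, "variant": VARIANTS[vi],
            "substituent": SUBSTITUENTS[ri],
        }
        if idx in held_idx:
            gt.held_out[cid] = HeldOutCell(cid, structure, 0.0, 0.0)
            continue

        if promiscuity_profile == "all":
            annotated = list(targets)
        elif isinstance(promiscuity_profile, float):
            annotated = [t for t in targets
                         if rng.random() < promiscuity_profile]
        elif callable(promiscuity_profile):
            annotated = list(promiscuity_profile(rng, cid, targets))
        else:
            annotated = list(promiscuity_profile.get(cid, ()))

        rec = CompoundRecord(cid, structure)
        for t in annotated:
            rec.add_activity(t, observed[t])
        cset.add(rec)
    return cset, gt


def write_library(cset: CompoundSet, gt: GroundTruth, out_dir) -> None:
    """Emit the standard on-disk form: library.smi, activities.csv,
    ground_truth.json — so fixtures can exercise the real I/O path."""
    from pathlib import Path
    from .chem_io import write_activities, write_smiles

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_smiles(cset, out / "library.smi")
    write_activities(cset, out / "activities.csv")
    gt.to_json(out / "ground_truth.json")


# --- random molecules for engine-vs-oracle testing -------------------------

_RING_BLOCKS = ("c1ccccc1", "C1CCCCC1", "c1ccncc1", "c1ccsc1", "C1CCCC1",
                "C1CCOC1")
_CHAIN_ATOMS = ("C", "C", "C", "C", "N", "O", "S")
_TERMINALS = ("F", "Cl", "Br")


def _free_valence(atom: Chem.Atom) -> int:
    if atom.GetIsAromatic():
        # one exocyclic single bond allowed on aromatic carbon only
        if atom.GetSymbol().upper() != "C":
            return 0
        return max(0, 3 - atom.GetDegree())
    default = Chem.GetPeriodicTable().GetDefaultValence(atom.GetAtomicNum())
    used = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
    return max(0, default - used)


def random_molecule(rng: np.random.Generator, max_heavy: int = 30) -> str:
    """One random branched molecule (rings + heterochains + halogens),
    at most ``max_heavy`` heavy atoms, as canonical SMILES.

    Built by attaching random building blocks with single bonds, so the
    result is rich in exocyclic single bonds — exactly the bond class
    the fragmenter enumerates."""
    target = int(rng.integers(4, max_heavy + 1))
    while True:
        if rng.random() < 0.5:
            mol = Chem.RWMol(Chem.MolFromSmiles(
                _RING_BLOCKS[rng.integers(len(_RING_BLOCKS))]))
        else:
            mol = Chem.RWMol()
            mol.AddAtom(Chem.Atom(_CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))]))
        for _ in range(60):
            if mol.GetNumAtoms() >= target:
                break
            anchors = [a.GetIdx() for a in mol.GetAtoms() if _free_valence(a) > 0]
            if not anchors:
                break
            anchor = int(anchors[rng.integers(len(anchors))])
            roll = rng.random()
            if roll < 0.15 and mol.GetNumAtoms() + 5 <= max_heavy:
                ring = Chem.MolFromSmiles(
                    _RING_BLOCKS[rng.integers(len(_RING_BLOCKS))])
                offset = mol.GetNumAtoms()
                mol = Chem.RWMol(Chem.CombineMols(mol, ring))
                mol.AddBond(anchor, offset, Chem.BondType.SINGLE)
            elif roll < 0.30:
                idx = mol.AddAtom(Chem.Atom(
                    _TERMINALS[rng.integers(len(_TERMINALS))]))
                mol.AddBond(anchor, idx, Chem.BondType.SINGLE)
            else:
                idx = mol.AddAtom(Chem.Atom(
                    _CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))]))
                mol.AddBond(anchor, idx, Chem.BondType.SINGLE)
        try:
            out = mol.GetMol()
            Chem.SanitizeMol(out)
        except Exception:  # rare valence clash; redraw
            continue
        if out.GetNumAtoms() >= 2:
            return Chem.MolToSmiles(out)


def random_molecules(n: int, max_heavy: int = 30, seed: int = 0) -> list[str]:
    rng = np.random.default_rng(seed)
    return [random_molecule(rng, max_heavy) for _ in range(n)]
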