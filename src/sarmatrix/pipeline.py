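"""One-call pipelines: compounds -> fragment index -> matched series ->
analogous-series groups -> matrices.  Levels are processed independently
(single-, dual- and triple-cut matrices are separate objects)."""

from __future__ import annotations

from typing import Iterable, Sequence

from .chem_io import CompoundSet
from .fragmentation import FragmentationConstraints, build_index
from .matrices import SARM, build_sarms, enumerate_virtuals
from .multitarget import CSM, build_csm
from .series import AMMS, identify_amms, matched_series


def compounds_to_amms(
    cset: CompoundSet,
    levels: Iterable[int] = (1,),
    constraints: FragmentationConstraints = FragmentationConstraints(),
) -> dict[int, list[AMMS]]:
    """Fragment, collect matched series, and group analogous series, per
    cut level."""
    indexes = build_index(cset, levels, constraints)
    return {
        lvl: identify_amms(matched_series(index), constraints)
        for lvl, index in sorted(indexes.items())
    }


def build_matrices(
    cset: CompoundSet,
    target_id: str,
    levels: Iterable[int] = (1,),
    constraints: FragmentationConstraints = FragmentationConstraints(),
    min_rows: int = 2,
    min_real: int = 3,
) -> list[SARM]:
    """Full single-target pipeline; virtual cells get structures and
    ``known_elsewhere`` flags."""
    out: list[SARM] = []
    for _, amms_list in sorted(compounds_to_amms(cset, levels, constraints).items()):
        built = build_sarms(amms_list, cset, target_id,
                            min_rows=min_rows, min_real=min_real)
        for sarm in built:
            enumerate_virtuals(sarm, cset)
        out.extend(built)
    return out


def build_multitarget_matrices(
    cset: CompoundSet,
    levels: Iterable[int] = (1,),
    constraints: FragmentationConstraints = FragmentationConstraints(),
    activity_threshold: float | None = None,
    min_rows: int = 2,
    min_real: int = 3,
) -> list[CSM]:
    """Full multi-target pipeline to compound series matrices."""
    out: list[CSM] = []
    for _, amms_list in sorted(compounds_to_amms(cset, levels, constraints).items()):
        out.extend(build_csm(amms_list, cset, activity_threshold,
                             min_rows=min_rows, min_real=min_real))
    return out
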