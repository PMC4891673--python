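"""Reference -> sample methylation-state transitions and DMF partitioning.

A locus whose state differs from the reference in at least one individual
is a differentially methylated fragment (DMF).  DMFs changed identically in
every individual are *uniform* (uDMF); the rest are *distinctive* (dDMF).

Transitions are ordered by methylation load IV > {II, III} > I: moves
toward I are demethylation, away from I methylation.  CHG (II) and CG (III)
carry one methylated context each and are incomparable; II <-> III is kept
as a separate interchange class, excluded from hyper/hypo percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._util import ratio_pct
from .msap import MethylationState


class TransitionClass(Enum):
    NO_CHANGE = "no_change"
    DEMETHYLATION = "demethylation"
    METHYLATION = "methylation"
    INTERCHANGE = "interchange"


class Uniformity(Enum):
    UNIFORM = "uDMF"
    DISTINCTIVE = "dDMF"


#: methylation load: number of methylated contexts at the CCGG site
_RANK = {
    MethylationState.UNMETHYLATED: 0,
    MethylationState.CHG: 1,
    MethylationState.CG: 1,
    MethylationState.CG_CHG: 2,
}


def classify_transition(
    ref_state: MethylationState, sample_state: MethylationState
) -> TransitionClass:
    """Classify one ordered (reference, sample) state pair.

    Over the 16 ordered pairs this yields 4 no-change, 5 demethylation,
    5 methylation and 2 interchange transitions.
    """
    if ref_state is sample_state:
        return TransitionClass.NO_CHANGE
    r, s = _RANK[ref_state], _RANK[sample_state]
    if r == s:
        return TransitionClass.INTERCHANGE
    return TransitionClass.DEMETHYLATION if s < r else TransitionClass.METHYLATION


def transition_taxonomy() -> dict[TransitionClass, list[tuple[MethylationState, MethylationState]]]:
    """Enumerate all 16 ordered state pairs grouped by transition class."""
    groups: dict[TransitionClass, list[tuple[MethylationState, MethylationState]]] = {
        cls: [] for cls in TransitionClass
    }
    for ref in MethylationState:
        for sample in MethylationState:
            groups[classify_transition(ref, sample)].append((ref, sample))
    return groups


@dataclass(frozen=True)
class TransitionRecord:
    locus_id: str
    individual_id: str
    ref_state: MethylationState
    sample_state: MethylationState
    cls: TransitionClass


@dataclass
class DMFRecord:
    """One differentially methylated locus with its per-individual states."""

    locus_id: str
    ref_state: MethylationState
    states: dict[str, Optional[MethylationState]]
    uniformity: Uniformity
    variant_state: Optional[MethylationState]  # defined only for uniform DMFs


StateMap = Mapping[str, Optional[MethylationState]]
PopulationMap = Mapping[str, StateMap]


def _check_panel(ref: StateMap, population: PopulationMap) -> None:
    ref_loci = set(ref)
    for indiv, states in population.items():
        if set(states) != ref_loci:
            raise ValueError(f"locus panel of individual {indiv!r} differs from reference")


def classify_population(ref: StateMap, population: PopulationMap) -> list[TransitionRecord]:
    """Per-locus, per-individual transition records (unscored loci skipped)."""
    _check_panel(ref, population)
    records = []
    for indiv in population:
        for locus in ref:
            r, s = ref[locus], population[indiv][locus]
            if r is None or s is None:
                continue
            records.append(TransitionRecord(locus, indiv, r, s, classify_transition(r, s)))
    return records


def population_pattern_table(ref: StateMap, population: PopulationMap) -> pd.DataFrame:
    """Per-individual counts and percentages of each transition class.

    Percentages are over all loci scored in both the reference and the
    individual, so the four class percentages sum to 100 per individual.
    """
    records = classify_population(ref, population)
    rows = []
    for indiv in population:
        mine = [rec for rec in records if rec.individual_id == indiv]
        n = len(mine)
        if n == 0:
            raise ValueError(f"individual {indiv!r} shares no scored loci with the reference")
        row: dict[str, object] = {"individual": indiv, "n_scored": n}
        for cls in TransitionClass:
            k = sum(rec.cls is cls for rec in mine)
            row[f"{cls.value}_count"] = k
            row[f"{cls.value}_pct"] = ratio_pct(k, n)
        rows.append(row)
    return pd.DataFrame(rows).set_index("individual")


def identify_dmfs(ref: StateMap, population: PopulationMap) -> list[DMFRecord]:
    """Find DMF loci and label each uniform or distinctive.

    A locus is a DMF if at least one scored individual's state differs from
    the reference.  It is uniform iff every scored individual differs and
    all share a single variant state; otherwise distinctive.  Uniformity is
    judged over scored individuals only.
    """
    if not population:
        raise ValueError("population must contain at least one individual")
    _check_panel(ref, population)
    dmfs: list[DMFRecord] = []
    for locus in ref:
        r = ref[locus]
        if r is None:
            continue
        states = {indiv: population[indiv][locus] for indiv in population}
        scored = {i: s for i, s in states.items() if s is not None}
        if not scored:
            continue
        changed = {i: s for i, s in scored.items() if s is not r}
        if not changed:
            continue
        variant_states = set(changed.values())
        if len(changed) == len(scored) and len(variant_states) == 1:
            uniformity = Uniformity.UNIFORM
            variant: Optional[MethylationState] = next(iter(variant_states))
        else:
            uniformity = Uniformity.DISTINCTIVE
            variant = None
        dmfs.append(DMFRecord(locus, r, states, uniformity, variant))
    return dmfs


def partition_summary(dmfs: Sequence[DMFRecord]) -> dict[str, float | int]:
    """Counts and uniform/distinctive percentages of a DMF list."""
    n_uniform = sum(d.uniformity is Uniformity.UNIFORM for d in dmfs)
    n_total = len(dmfs)
    out: dict[str, float | int] = {
        "n_dmfs": n_total,
        "n_uniform": n_uniform,
        "n_distinctive": n_total - n_uniform,
    }
    if n_total:
        out["uniform_pct"] = ratio_pct(n_uniform, n_total)
        out["distinctive_pct"] = ratio_pct(n_total - n_uniform, n_total)
    return out
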