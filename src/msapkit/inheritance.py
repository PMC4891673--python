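"""Transgenerational retention of uniform-DMF variant states.

For each uniform DMF the first selfed generation fixed a variant state at
the locus; later generations are scored for how many individuals still
carry that exact state.  Per-generation retention ratios classify each
locus as stable (retained by every individual in every generation),
reverting (partially retained) or lost (absent from the final generation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

from ._util import ratio_pct
from .msap import BandCall, MethylationState, classify_locus


class Verdict(Enum):
    STABLE = "stable"
    REVERTING = "reverting"
    LOST = "lost"


@dataclass(frozen=True)
class TransitionRatio:
    """Retention at one generation transition: pct = retained / n * 100."""

    label: str
    retained: int
    n: int
    pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.retained <= self.n):
            raise ValueError(f"retained must lie in [0, n]: {self}")


@dataclass
class GenerationPanel:
    """All scored individuals of one generation, states per tracked locus."""

    generation_id: str
    states: Mapping[str, Sequence[Optional[MethylationState]]]  # locus -> per individual

    def n_individuals(self, locus_id: str) -> int:
        return len(self.states[locus_id])


@dataclass
class InheritanceSeries:
    locus_id: str
    ref_state: MethylationState
    variant_state: MethylationState
    ratios: list[TransitionRatio]
    verdict: Verdict


def inheritance_ratio(
    panel: GenerationPanel, locus_id: str, variant_state: MethylationState, label: str = ""
) -> TransitionRatio:
    """Fraction of a generation's individuals retaining the variant state.

    Retention is exact state equality; unscored individuals are excluded
    from the denominator.
    """
    if locus_id not in panel.states:
        raise KeyError(f"locus {locus_id!r} absent from panel {panel.generation_id!r}")
    states = [s for s in panel.states[locus_id] if s is not None]
    if not states:
        raise ValueError(f"locus {locus_id!r} unscored in every individual of {panel.generation_id!r}")
    retained = sum(s is variant_state for s in states)
    n = len(states)
    return TransitionRatio(label or panel.generation_id, retained, n, ratio_pct(retained, n))


def classify_stability(ratios: Sequence[TransitionRatio]) -> Verdict:
    """Stable iff every ratio is 100%; lost iff the variant is absent from
    the final generation; reverting otherwise."""
    if not ratios:
        raise ValueError("empty ratio series")
    if all(r.retained == r.n for r in ratios):
        return Verdict.STABLE
    if ratios[-1].retained == 0:
        return Verdict.LOST
    return Verdict.REVERTING


def track_inheritance(
    manifest: Sequence[tuple[str, MethylationState, MethylationState]],
    panels: Sequence[GenerationPanel],
    origin_id: str = "GS1",
) -> list[InheritanceSeries]:
    """Build per-locus inheritance series across ordered generation panels.

    ``manifest`` rows are (locus_id, reference state, variant state); ratio
    labels are consecutive-generation pairs starting from ``origin_id``.
    """
    if not panels:
        raise ValueError("at least one generation panel required")
    series = []
    prev_ids = [origin_id] + [p.generation_id for p in panels[:-1]]
    for locus_id, ref_state, variant_state in manifest:
        ratios = [
            inheritance_ratio(panel, locus_id, variant_state, f"{prev}-{panel.generation_id}")
            for prev, panel in zip(prev_ids, panels)
        ]
        series.append(
            InheritanceSeries(locus_id, ref_state, variant_state, ratios, classify_stability(ratios))
        )
    return series


@dataclass(frozen=True)
class InheritanceSummary:
    n_series: int
    n_stable: int
    n_reverting: int
    n_lost: int
    stable_pct_of_tracked: float
    stable_pct_of_all_dmfs: Optional[float]


def summarize_inheritance(
    series: Sequence[InheritanceSeries], total_dmfs: Optional[int] = None
) -> InheritanceSummary:
    """Verdict counts plus the stable fraction of tracked loci and,
    if ``total_dmfs`` is given, of the full DMF inventory."""
    if not series:
        raise ValueError("no inheritance series supplied")
    n_stable = sum(s.verdict is Verdict.STABLE for s in series)
    n_lost = sum(s.verdict is Verdict.LOST for s in series)
    n_rev = len(series) - n_stable - n_lost
    return InheritanceSummary(
        n_series=len(series),
        n_stable=n_stable,
        n_reverting=n_rev,
        n_lost=n_lost,
        stable_pct_of_tracked=ratio_pct(n_stable, len(series)),
        stable_pct_of_all_dmfs=ratio_pct(n_stable, total_dmfs) if total_dmfs else None,
    )


# ---------------------------------------------------------------------------
# Printed-table round-trip: "pct (retained/n)" cells

_CELL_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(?:\((\d+)\s*/\s*(\d+)\))?\s*$")


def parse_ratio_cell(cell: str, label: str = "", default_n: Optional[int] = None) -> TransitionRatio:
    """Parse a report cell like ``86.67 (13/15)`` into a TransitionRatio.

    Cells printed without the fraction (``100.00``) need ``default_n`` (the
    generation's panel size).  The printed pct must equal the half-up
    rounding of retained/n.
    """
    m = _CELL_RE.match(cell)
    if not m:
        raise ValueError(f"malformed ratio cell {cell!r}")
    pct = float(m.group(1))
    if m.group(2) is not None:
        retained, n = int(m.group(2)), int(m.group(3))
    else:
        if default_n is None:
            raise ValueError(f"cell {cell!r} lacks (retained/n) and no panel size given")
        n = default_n
        retained = round(pct / 100.0 * n)
    expected = ratio_pct(retained, n)
    if abs(expected - pct) > 1e-9:
        raise ValueError(f"cell {cell!r}: printed pct {pct} != {retained}/{n} = {expected}")
    return TransitionRatio(label, retained, n, pct)


def _state_from_pair(text: str) -> MethylationState:
    h, m = (int(x) for x in re.findall(r"[01]", text))
    return classify_locus(BandCall(h, m))


def load_inheritance_table(
    path: str | Path, panel_sizes: Optional[Sequence[int]] = None
) -> list[InheritanceSeries]:
    """Load a retention table (TSV) of per-locus "pct (retained/n)" cells.

    Expected columns: ``locus``, ``ref_call``, ``variant_call`` (band pairs
    like ``(0, 1)``), then one column per generation transition.
    ``panel_sizes`` supplies denominators for cells printed without one.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus", "ref_call", "variant_call"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    ratio_cols = [c for c in df.columns if c not in required]
    if panel_sizes is not None and len(panel_sizes) != len(ratio_cols):
        raise ValueError("panel_sizes length must match the number of transition columns")
    series = []
    for _, row in df.iterrows():
        ratios = [
            parse_ratio_cell(
                row[col], col, default_n=panel_sizes[i] if panel_sizes is not None else None
            )
            for i, col in enumerate(ratio_cols)
        ]
        series.append(
            InheritanceSeries(
                locus_id=row["locus"],
                ref_state=_state_from_pair(row["ref_call"]),
                variant_state=_state_from_pair(row["variant_call"]),
                ratios=ratios,
                verdict=classify_stability(ratios),
            )
        )
    return series
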