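"""Per-cytosine methylation calling from Sanger bisulfite clones.

Clones are reads of the top strand of a PCR amplicon after bisulfite
conversion: unmethylated cytosines read as T, methylated cytosines as C.
Contexts (CG / CHG / CHH, H in {A, C, T}) are assigned from the reference
sequence only.  Alignment is global and conversion-aware — a clone T
opposite a reference C is a match, never a penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

VALID_BASES = set("ACGT")
_H = set("ACT")


class Context(Enum):
    CG = "CG"
    CHG = "CHG"
    CHH = "CHH"


class Call(Enum):
    METHYLATED = "methylated"
    UNMETHYLATED = "unmethylated"
    AMBIGUOUS = "ambiguous"


@dataclass
class Amplicon:
    """Reference amplicon with context-annotated cytosine positions.

    ``contexts`` maps 0-based reference positions of cytosines to their
    context; cytosines too close to the 3' end for the context to be
    determined are listed in ``indeterminate`` and excluded from calling.
    """

    region_id: str
    sequence: str
    contexts: dict[int, Context] = field(default_factory=dict)
    indeterminate: set[int] = field(default_factory=set)

    @property
    def cytosine_positions(self) -> list[int]:
        return sorted(self.contexts)


def assign_contexts(sequence: str, region_id: str = "region") -> Amplicon:
    """Annotate every reference cytosine with its CG / CHG / CHH context.

    CG if the next base is G; CHG if C-H-G; CHH if C-H-H.  A cytosine whose
    context cannot be resolved within the sequence (fewer than the needed
    downstream bases) is flagged indeterminate.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence must be at least 3 bases long")
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    contexts: dict[int, Context] = {}
    indeterminate: set[int] = set()
    n = len(seq)
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if i + 1 < n and seq[i + 1] == "G":
            contexts[i] = Context.CG
        elif i + 2 < n:
            contexts[i] = Context.CHG if seq[i + 2] == "G" else Context.CHH
        else:
            indeterminate.add(i)
    return Amplicon(region_id, seq, contexts, indeterminate)


def _conversion_aware_aligner() -> Align.PairwiseAligner:
    # target = reference, query = clone; asymmetric: ref C vs clone T is a
    # match (bisulfite conversion), clone C vs ref T is not.
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                matrix[a, b] = 0.0
            else:
                matrix[a, b] = 2.0 if a == b else -1.0
    matrix["C", "T"] = 2.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


_ALIGNER = _conversion_aware_aligner()


class CloneRejected(Exception):
    """Clone failed the conversion-aware identity threshold."""

    def __init__(self, clone_id: str, identity: float, threshold: float) -> None:
        self.clone_id = clone_id
        self.identity = identity
        self.threshold = threshold
        super().__init__(
            f"clone {clone_id!r} identity {identity:.3f} below threshold {threshold:.2f}"
        )


def align_clone(
    amplicon: Amplicon,
    clone: str,
    clone_id: str = "clone",
    min_identity: float = 0.90,
) -> dict[int, Call]:
    """Call methylation at every determinate reference cytosine of one clone.

    Returns position -> call: C at a reference-C position is METHYLATED,
    T is UNMETHYLATED, anything else (N, other base, deletion) AMBIGUOUS.
    Raises :class:`CloneRejected` if conversion-aware identity over the
    alignment falls below ``min_identity``.
    """
    clone_seq = clone.upper().replace("U", "T")
    if not clone_seq:
        raise ValueError("empty clone sequence")
    if set(clone_seq) - (VALID_BASES | {"N"}):
        raise ValueError("clone contains characters outside ACGTN")
    alignment = _ALIGNER.align(amplicon.sequence, clone_seq)[0]

    ref_to_clone: dict[int, str] = {}
    matches = 0
    n_neutral = 0  # N columns are neither match nor mismatch
    columns = alignment.length
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            rbase = amplicon.sequence[t0 + offset]
            qbase = clone_seq[q0 + offset]
            ref_to_clone[t0 + offset] = qbase
            if qbase == "N":
                n_neutral += 1
            elif rbase == qbase or (rbase == "C" and qbase == "T"):
                matches += 1
    scored_columns = columns - n_neutral
    identity = matches / scored_columns if scored_columns else 0.0
    if identity < min_identity:
        raise CloneRejected(clone_id, identity, min_identity)

    calls: dict[int, Call] = {}
    for pos in amplicon.cytosine_positions:
        base = ref_to_clone.get(pos)
        if base == "C":
            calls[pos] = Call.METHYLATED
        elif base == "T":
            calls[pos] = Call.UNMETHYLATED
        else:
            calls[pos] = Call.AMBIGUOUS
    return calls


@dataclass
class CloneCallMatrix:
    """clone_id x cytosine-position call matrix plus rejected clones."""

    region_id: str
    calls: dict[str, dict[int, Call]] = field(default_factory=dict)
    rejected: list[CloneRejected] = field(default_factory=list)

    @property
    def n_clones(self) -> int:
        return len(self.calls)


def call_clones(
    amplicon: Amplicon,
    clones: Iterable[tuple[str, str]],
    min_identity: float = 0.90,
) -> CloneCallMatrix:
    """Align and call a set of (clone_id, sequence) pairs against one amplicon."""
    matrix = CloneCallMatrix(amplicon.region_id)
    for clone_id, seq in clones:
        if clone_id in matrix.calls:
            raise ValueError(f"duplicate clone id {clone_id!r}")
        try:
            matrix.calls[clone_id] = align_clone(amplicon, seq, clone_id, min_identity)
        except CloneRejected as exc:
            matrix.rejected.append(exc)
    return matrix


@dataclass(frozen=True)
class ContextSummary:
    """Pooled per-context methylation percentages for one region/sample.

    ``pct`` entries are None when a context has no scored call (NA).
    """

    region_id: str
    methylated: Mapping[str, int]
    total: Mapping[str, int]
    pct: Mapping[str, Optional[float]]
    overall_methylated: int
    overall_total: int
    overall_pct: Optional[float]


def summarize_region(matrix: CloneCallMatrix, amplicon: Amplicon) -> ContextSummary:
    """Pool calls over clones into per-context methylation percentages.

    Ambiguous calls are excluded from both numerator and denominator.
    """
    if matrix.n_clones == 0:
        raise ValueError("no accepted clones to summarize")
    meth = {c.value: 0 for c in Context}
    total = {c.value: 0 for c in Context}
    for clone_calls in matrix.calls.values():
        for pos, call in clone_calls.items():
            if call is Call.AMBIGUOUS:
                continue
            ctx = amplicon.contexts[pos].value
            total[ctx] += 1
            if call is Call.METHYLATED:
                meth[ctx] += 1
    pct = {
        ctx: (meth[ctx] / total[ctx] * 100.0 if total[ctx] else None) for ctx in total
    }
    om, ot = sum(meth.values()), sum(total.values())
    return ContextSummary(
        region_id=matrix.region_id,
        methylated=meth,
        total=total,
        pct=pct,
        overall_methylated=om,
        overall_total=ot,
        overall_pct=om / ot * 100.0 if ot else None,
    )


def compare_regions(a: ContextSummary, b: ContextSummary) -> dict[str, Optional[float]]:
    """Percentage-point differences (a - b) per context and overall.

    An NA context on either side yields an NA (None) difference.
    """
    if a.region_id != b.region_id:
        raise ValueError(f"summaries are for different regions: {a.region_id!r} vs {b.region_id!r}")
    diff: dict[str, Optional[float]] = {}
    for ctx in a.pct:
        pa, pb = a.pct[ctx], b.pct.get(ctx)
        diff[ctx] = None if pa is None or pb is None else pa - pb
    if a.overall_pct is None or b.overall_pct is None:
        diff["overall"] = None
    else:
        diff["overall"] = a.overall_pct - b.overall_pct
    return diff


def conversion_efficiency(
    matrix: CloneCallMatrix,
    amplicon: Amplicon,
    assumed_unmethylated: Sequence[Context] = (Context.CHH,),
) -> float:
    """Estimate bisulfite conversion from contexts assumed unmethylated.

    Rate = T-calls / scored calls at cytosines of the designated contexts
    (default CHH); a QC proxy for the chemical conversion step.
    """
    wanted = set(assumed_unmethylated)
    t_calls = scored = 0
    for clone_calls in matrix.calls.values():
        for pos, call in clone_calls.items():
            if amplicon.contexts[pos] not in wanted or call is Call.AMBIGUOUS:
                continue
            scored += 1
            if call is Call.UNMETHYLATED:
                t_calls += 1
    if scored == 0:
        raise ValueError("no scored calls in the designated contexts")
    return t_calls / scored


def lollipop_text(matrix: CloneCallMatrix, amplicon: Amplicon) -> str:
    """Plain-text clone x cytosine matrix: ● methylated, ○ unmethylated, · ambiguous."""
    glyph = {Call.METHYLATED: "●", Call.UNMETHYLATED: "○", Call.AMBIGUOUS: "·"}
    positions = amplicon.cytosine_positions
    lines = ["\t".join(["clone"] + [str(p + 1) for p in positions])]
    for clone_id in sorted(matrix.calls):
        row = [glyph[matrix.calls[clone_id][p]] for p in positions]
        lines.append("\t".join([clone_id] + row))
    return "\n".join(lines) + "\n"
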