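"""siRNA differential expression and exact matching against DMF sequences.

Counts are compared between two library groups with a pooled two-sided
exact binomial test against the library-size-proportional null, BH-adjusted
across records.  A record is differentially expressed when
|log2 fold change| >= 1 and adjusted p < 0.05.  Differential siRNAs are
then matched to DMF sequences by exact substring search on both strands.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

MIN_LENGTH, MAX_LENGTH = 18, 30

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U onto T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return normalize_sequence(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SirnaRecord:
    """One small-RNA sequence with raw counts per library."""

    sequence: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
            raise ValueError(
                f"siRNA length {len(seq)} outside [{MIN_LENGTH}, {MAX_LENGTH}]: {seq!r}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return len(self.sequence)


class Direction(Enum):
    UP = "up"
    DOWN = "down"
    NS = "ns"


@dataclass
class DEResult:
    sequence: str
    length: int
    log2_fold_change: float
    p_value: float
    adjusted_p: Optional[float]
    direction: Direction


def normalize(count: float, library_size: float) -> float:
    """Counts per million: count / library_size * 1e6."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / library_size * 1e6


def _group_totals(
    record: SirnaRecord, libs: Sequence[str], library_sizes: Mapping[str, int]
) -> tuple[int, int]:
    count = sum(record.counts.get(lib, 0) for lib in libs)
    size = sum(library_sizes[lib] for lib in libs)
    return count, size


def de_test(
    record: SirnaRecord,
    group_a: Sequence[str],
    group_b: Sequence[str],
    library_sizes: Mapping[str, int],
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Pooled (log2FC, p) for one record: group A over group B.

    log2FC uses pooled cpm with the pseudocount added to both sides; the
    p-value is a two-sided exact binomial test of the pooled group-A count
    against the library-size-proportional expectation and takes no
    pseudocount.
    """
    if not group_a or not group_b:
        raise ValueError("both groups need at least one library")
    ca, sa = _group_totals(record, group_a, library_sizes)
    cb, sb = _group_totals(record, group_b, library_sizes)
    if sa <= 0 or sb <= 0:
        raise ValueError("zero group library size")
    cpm_a, cpm_b = normalize(ca, sa), normalize(cb, sb)
    log2fc = float(np.log2((cpm_a + pseudocount) / (cpm_b + pseudocount)))
    total = ca + cb
    if total == 0:
        raise ValueError("record absent from every library")
    p_null = sa / (sa + sb)
    p = stats.binomtest(ca, total, p_null, alternative="two-sided").pvalue
    return log2fc, float(p)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH adjusted p-values (monotone, rank-preserving)."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


def differential_expression(
    records: Iterable[SirnaRecord],
    group_a: Sequence[str],
    group_b: Sequence[str],
    library_sizes: Mapping[str, int],
    *,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> list[DEResult]:
    """Test every record and BH-adjust across the tested set.

    Records with zero counts in all libraries are excluded (untestable).
    Direction is UP/DOWN only when |log2FC| >= ``lfc_threshold`` and
    adjusted p < ``alpha``.
    """
    tested: list[tuple[SirnaRecord, float, float]] = []
    for record in records:
        if sum(record.counts.get(lib, 0) for lib in list(group_a) + list(group_b)) == 0:
            continue
        log2fc, p = de_test(record, group_a, group_b, library_sizes, pseudocount)
        tested.append((record, log2fc, p))
    if not tested:
        return []
    adjusted = benjamini_hochberg([p for _, _, p in tested])
    results = []
    for (record, log2fc, p), adj in zip(tested, adjusted):
        if adj < alpha and log2fc >= lfc_threshold:
            direction = Direction.UP
        elif adj < alpha and log2fc <= -lfc_threshold:
            direction = Direction.DOWN
        else:
            direction = Direction.NS
        results.append(
            DEResult(record.sequence, record.length, log2fc, p, float(adj), direction)
        )
    return results


@dataclass(frozen=True)
class DmfMatch:
    """Exact occurrence of an siRNA (or its reverse complement) in a DMF."""

    sirna: str
    dmf_id: str
    offset: int  # 0-based start within the DMF sequence
    strand: str  # '+' or '-'


def _occurrences(needle: str, haystack: str, max_mismatches: int) -> list[int]:
    if max_mismatches == 0:
        hits, start = [], haystack.find(needle)
        while start != -1:
            hits.append(start)
            start = haystack.find(needle, start + 1)
        return hits
    k = len(needle)
    return [
        i
        for i in range(len(haystack) - k + 1)
        if sum(a != b for a, b in zip(needle, haystack[i : i + k])) <= max_mismatches
    ]


def match_to_dmfs(
    sirnas: Iterable[str],
    dmf_sequences: Mapping[str, str],
    max_mismatches: int = 0,
) -> list[DmfMatch]:
    """Search each siRNA and its reverse complement in every DMF sequence.

    All occurrences are reported; U is treated as T.  ``max_mismatches``
    (default 0, exact) allows exploratory inexact matching.
    """
    dmfs = {dmf_id: normalize_sequence(seq) for dmf_id, seq in dmf_sequences.items()}
    for dmf_id, seq in dmfs.items():
        if set(seq) - set("ACGT"):
            raise ValueError(f"DMF {dmf_id!r} contains non-ACGT characters")
    matches = []
    for raw in sirnas:
        sirna = normalize_sequence(raw)
        for dmf_id, seq in dmfs.items():
            for offset in _occurrences(sirna, seq, max_mismatches):
                matches.append(DmfMatch(sirna, dmf_id, offset, "+"))
            rc = reverse_complement(sirna)
            for offset in _occurrences(rc, seq, max_mismatches):
                matches.append(DmfMatch(sirna, dmf_id, offset, "-"))
    return matches


def length_stratify(matches: Iterable[DmfMatch]) -> dict[int, int]:
    """Count distinct matched siRNA sequences per length (24 nt flags RdDM)."""
    by_length = Counter(len(s) for s in {m.sirna for m in matches})
    return dict(sorted(by_length.items()))
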