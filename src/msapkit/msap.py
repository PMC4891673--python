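"""Dual-digest (HpaII / MspI) band scoring into cytosine-methylation states.

Each MSAP locus in each sample carries two binary band calls: presence in
the EcoRI+HpaII digest (``h``) and presence in the EcoRI+MspI digest
(``m``).  The joint pattern encodes one of four methylation states of the
CCGG site; per-sample state counts yield the total- and fully-methylated
band ratios.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from ._util import ratio_pct


class UnscoredCallError(ValueError):
    """Raised when a band call with missing data is classified."""


@dataclass(frozen=True)
class BandCall:
    """Presence (1) / absence (0) of the two digest bands at one locus.

    ``None`` in either lane marks the locus as unscored for that sample;
    unscored loci are excluded from state counts, never coerced to 0.
    """

    h_present: Optional[int]
    m_present: Optional[int]

    def __post_init__(self) -> None:
        for lane, value in (("h_present", self.h_present), ("m_present", self.m_present)):
            if value is not None and value not in (0, 1):
                raise ValueError(f"{lane} must be 0, 1 or None, got {value!r}")

    @property
    def is_scored(self) -> bool:
        return self.h_present is not None and self.m_present is not None


UNSCORED = BandCall(None, None)


class MethylationState(Enum):
    """The four MSAP states, keyed by their (H, M) band pattern.

    I  (1,1) unmethylated; II (1,0) CHG-methylated; III (0,1) CG-methylated;
    IV (0,0) methylated at both CG and CHG (no bands in either digest).
    """

    UNMETHYLATED = ("I", 1, 1)
    CHG = ("II", 1, 0)
    CG = ("III", 0, 1)
    CG_CHG = ("IV", 0, 0)

    def __init__(self, roman: str, h: int, m: int) -> None:
        self.roman = roman
        self._h = h
        self._m = m

    @property
    def band_call(self) -> BandCall:
        return BandCall(self._h, self._m)

    @classmethod
    def from_call(cls, call: BandCall) -> "MethylationState":
        return classify_locus(call)


_STATE_BY_BANDS = {
    (1, 1): MethylationState.UNMETHYLATED,
    (1, 0): MethylationState.CHG,
    (0, 1): MethylationState.CG,
    (0, 0): MethylationState.CG_CHG,
}


def classify_locus(call: BandCall) -> MethylationState:
    """Map a scored (H, M) band pair onto its methylation state.

    (1,1) -> I unmethylated, (1,0) -> II CHG, (0,1) -> III CG,
    (0,0) -> IV CG/CHG.  Raises :class:`UnscoredCallError` for missing data.
    """
    if not call.is_scored:
        raise UnscoredCallError("cannot classify an unscored band call")
    return _STATE_BY_BANDS[(call.h_present, call.m_present)]


@dataclass
class SampleProfile:
    """Per-sample methylation-state counts over a locus panel."""

    sample_id: str
    counts: dict[MethylationState, int] = field(default_factory=dict)
    n_loci: int = 0

    def __post_init__(self) -> None:
        for state in MethylationState:
            self.counts.setdefault(state, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("state counts must be non-negative")
        if self.n_scored > self.n_loci:
            raise ValueError("scored counts exceed n_loci")

    @property
    def n_scored(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unscored(self) -> int:
        return self.n_loci - self.n_scored


def profile_sample(column: Sequence[BandCall], sample_id: str) -> SampleProfile:
    """Count methylation states over one sample's band-call column.

    Unscored calls are recorded in ``n_loci`` but excluded from counts.
    """
    if len(column) == 0:
        raise ValueError(f"empty band-call column for sample {sample_id!r}")
    counts: Counter[MethylationState] = Counter()
    for call in column:
        if call.is_scored:
            counts[classify_locus(call)] += 1
    return SampleProfile(sample_id=sample_id, counts=dict(counts), n_loci=len(column))


@dataclass(frozen=True)
class RatioSummary:
    """Total / fully methylated band counts and percentages for one sample.

    ``*_pct`` fields are rounded half-up to 2 decimals for reports;
    ``*_raw`` retain the unrounded values for downstream computation.
    """

    sample_id: str
    total_methylated_bands: int
    total_ratio_pct: float
    full_methylated_bands: int
    full_ratio_pct: float
    total_ratio_raw: float
    full_ratio_raw: float
    n_scored: int


def methylation_ratios(profile: SampleProfile) -> RatioSummary:
    """Compute total (II+III+IV) and fully (III+IV) methylated band ratios.

    Ratios are over scored loci only: ratio = bands / (I+II+III+IV) * 100.
    """
    n = profile.n_scored
    if n == 0:
        raise ValueError(f"sample {profile.sample_id!r} has zero scored loci")
    c = profile.counts
    total = c[MethylationState.CHG] + c[MethylationState.CG] + c[MethylationState.CG_CHG]
    full = c[MethylationState.CG] + c[MethylationState.CG_CHG]
    return RatioSummary(
        sample_id=profile.sample_id,
        total_methylated_bands=total,
        total_ratio_pct=ratio_pct(total, n),
        full_methylated_bands=full,
        full_ratio_pct=ratio_pct(full, n),
        total_ratio_raw=total / n * 100.0,
        full_ratio_raw=full / n * 100.0,
        n_scored=n,
    )


@dataclass(frozen=True)
class LevelComparison:
    statistic: float
    p_value: float
    significant: bool
    method: str
    alpha: float


def compare_levels(
    ref: SampleProfile,
    other: SampleProfile,
    *,
    method: str = "fisher",
    alpha: float = 0.05,
) -> LevelComparison:
    """Test the methylated-vs-unmethylated band split between two samples.

    Builds the 2x2 table [methylated (II+III+IV), unmethylated (I)] x sample
    and applies Fisher's exact test (default) or the chi-square test.  The
    two profiles must share the locus panel (equal ``n_loci``).
    """
    if ref.n_loci != other.n_loci:
        raise ValueError(
            f"locus panels differ: {ref.sample_id!r} has {ref.n_loci}, "
            f"{other.sample_id!r} has {other.n_loci}"
        )

    def split(p: SampleProfile) -> tuple[int, int]:
        meth = p.n_scored - p.counts[MethylationState.UNMETHYLATED]
        return meth, p.counts[MethylationState.UNMETHYLATED]

    table = [list(split(ref)), list(split(other))]
    if method == "fisher":
        res = stats.fisher_exact(table)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "chi2":
        res = stats.chi2_contingency(table)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return LevelComparison(statistic, p, p < alpha, method, alpha)


def consensus_call(replicates: Iterable[BandCall]) -> BandCall:
    """Majority vote over technical-replicate band calls for one locus.

    Unscored replicates are ignored; a tie for the most frequent scored
    (H, M) pair — or no scored replicate at all — yields an unscored call.
    """
    votes = Counter(
        (c.h_present, c.m_present) for c in replicates if c.is_scored
    )
    if not votes:
        return UNSCORED
    ranked = votes.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return UNSCORED
    h, m = ranked[0][0]
    return BandCall(h, m)


def states_from_calls(
    calls: Mapping[str, BandCall]
) -> dict[str, Optional[MethylationState]]:
    """Convert a locus -> BandCall map to locus -> state (None if unscored)."""
    return {
        locus: classify_locus(call) if call.is_scored else None
        for locus, call in calls.items()
    }
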