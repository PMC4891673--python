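"""Synthetic inputs with machine-readable ground truth for every stage.

Each generator is driven by a single seed through spawned child streams,
so sub-draws are reproducible regardless of draw order, and each emits a
truth structure sufficient to score its consuming analysis exactly.

Default parameters are calibrated to the scale of the grafting study this
package targets: 926 loci, 7 first-generation individuals, 76 DMFs of
which 32 uniform, later panels of 15/15/10/10 individuals, >= 10 bisulfite
clones, 18-30 nt small RNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .bisulfite import Amplicon, Context, assign_contexts
from .inheritance import GenerationPanel
from .msap import MethylationState
from .patterns import TransitionClass, Uniformity, classify_transition
from .sirna import SirnaRecord

_STATES = list(MethylationState)


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# MSAP band matrices


@dataclass
class BandSimParams:
    n_loci: int = 926
    n_individuals: int = 7
    state_frequencies: Sequence[float] = (0.53, 0.15, 0.31, 0.01)  # I, II, III, IV
    change_rate: float = 76 / 926
    uniform_fraction: float = 32 / 76
    demethylation_odds: float = 1.8  # demethylation : methylation weight
    exact_counts: bool = False  # round expected counts instead of Bernoulli draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_individuals < 1:
            raise ValueError("n_loci and n_individuals must be >= 1")
        freqs = np.asarray(self.state_frequencies, dtype=float)
        if freqs.shape != (4,) or (freqs < 0).any() or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("state_frequencies must be a 4-vector summing to 1")
        for name in ("change_rate", "uniform_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.demethylation_odds <= 0:
            raise ValueError("demethylation_odds must be positive")
        if self.change_rate > 0 and self.n_loci * self.change_rate < 1 and self.exact_counts:
            raise ValueError("change_rate too small to plant any change at this n_loci")


@dataclass
class PlantedDmf:
    locus_id: str
    ref_state: MethylationState
    uniformity: Uniformity
    variant_state: MethylationState
    individuals: list[str]  # carriers of the variant state
    cls: TransitionClass


@dataclass
class BandSimResult:
    ref: dict[str, MethylationState]
    population: dict[str, dict[str, MethylationState]]  # individual -> locus -> state
    truth: list[PlantedDmf]
    individuals: list[str]


def _draw_variant(
    rng: np.random.Generator, ref_state: MethylationState, odds: float
) -> MethylationState:
    candidates = [s for s in _STATES if s is not ref_state]
    weights = []
    for s in candidates:
        cls = classify_transition(ref_state, s)
        weights.append(odds if cls is TransitionClass.DEMETHYLATION else 1.0)
    w = np.asarray(weights) / sum(weights)
    return candidates[rng.choice(len(candidates), p=w)]


def gen_band_matrices(params: BandSimParams) -> BandSimResult:
    """Simulate a reference column and a population matrix with planted DMFs.

    Changed loci are drawn at ``change_rate``; a ``uniform_fraction`` of
    them flips identically in all individuals, the rest in a random
    nonempty proper subset (distinctive by construction when
    ``n_individuals`` > 1).  The truth table lists every planted DMF.
    """
    rng_states, rng_change, rng_variant, rng_subset = _rngs(params.seed, 4)
    loci = [f"L{i + 1:04d}" for i in range(params.n_loci)]
    individuals = [f"GS1-{i + 1}" for i in range(params.n_individuals)]
    state_idx = rng_states.choice(4, size=params.n_loci, p=np.asarray(params.state_frequencies))
    ref = {locus: _STATES[i] for locus, i in zip(loci, state_idx)}

    if params.exact_counts:
        n_changed = round(params.change_rate * params.n_loci)
        n_uniform = round(params.uniform_fraction * n_changed)
        changed = list(rng_change.choice(params.n_loci, size=n_changed, replace=False))
        uniform_set = set(
            np.asarray(changed)[rng_change.choice(n_changed, size=n_uniform, replace=False)]
        ) if n_changed else set()
    else:
        changed = [i for i in range(params.n_loci) if rng_change.random() < params.change_rate]
        uniform_set = {i for i in changed if rng_change.random() < params.uniform_fraction}

    population = {indiv: dict(ref) for indiv in individuals}
    truth: list[PlantedDmf] = []
    for i in sorted(changed):
        locus = loci[i]
        ref_state = ref[locus]
        variant = _draw_variant(rng_variant, ref_state, params.demethylation_odds)
        if i in uniform_set or params.n_individuals == 1:
            carriers = list(individuals)
            uniformity = Uniformity.UNIFORM
        else:
            size = int(rng_subset.integers(1, params.n_individuals))  # proper subset
            idx = rng_subset.choice(params.n_individuals, size=size, replace=False)
            carriers = [individuals[j] for j in sorted(idx)]
            uniformity = Uniformity.DISTINCTIVE
        for indiv in carriers:
            population[indiv][locus] = variant
        truth.append(
            PlantedDmf(
                locus, ref_state, uniformity, variant, carriers,
                classify_transition(ref_state, variant),
            )
        )
    return BandSimResult(ref, population, truth, individuals)


# ---------------------------------------------------------------------------
# Generation panels


@dataclass
class GenerationSimParams:
    panel_sizes: Sequence[int] = (15, 15, 10, 10)
    reversion_probability: float = 0.05
    generation_ids: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.panel_sizes or any(n < 1 for n in self.panel_sizes):
            raise ValueError("panel sizes must all be >= 1")
        if not 0 <= self.reversion_probability <= 1:
            raise ValueError("reversion_probability must lie in [0, 1]")
        if self.generation_ids is None:
            self.generation_ids = [f"GS{i + 2}" for i in range(len(self.panel_sizes))]
        elif len(self.generation_ids) != len(self.panel_sizes):
            raise ValueError("generation_ids must match panel_sizes in length")


@dataclass
class GenerationSimResult:
    panels: list[GenerationPanel]
    truth_stable: dict[str, bool]  # locus -> no reversion sampled anywhere


def gen_generation_panels(
    params: GenerationSimParams,
    manifest: Sequence[tuple[str, MethylationState, MethylationState]],
) -> GenerationSimResult:
    """Simulate per-generation panels where each individual independently
    reverts each variant locus to its reference state with the stated
    probability; truth marks a locus stable iff no reversion was sampled."""
    if not manifest:
        raise ValueError("empty locus manifest")
    (rng,) = _rngs(params.seed, 1)
    stable = {locus: True for locus, _, _ in manifest}
    panels = []
    for gen_id, n in zip(params.generation_ids, params.panel_sizes):  # type: ignore[arg-type]
        states: dict[str, list[Optional[MethylationState]]] = {}
        for locus, ref_state, variant_state in manifest:
            reverted = rng.random(n) < params.reversion_probability
            if reverted.any():
                stable[locus] = False
            states[locus] = [ref_state if r else variant_state for r in reverted]
        panels.append(GenerationPanel(gen_id, states))
    return GenerationSimResult(panels, stable)


# ---------------------------------------------------------------------------
# Bisulfite clones


@dataclass
class BisulfiteSimParams:
    amplicon_length: int = 400
    p_cg: float = 0.8
    p_chg: float = 0.4
    p_chh: float = 0.1
    conversion_rate: float = 1.0
    n_clones: int = 50
    region_id: str = "region1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplicon_length < 3:
            raise ValueError("amplicon_length must be >= 3")
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        for name in ("p_cg", "p_chg", "p_chh", "conversion_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class BisulfiteSimResult:
    amplicon: Amplicon
    clones: list[tuple[str, str]]
    truth_methylated: dict[str, set[int]]  # clone -> methylated reference-C positions


def gen_bisulfite_clones(params: BisulfiteSimParams) -> BisulfiteSimResult:
    """Simulate bisulfite clones of a random amplicon.

    Per clone, each reference cytosine is methylated by a Bernoulli draw
    with its context's probability; unmethylated cytosines convert to T
    with probability ``conversion_rate``.  Non-C bases are copied verbatim
    (no sequencing error or indels).
    """
    rng_seq, rng_meth, rng_conv = _rngs(params.seed, 3)
    sequence = "".join(rng_seq.choice(list("ACGT"), size=params.amplicon_length))
    amplicon = assign_contexts(sequence, params.region_id)
    p_by_context = {Context.CG: params.p_cg, Context.CHG: params.p_chg, Context.CHH: params.p_chh}

    clones: list[tuple[str, str]] = []
    truth: dict[str, set[int]] = {}
    for k in range(params.n_clones):
        clone_id = f"{params.region_id}_clone{k + 1:03d}"
        bases = list(sequence)
        methylated: set[int] = set()
        for pos in range(len(sequence)):
            if sequence[pos] != "C":
                continue
            ctx = amplicon.contexts.get(pos)
            p = p_by_context[ctx] if ctx is not None else params.p_chh
            if rng_meth.random() < p:
                methylated.add(pos)
            elif rng_conv.random() < params.conversion_rate:
                bases[pos] = "T"
        clones.append((clone_id, "".join(bases)))
        truth[clone_id] = methylated
    return BisulfiteSimResult(amplicon, clones, truth)


# ---------------------------------------------------------------------------
# siRNA count tables


@dataclass
class SirnaSimParams:
    n_records: int = 2000
    length_low: int = 18
    length_high: int = 30
    mean_count: float = 200.0
    dispersion: float = 0.0  # NB dispersion of per-record totals; 0 = Poisson
    library_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"A1": 1_000_000, "A2": 1_000_000, "B1": 1_000_000, "B2": 1_000_000}
    )
    group_a: Sequence[str] = ("A1", "A2")
    group_b: Sequence[str] = ("B1", "B2")
    n_spiked: int = 0
    spike_log2fc: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if not (18 <= self.length_low <= self.length_high <= 30):
            raise ValueError("length bounds must satisfy 18 <= low <= high <= 30")
        if any(s <= 0 for s in self.library_sizes.values()):
            raise ValueError("library sizes must be positive")
        if self.n_spiked > self.n_records:
            raise ValueError("n_spiked cannot exceed n_records")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SirnaSimResult:
    records: list[SirnaRecord]
    spiked: set[str]  # sequences with a true fold change
    planted_matches: dict[str, tuple[str, int, str]]  # sirna -> (dmf_id, offset, strand)


def _random_sequences(rng: np.random.Generator, n: int, low: int, high: int) -> list[str]:
    seqs: set[str] = set()
    while len(seqs) < n:
        length = int(rng.integers(low, high + 1))
        seqs.add("".join(rng.choice(list("ACGT"), size=length)))
    return sorted(seqs)


def gen_sirna_counts(
    params: SirnaSimParams,
    dmf_sequences: Optional[Mapping[str, str]] = None,
    n_planted: int = 0,
    planted_length: int = 24,
) -> SirnaSimResult:
    """Simulate an siRNA count table with optional spiked fold changes.

    Per-record total counts are Poisson (or gamma-Poisson when
    ``dispersion`` > 0) around ``mean_count`` and split multinomially
    across libraries in proportion to library size; spiked records weight
    group-A libraries by ``2**spike_log2fc``, so under the null the
    group split is exactly binomial.  With ``dmf_sequences``, ``n_planted``
    spiked records are exact substrings of the given DMFs.
    """
    rng_seq, rng_tot, rng_split, rng_plant = _rngs(params.seed, 4)
    if n_planted and not dmf_sequences:
        raise ValueError("n_planted requires dmf_sequences")
    if n_planted > params.n_spiked:
        raise ValueError("planted records must be spiked (n_planted <= n_spiked)")

    planted: dict[str, tuple[str, int, str]] = {}
    sequences: list[str] = []
    if n_planted:
        dmf_ids = sorted(dmf_sequences)  # type: ignore[arg-type]
        for _ in range(n_planted):
            dmf_id = dmf_ids[int(rng_plant.integers(len(dmf_ids)))]
            seq = dmf_sequences[dmf_id].upper()  # type: ignore[index]
            if len(seq) < planted_length:
                raise ValueError(f"DMF {dmf_id!r} shorter than planted_length")
            for _attempt in range(1000):
                offset = int(rng_plant.integers(0, len(seq) - planted_length + 1))
                sub = seq[offset : offset + planted_length]
                if sub not in planted:
                    break
            planted[sub] = (dmf_id, offset, "+")
            sequences.append(sub)
    sequences += _random_sequences(
        rng_seq, params.n_records - len(sequences), params.length_low, params.length_high
    )
    spiked = set(sequences[: params.n_spiked])  # planted records come first

    libs = list(params.library_sizes)
    sizes = np.array([params.library_sizes[lib] for lib in libs], dtype=float)
    group_a = set(params.group_a)
    records = []
    for seq in sequences:
        if params.dispersion > 0:
            lam = rng_tot.gamma(1.0 / params.dispersion, params.mean_count * params.dispersion)
        else:
            lam = params.mean_count
        total = int(rng_tot.poisson(lam))
        weights = sizes * np.array(
            [2.0 ** params.spike_log2fc if (seq in spiked and lib in group_a) else 1.0
             for lib in libs]
        )
        split = rng_split.multinomial(total, weights / weights.sum())
        records.append(SirnaRecord(seq, dict(zip(libs, (int(c) for c in split)))))
    return SirnaSimResult(records, spiked, planted)
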