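"""Readers, writers, run configuration and pipeline orchestration.

Band matrices travel as TSV with a ``locus_id`` column followed by paired
``<sample>_H`` / ``<sample>_M`` columns holding 0, 1 or NA.  Sequences are
plain FASTA.  Reports are TSV plus JSON carrying a schema version, with
deterministic row ordering so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .msap import BandCall, MethylationState, UNSCORED

SCHEMA_VERSION = 1

logger = logging.getLogger("msapkit")


def setup_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# Band matrices


@dataclass
class BandMatrix:
    """Loci x samples table of band calls."""

    loci: list[str]
    samples: list[str]
    calls: dict[str, dict[str, BandCall]]  # sample -> locus -> call

    def column(self, sample: str) -> list[BandCall]:
        return [self.calls[sample][locus] for locus in self.loci]

    def states(self, sample: str) -> dict[str, Optional[MethylationState]]:
        from .msap import states_from_calls

        return states_from_calls(self.calls[sample])


_NA_VALUES = {"NA", "NaN", "nan", ""}


def _parse_cell(value: object, locus: str, column: str) -> Optional[int]:
    text = "" if value is None or (isinstance(value, float) and pd.isna(value)) else str(value).strip()
    if text in _NA_VALUES:
        return None
    if text in {"0", "1"}:
        return int(text)
    raise ValueError(f"non-binary cell {text!r} at locus {locus!r}, column {column!r}")


def read_band_matrix(path: str | Path) -> BandMatrix:
    """Read a band-matrix TSV, validating binarity and locus uniqueness."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "locus_id" not in df.columns:
        raise ValueError(f"{path}: missing 'locus_id' column")
    loci = df["locus_id"].tolist()
    dupes = {l for l in loci if loci.count(l) > 1} if len(set(loci)) != len(loci) else set()
    if dupes:
        raise ValueError(f"{path}: duplicate locus ids {sorted(dupes)}")
    lanes = [c for c in df.columns if c != "locus_id"]
    samples = []
    for col in lanes:
        if not (col.endswith("_H") or col.endswith("_M")):
            raise ValueError(f"{path}: column {col!r} is not of the form <sample>_H or <sample>_M")
        sample = col[:-2]
        if sample not in samples:
            samples.append(sample)
    for sample in samples:
        for suffix in ("_H", "_M"):
            if f"{sample}{suffix}" not in df.columns:
                raise ValueError(f"{path}: sample {sample!r} lacks the {suffix} column")
    calls: dict[str, dict[str, BandCall]] = {s: {} for s in samples}
    columns = {col: df[col].tolist() for col in df.columns}
    for i, locus in enumerate(loci):
        for sample in samples:
            h = _parse_cell(columns[f"{sample}_H"][i], locus, f"{sample}_H")
            m = _parse_cell(columns[f"{sample}_M"][i], locus, f"{sample}_M")
            # one lane missing makes the whole call unscorable
            calls[sample][locus] = BandCall(h, m) if h is not None and m is not None else UNSCORED
    return BandMatrix(loci, samples, calls)


def write_band_matrix(
    path: str | Path,
    loci: Sequence[str],
    states: Mapping[str, Mapping[str, Optional[MethylationState]]],
) -> None:
    """Write sample -> locus -> state maps as a band-matrix TSV."""
    samples = list(states)
    columns: dict[str, list[str]] = {"locus_id": list(loci)}
    for sample in samples:
        h_col, m_col = [], []
        for locus in loci:
            state = states[sample].get(locus)
            if state is None:
                h_col.append("NA")
                m_col.append("NA")
            else:
                call = state.band_call
                h_col.append(str(call.h_present))
                m_col.append(str(call.m_present))
        columns[f"{sample}_H"] = h_col
        columns[f"{sample}_M"] = m_col
    pd.DataFrame(columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence map; duplicate ids error."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Reports


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(payload: dict, path: str | Path) -> None:
    body = {"schema_version": SCHEMA_VERSION, **payload}
    Path(path).write_text(json.dumps(body, indent=2, sort_keys=True) + "\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class RunConfig:
    """Pipeline configuration; every analysis threshold lives here."""

    band_matrix: Optional[str] = None
    reference_sample: Optional[str] = None
    inherit_panels: Optional[str] = None  # long TSV: generation, individual, locus, H, M
    inherit_manifest: Optional[str] = None  # TSV: locus, ref_call, variant_call
    bisulfite_reference: Optional[str] = None
    bisulfite_clones: Optional[str] = None
    sirna_counts: Optional[str] = None
    library_sizes: Optional[str] = None
    group_a: tuple[str, ...] = ()
    group_b: tuple[str, ...] = ()
    dmf_fasta: Optional[str] = None
    out_dir: str = "msapkit_out"
    alpha: float = 0.05
    lfc_threshold: float = 1.0
    clone_identity: float = 0.90
    pseudocount: float = 0.5
    max_mismatches: int = 0
    seed: int = 0
    stages: tuple[str, ...] = ("score", "patterns", "inherit", "bisulfite", "sirna")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_threshold < 0 or self.pseudocount < 0 or self.max_mismatches < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0 < self.clone_identity <= 1:
            raise ValueError("clone_identity must lie in (0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a plain ``key = value`` config file (lists comma-separated)."""
        kwargs: dict[str, object] = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            if key in ("group_a", "group_b", "stages"):
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key in ("alpha", "lfc_threshold", "clone_identity", "pseudocount"):
                kwargs[key] = float(value)
            elif key in ("seed", "max_mismatches"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            if isinstance(value, tuple):
                value = ",".join(value)
            lines.append(f"{f.name} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pipeline


def _stage_score(config: RunConfig, out: Path) -> None:
    from .msap import methylation_ratios, profile_sample

    matrix = read_band_matrix(config.band_matrix)  # type: ignore[arg-type]
    rows = []
    for sample in matrix.samples:
        profile = profile_sample(matrix.column(sample), sample)
        ratios = methylation_ratios(profile)
        rows.append(
            {
                "sample": sample,
                **{s.roman: profile.counts[s] for s in MethylationState},
                "n_loci": profile.n_loci,
                "n_scored": profile.n_scored,
                "total_methylated_bands": ratios.total_methylated_bands,
                "total_ratio_pct": ratios.total_ratio_pct,
                "full_methylated_bands": ratios.full_methylated_bands,
                "full_ratio_pct": ratios.full_ratio_pct,
            }
        )
    df = pd.DataFrame(rows).sort_values("sample").reset_index(drop=True)
    write_tsv(df, out / "methylation_levels.tsv")
    write_json({"samples": df.to_dict(orient="records")}, out / "methylation_levels.json")


def _stage_patterns(config: RunConfig, out: Path) -> None:
    from .patterns import classify_population, identify_dmfs, partition_summary, population_pattern_table

    matrix = read_band_matrix(config.band_matrix)  # type: ignore[arg-type]
    ref_sample = config.reference_sample
    if ref_sample is None or ref_sample not in matrix.samples:
        raise ValueError(f"reference_sample {ref_sample!r} not found in the band matrix")
    ref = matrix.states(ref_sample)
    population = {s: matrix.states(s) for s in matrix.samples if s != ref_sample}

    records = classify_population(ref, population)
    trans_df = pd.DataFrame(
        [
            {
                "locus": r.locus_id,
                "individual": r.individual_id,
                "ref_state": r.ref_state.roman,
                "sample_state": r.sample_state.roman,
                "class": r.cls.value,
            }
            for r in records
        ]
    ).sort_values(["locus", "individual"]).reset_index(drop=True)
    write_tsv(trans_df, out / "transitions.tsv")

    freq = population_pattern_table(ref, population).reset_index()
    write_tsv(freq, out / "pattern_frequencies.tsv")

    dmfs = identify_dmfs(ref, population)
    indivs = sorted(population)
    dmf_df = pd.DataFrame(
        [
            {
                "locus": d.locus_id,
                "uniformity": d.uniformity.value,
                "ref_state": d.ref_state.roman,
                "variant_state": d.variant_state.roman if d.variant_state else "NA",
                **{i: (d.states[i].roman if d.states[i] else "NA") for i in indivs},
            }
            for d in dmfs
        ]
    ).sort_values("locus").reset_index(drop=True)
    write_tsv(dmf_df, out / "dmfs.tsv")
    write_json({"partition": partition_summary(dmfs)}, out / "dmf_partition.json")


def _read_long_panels(path: str | Path) -> list:
    from .inheritance import GenerationPanel
    from .msap import classify_locus

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"generation", "individual", "locus", "H", "M"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    panels = []
    for gen_id in df["generation"].drop_duplicates():
        sub = df[df["generation"] == gen_id]
        states: dict[str, list] = {}
        for locus in sub["locus"].drop_duplicates():
            rows = sub[sub["locus"] == locus].sort_values("individual")
            per_indiv = []
            for h, m in zip(rows["H"], rows["M"]):
                hh = _parse_cell(h, locus, "H")
                mm = _parse_cell(m, locus, "M")
                per_indiv.append(
                    classify_locus(BandCall(hh, mm)) if hh is not None and mm is not None else None
                )
            states[locus] = per_indiv
        panels.append(GenerationPanel(gen_id, states))
    return panels


def _stage_inherit(config: RunConfig, out: Path) -> None:
    from .inheritance import _state_from_pair, summarize_inheritance, track_inheritance

    manifest_df = pd.read_csv(config.inherit_manifest, sep="\t", dtype=str)  # type: ignore[arg-type]
    manifest = [
        (row["locus"], _state_from_pair(row["ref_call"]), _state_from_pair(row["variant_call"]))
        for _, row in manifest_df.iterrows()
    ]
    panels = _read_long_panels(config.inherit_panels)  # type: ignore[arg-type]
    series = track_inheritance(manifest, panels)
    rows = []
    for s in series:
        row = {
            "locus": s.locus_id,
            "ref_state": s.ref_state.roman,
            "variant_state": s.variant_state.roman,
            "verdict": s.verdict.value,
        }
        for r in s.ratios:
            row[r.label] = f"{r.pct:.2f} ({r.retained}/{r.n})"
        rows.append(row)
    write_tsv(pd.DataFrame(rows), out / "inheritance.tsv")
    summary = summarize_inheritance(series)
    write_json({"summary": dataclasses.asdict(summary)}, out / "inheritance_summary.json")


def _stage_bisulfite(config: RunConfig, out: Path) -> None:
    from .bisulfite import assign_contexts, call_clones, summarize_region

    references = read_fasta(config.bisulfite_reference)  # type: ignore[arg-type]
    clones = read_fasta(config.bisulfite_clones)  # type: ignore[arg-type]
    call_rows = []
    summaries = {}
    for region_id, sequence in references.items():
        amplicon = assign_contexts(sequence, region_id)
        mine = [
            (clone_id, seq) for clone_id, seq in clones.items() if clone_id.startswith(region_id)
        ]
        if not mine:
            continue
        matrix = call_clones(amplicon, mine, min_identity=config.clone_identity)
        for clone_id in sorted(matrix.calls):
            for pos in amplicon.cytosine_positions:
                call_rows.append(
                    {
                        "region": region_id,
                        "position": pos + 1,  # 1-based in reports
                        "context": amplicon.contexts[pos].value,
                        "clone": clone_id,
                        "call": matrix.calls[clone_id][pos].value,
                    }
                )
        summary = summarize_region(matrix, amplicon)
        summaries[region_id] = {
            "pct": summary.pct,
            "overall_pct": summary.overall_pct,
            "methylated": dict(summary.methylated),
            "total": dict(summary.total),
            "n_clones": matrix.n_clones,
            "n_rejected": len(matrix.rejected),
        }
    write_tsv(pd.DataFrame(call_rows), out / "bisulfite_calls.tsv")
    write_json({"regions": summaries}, out / "bisulfite_summary.json")


def _stage_sirna(config: RunConfig, out: Path) -> None:
    from .sirna import SirnaRecord, differential_expression, length_stratify, match_to_dmfs

    counts = pd.read_csv(config.sirna_counts, sep="\t", dtype=str)  # type: ignore[arg-type]
    if "sequence" not in counts.columns:
        raise ValueError("sirna counts TSV must have a 'sequence' column")
    libs = [c for c in counts.columns if c not in ("sequence", "length")]
    sizes_df = pd.read_csv(config.library_sizes, sep="\t", dtype=str)  # type: ignore[arg-type]
    library_sizes = {row["library"]: int(row["size"]) for _, row in sizes_df.iterrows()}
    records = [
        SirnaRecord(row["sequence"], {lib: int(row[lib]) for lib in libs})
        for _, row in counts.iterrows()
    ]
    results = differential_expression(
        records,
        list(config.group_a),
        list(config.group_b),
        library_sizes,
        pseudocount=config.pseudocount,
        alpha=config.alpha,
        lfc_threshold=config.lfc_threshold,
    )
    de_df = pd.DataFrame(
        [
            {
                "sequence": r.sequence,
                "length": r.length,
                "log2_fold_change": r.log2_fold_change,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "direction": r.direction.value,
            }
            for r in results
        ]
    ).sort_values("sequence").reset_index(drop=True)
    write_tsv(de_df, out / "sirna_de.tsv")

    if config.dmf_fasta:
        dmfs = read_fasta(config.dmf_fasta)
        de_seqs = sorted(r.sequence for r in results if r.direction.value != "ns")
        matches = match_to_dmfs(de_seqs, dmfs, max_mismatches=config.max_mismatches)
        match_df = pd.DataFrame(
            [
                {"sirna": m.sirna, "dmf": m.dmf_id, "offset": m.offset, "strand": m.strand}
                for m in matches
            ]
        ).sort_values(["sirna", "dmf", "offset"] if matches else []).reset_index(drop=True)
        write_tsv(match_df, out / "dmf_matches.tsv")
        write_json({"matched_lengths": length_stratify(matches)}, out / "match_lengths.json")


_STAGE_FUNCS = {
    "score": (_stage_score, ("band_matrix",)),
    "patterns": (_stage_patterns, ("band_matrix", "reference_sample")),
    "inherit": (_stage_inherit, ("inherit_panels", "inherit_manifest")),
    "bisulfite": (_stage_bisulfite, ("bisulfite_reference", "bisulfite_clones")),
    "sirna": (_stage_sirna, ("sirna_counts", "library_sizes")),
}


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run the enabled stages in dependency order; returns stage -> status.

    Stages missing their inputs are skipped with a logged reason; a stage
    exception is recorded and does not abort the remaining stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}
    manifest_inputs = {}
    for stage in config.stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        func, required = _STAGE_FUNCS[stage]
        missing = [r for r in required if not getattr(config, r)]
        if missing:
            status[stage] = f"skipped (missing {', '.join(missing)})"
            logger.info("stage %s skipped: missing %s", stage, missing)
            continue
        try:
            func(config, out)
            status[stage] = "ok"
            logger.info("stage %s complete", stage)
        except Exception as exc:  # noqa: BLE001 - per-stage failure report
            status[stage] = f"failed ({exc})"
            logger.error("stage %s failed: %s", stage, exc)
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, str) and Path(value).is_file():
            manifest_inputs[f.name] = {"path": value, "sha256": sha256_file(value)}
    write_json(
        {
            "tool": "msapkit",
            "version": __version__,
            "config": {
                f.name: (list(v) if isinstance(v := getattr(config, f.name), tuple) else v)
                for f in dataclasses.fields(config)
            },
            "inputs": manifest_inputs,
            "stages": status,
        },
        out / "run_manifest.json",
    )
    return status
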