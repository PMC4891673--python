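# msapkit

Tools for analysing grafting- or stress-induced DNA methylation change from
MSAP (methylation-sensitive amplified polymorphism) band data, plus the
companion assays used to validate and interpret such changes:

- **MSAP scoring** (`msapkit.msap`): classify dual-digest (EcoRI+HpaII /
  EcoRI+MspI) presence–absence band pairs into four methylation states
  (unmethylated, CHG, CG, CG/CHG), compute total- and fully-methylated band
  ratios, compare levels between samples (Fisher's exact / chi-square), and
  build consensus calls over technical replicates.
- **Pattern transitions** (`msapkit.patterns`): classify reference→sample
  state transitions into no-change / demethylation / methylation /
  interchange (4/5/5/2 of the 16 ordered pairs), tabulate per-individual
  pattern frequencies, and partition differentially methylated fragments
  (DMFs) into uniform (changed identically in every individual) versus
  distinctive.
- **Inheritance** (`msapkit.inheritance`): track uniform-DMF variant states
  across selfed generations, compute per-transition retention ratios
  ("pct (retained/n)"), and classify each locus stable / reverting / lost.
- **Bisulfite clones** (`msapkit.bisulfite`): conversion-aware global
  alignment of Sanger bisulfite clones against a reference amplicon,
  per-cytosine methylation calls, CG/CHG/CHH context summaries, region
  comparisons, and conversion-efficiency QC.
- **siRNA pipeline** (`msapkit.sirna`): CPM normalisation, pooled exact
  binomial differential-expression test with Benjamini–Hochberg adjustment
  (|log2FC| ≥ 1, adjusted p < 0.05), exact substring matching of
  differential siRNAs against DMF sequences on both strands, and per-length
  stratification (24-nt class flags RdDM candidates).
- **Simulation** (`msapkit.simulate`): seeded generators for every input —
  band matrices with planted DMFs, generation panels under per-individual
  reversion, bisulfite clones with per-context methylation probabilities and
  imperfect conversion, and siRNA count tables with spiked fold changes —
  each with a machine-readable truth table.
- **I/O + orchestration** (`msapkit.io`, `msapkit.cli`): TSV/FASTA/JSON
  readers and writers, a plain-text run configuration, and a stage pipeline
  with a checksummed run manifest.

Bundled reference data (`msapkit.datasets`) ships the published per-sample
band-type counts and the 32-locus uDMF retention table used by the
regression tests and the acceptance script.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(partition conservation, permutation invariance, transition antisymmetry,
BH monotonicity), and `tests/test_acceptance.py` with the table
reproductions and calibrated recovery checks (bisulfite parameter recovery
within binomial CIs, differential-expression null calibration and power,
inheritance-simulator closed form, exact planted-DMF recovery).

## CLI

```sh
msapkit score    --matrix bands.tsv --out-dir out/
msapkit patterns --matrix bands.tsv --reference TTT --out-dir out/
msapkit inherit  --panels panels.tsv --manifest loci.tsv --out-dir out/
msapkit bisulfite --reference amplicon.fasta --clones clones.fasta --out-dir out/
msapkit sirna-de --counts counts.tsv --library-sizes sizes.tsv \
                 --group-a A1,A2 --group-b B1,B2 --dmfs dmfs.fasta --out-dir out/
msapkit match    --sirnas seqs.txt --dmfs dmfs.fasta --out matches.tsv
msapkit simulate bands|panels|clones|sirna --out-dir sim/ [options]
msapkit run      --config run.cfg
```

Band matrices are TSV with a `locus_id` column and paired `<sample>_H` /
`<sample>_M` columns in {0, 1, NA}. Run configs are plain `key = value`
files; all analysis thresholds (alpha, |log2FC|, clone identity,
pseudocount) live there.

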