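# erv-antigen

A tested, reusable pipeline for discovering endogenous retrovirus (ERV)
derived, HLA-presented tumor antigens from standard file formats:

- **`erv_catalog`** — BED/FASTA I/O for ERV catalogs, sequence extraction
  (strand-aware), interval extension, and binding-peak proximity annotation
  at 0/1/5/10 kb windows.
- **`sixframe_db`** — six-frame ORF enumeration (minimum protein length 7,
  no start-codon requirement), merged ERV + reference + contaminant search
  databases, unique 9-mer accounting, and I/L-aware peptide source mapping.
- **`erv_quant`** — ERV expression from alignment evidence: paired-end
  PM/1MM retention, three-criterion single-end retention, fragment
  deduplication, the `2*(PE) + SE` counting rule, per-million/per-kilobase
  normalization, responsiveness calling, and candidate tiering/union.
- **`immunopep_filter`** — target-decoy FDR (per-run and aggregate, <1%),
  fixed thresholds (score >= 7, SPI >= 50%, BCS >= 5, charge 1-4, length
  8-11), spectral-contrast-angle similarity, RT-calibration subset
  selection, three-metric strike classification (0 pass / 1 maybe / >=2
  fail), sequence-tag spectrum quality, peptide mass utilities, and the
  final peptide call chain with a stage audit.
- **`signature_stats`** — log2(x+1)/z-score normalization, gene-set
  signature scoring, Pearson correlation with Benjamini-Hochberg
  adjustment per target family.
- **`synthetic_data`** — deterministic generators with ground truth:
  homologous ERV catalogs, alignment evidence with planted abundances,
  PSM mixtures with known correctness, and latent-factor expression
  matrices.
- **`orchestration` / `cli`** — YAML-configured end-to-end driver with a
  machine-readable audit report.

## Tests

```sh
python -m pytest -q tests/
```

The suite covers every operation against independent oracles (brute-force
interval overlap, codon-by-codon translation, recounting, grouping,
hand-enumerated filter chains) plus property tests (hypothesis) and a
dedicated acceptance suite (`tests/test_acceptance.py`).

## CLI

```sh
erv-antigen proximity --ervs ervs.bed --peaks peaks.bed --windows 0,1,5,10 -o proximity.tsv
erv-antigen builddb --ervs ervs.bed --genome genome.fa --reference ref.fa -o searchdb.fa
erv-antigen quant --alignments aln.tsv --ervs ervs.bed -o erv_counts.tsv
erv-antigen filter-psms --psms psms.tsv --db searchdb.fa --fdr 0.01 -o calls.tsv
erv-antigen correlate --matrix expr.tsv --signature hif2.txt -o correlations.tsv
erv-antigen simulate catalog --seed 1 -o simdir/
erv-antigen run --config pipeline.yaml
```

`erv-antigen run` executes quantification -> responsiveness calls ->
candidate union -> proximity -> search database -> PSM filtering ->
correlation from a single YAML config and writes `audit.json` with stage
counts and all effective parameters (every threshold defaults to its
published value).

Alignment evidence is exchanged as a simplified TSV
(`read_id mate txome_mapped erv_id nm frag_pos orient`); PSM tables are TSV
with `ion:intensity` lists for observed/predicted b/y intensities (see
`erv_antigen.immunopep_filter.read_psm_tsv`).

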