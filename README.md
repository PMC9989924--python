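# coordscan

Transcriptome coordination analysis: identify genes whose relationship to the
whole transcriptome mirrors that of a query gene panel.

For each gene, its **correlation profile** is the vector of Pearson R values
between its expression and every gene in the matrix, computed across
(genetically diverse) samples. The **coordination** of two genes is the
Pearson correlation of their two profiles after excluding both genes' own
entries. Scanning every gene against a panel of pathway genes and ranking by
mean coordination surfaces candidates that are co-regulated with the pathway
even when individual expression differences are not significant.

The package provides:

- `expression_io` — TSV expression matrix I/O, validation, log-normalization,
  zero-variance filtering.
- `coordination` — Pearson R with exact small-sample significance
  (t transform, df = n−2), critical-r inversion, correlation profiles, the
  coordination statistic with analytic and permutation p-values, panel
  scanning, and significance-thresholded correlated-gene-set selection.
- `enrichment` — GMT gene-set collections, hypergeometric upper-tail
  over-representation tests, Benjamini–Hochberg q-values.
- `promoter_motif` — TSS-relative promoter coordinates (no position 0;
  −931..+38 spans 969 bp), IUPAC consensus scanning by Levenshtein edit
  distance (so an 8-nt site can match a 9-nt consensus like `TGATGxAAx`).
- `synthetic` — a seeded latent-factor simulator that plants a coordinated
  gene module, a hidden target gene and a partially coordinated dual-loading
  gene into noise background, with full ground truth, for testing and
  benchmarking.
- `pipeline` / CLI — end-to-end orchestration with YAML config, stable TSV
  outputs and a JSON run report.

## Test

```bash
python -m pytest tests/
```

The suite includes property-based tests (hypothesis) and an acceptance suite
(`tests/test_acceptance.py`) that validates every statistic against
independent oracles (pure-Python brute force, combinatorial enumeration,
numeric integration, recursive DP). One acceptance test
(`test_planted_target_rank_one_in_95_percent`) is known-red: the required
recovery rate is not statistically attainable at the fixed fixture
parameters (see the comment in the test).

## CLI

```bash
# simulate a dataset with a planted coordinated module + hidden target
coordscan simulate --seed 42 --out data/

# scan all genes against a panel
coordscan scan --expr data/expression.tsv \
    --panel HSPA5,DNAJB9,HSP90B1,ATF4,DNAJC3,DDIT3 --out scan.tsv

# correlated gene set for a query gene (P < 0.05, positive R)
coordscan geneset --expr data/expression.tsv --gene RASSF1 --out geneset.tsv

# hypergeometric enrichment against a GMT collection
coordscan enrich --query query.txt --background bg.txt --gmt sets.gmt --out enr.tsv

# promoter consensus scan (TSS-relative coordinates, edit distance ≤ 2)
coordscan motif --fasta promoters.fa --consensus TGATGxAAx --max-edit 2 --out hits.tsv

# full pipeline from YAML
coordscan run --config run.yaml
```

Minimal `run.yaml`:

```yaml
expression: data/expression.tsv
sample_sheet: data/samples.tsv      # optional: sample_id, condition columns
panel: [HSPA5, DNAJB9, HSP90B1, ATF4, DNAJC3, DDIT3]
gmt: sets.gmt                       # optional
promoters: promoters.fa             # optional; header token tss=<int>
alpha: 0.05
seed: 7
out_dir: out/
```

## File formats

- **Expression TSV** — genes × samples, first column gene id, header row
  sample ids; `--transpose` for the other orientation.
- **Sample sheet TSV** — columns `sample_id`, `condition`
  (control/treated/unknown).
- **GMT** — `term <TAB> description <TAB> member genes...`, one set per line.
- **Promoter FASTA** — sense strand 5′→3′; header token `tss=<int>` gives the
  1-based string index of the +1 position (defaults to the sequence end).
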