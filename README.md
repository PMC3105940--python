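# readqa

Headless quality assessment for second-generation sequencing reads.
`readqa` parses multifasta-style phred quality files alongside nucleotide
FASTA or SOLiD color-space (`.csfasta`) sequence files, accumulates
per-base quality statistics in a single streaming pass, filters reads by
mean or median phred quality at a chosen cutoff, estimates genome
coverage before and after filtering, and emits validated filtered files
(`<name>.new`) plus chart-ready summaries.

Malformed records (wrong length, invalid characters, non-integer or
out-of-range quality values, blank lines) are eliminated — never fatal —
and every elimination is recorded in a machine-readable validation log.

## CLI

```bash
# per-base tables + charts for a quality file
readqa stats --qual reads.qual --length 35 --genome-size 2300000 --out report/

# mean- or median-based phred filter; writes reads.qual.new / reads.csfasta.new
readqa filter --qual reads.qual --seq reads.csfasta --length 35 \
    --stat mean --qv 20 --genome-size 2300000

# kept reads + estimated coverage per statistic x cutoff
readqa coverage-table --qual reads.qual --length 35 \
    --genome-size 2300000 --qv 20 --qv 23 --qv 25

# deterministic synthetic paired dataset with a ground-truth manifest
readqa generate --out data/ -n 1000 --encoding colorspace --seed 1
```

Filtering keeps a read when its chosen statistic is **greater than or
equal to** the cutoff. Coverage is `floor((n * L) / S)` with exact
integer arithmetic; retention percentages are truncated (not rounded) to
two decimals.

## Library

```python
from readqa import FilterConfig, run_filter_job, accumulate, coverage_table

outcome, log = run_filter_job("reads.qual", "reads.csfasta", 35,
                              FilterConfig("median", 20))
print(outcome.kept_count, outcome.retention_percent)
```

## Layout

- `src/readqa/io.py` — streaming quality/sequence parsers, validation log, writers
- `src/readqa/stats.py` — per-base aggregation, mean/median, coverage arithmetic
- `src/readqa/filters.py` — quality filtering and the filter job pipeline
- `src/readqa/report.py` — chart series and static PNG/SVG rendering
- `src/readqa/cli.py` — `readqa` command-line entry point
- `src/readqa/fixtures.py` — deterministic synthetic dataset generator
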