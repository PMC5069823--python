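# somatrack

Case-matched spatio-temporal somatic mutation profiling for multi-lesion
tumour cohorts: variant filtering, matched-normal (germline) subtraction,
truncal / lesion-private partitioning, de-novo variant derivation for
metastases, synchronous-vs-metachronous timing classification, RAS hotspot
trajectory tracking with a low-frequency rescue scan, and cohort summary
reports.  A synthetic-cohort simulator with planted ground truth makes every
stage testable without any external data.

## Layout

| module | role |
|---|---|
| `somatrack.model` | domain types (variants, calls, specimens, cases, filter config) and variant identity rules |
| `somatrack.io` | cohort manifest (YAML), variant tables (TSV), VCF reading, report writing |
| `somatrack.filtering` | the variant-filter stack and the FFPE qPCR QC metric |
| `somatrack.casematch` | germline subtraction, truncal/private partition, de-novo derivation, timing rule, RAS trajectory, co-resected lesion concordance |
| `somatrack.aggregate` | cohort-level tables (recurrent variants per case, case-mixed site tally, de-novo frequency, treatment report, headline summary) |
| `somatrack.simulate` | seeded clonal-evolution cohort generator with purity-scaled allele fractions and ground truth |
| `somatrack.cli` | `somatrack` command-line tool and end-to-end pipeline |
| `somatrack.fixtures` | loaders for the bundled 14-case / 70-specimen reference cohort |

Key conventions: allele fractions are percent (0–100) everywhere in the API
(`population_af` is a 0–1 fraction); dates have month precision; variant
identity is the genomic quadruple when complete, else (gene, protein change).
The AF cutoff is inclusive (≥ 10 % retained), the population-frequency
cutoff exclusive (> 5 % removed).

A documented quirk of the bundled reference tables: recounting APC rows
yields 9 cases with a recurrent APC variant, while the accompanying
narrative total is 8; the APC cohort count is therefore not used as an
acceptance quantity.

## CLI

```bash
# generate a synthetic cohort (manifest + per-specimen VCFs + truth.json)
somatrack simulate --seed 7 --n-cases 6 --out scratch/sim

# full pipeline on it
somatrack run --manifest scratch/sim/manifest.yaml --vcf-dir scratch/sim \
    --out scratch/reports

# individual stages
somatrack filter --calls calls.tsv --out filtered.tsv --af-cutoff 10
somatrack ras-status --manifest m.yaml --calls calls.tsv --out reports/
somatrack summarize --manifest m.yaml --calls calls.tsv --out reports/
```

Thresholds can come from a YAML config (`--config cfg.yaml`, keys under
`filter:`); explicit flags override the config, which overrides defaults.
Each stage logs machine-parsable `STAGE` count lines (`in == kept + removed`)
to stderr.

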