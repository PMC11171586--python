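# svcoseg

Familial structural-variant (SV) co-segregation analysis for multiplex
pedigrees: ingest per-family and control SV VCFs, cluster equivalent calls
across samples, filter them against per-family segregation schemes, tier
them by control-cohort carrier frequency, annotate genomic context against
gene models, and attach null co-segregation probabilities computed by
Mendelian gene dropping.

## What it computes

- **P(seg)** — the probability, under Mendelian transmission of a single
  variant allele introduced heterozygously in one founder, that the carrier
  pattern among genotyped family members matches the family's segregation
  scheme (all obligate carriers carry ≥1 alternative allele, no obligate
  non-carrier does). Computed exactly by exhaustive enumeration of
  transmission outcomes (maximised over founder origins) or by seeded Monte
  Carlo gene dropping for large pedigrees.
- **Frequency tiers** — per-cluster control carrier frequency (carriers /
  control individuals) classified as ABSENT (0%), RARE (<1%), UNCOMMON
  (<5%), or COMMON (≥5%), with strict `<` boundaries.
- **P(obs)** — the composite observation statistic:
  `P(seg) × P(exvar)` for a single-family exonic hit (P(exvar) = exonic
  fraction of detected variants), and
  `∏ P(seg_i) × P(anyvar) × P(var)^(k−1) × C(F, k)` for a variant recurring
  in k of F families, with P(var) the control carrier fraction and C(F, k)
  the Bonferroni factor over family combinations.

## Layout

| module | role |
|---|---|
| `svcoseg.core_model` | pedigrees, phenotypes, segregation schemes, PED/YAML I/O |
| `svcoseg.pedigree_stats` | gene-dropping P(seg) engine and P(obs) statistics |
| `svcoseg.sv_cohort` | SV VCF ingestion, cross-sample clustering, frequency tiers |
| `svcoseg.annotation` | GFF3/GTF gene models, exon/UTR/intron context classification |
| `svcoseg.coseg_pipeline` | scheme filtering, candidate selection, SNV-overlap, reports |
| `svcoseg.synthetic_data` | synthetic cohort generator with known truth |
| `svcoseg.cli` | `svcoseg` command-line entry points |

## CLI

Generate a synthetic cohort, run the pipeline, and inspect the reports:

```sh
svcoseg simulate --seed 7 --out demo/sim
svcoseg run \
  --family-vcfs demo/sim/families --control-vcfs demo/sim/controls \
  --ped demo/sim/cohort.ped --schemes demo/sim/schemes.yaml \
  --gff demo/sim/genes.gff3 --out demo/run --total-families 17
svcoseg stats --ped demo/sim/cohort.ped --schemes demo/sim/schemes.yaml --out demo/pseg.tsv
svcoseg report --run-dir demo/run       # re-render TSVs from candidates.json
```

`svcoseg run` writes `families.tsv` (per-family P(seg)),
`exonic_candidates.tsv`, `multifamily_candidates.tsv`, `summary.tsv`
(nested type × tier counts), `genes.txt` (for external enrichment tools),
`candidates.json`, and a `config.yaml` echo for reproducibility. A
`--config FILE` YAML can supply any flag's default; all randomness flows
from `--seed`.

## Conventions

- Coordinates are 1-based inclusive (VCF convention); a deletion written
  `chrN:pos-end` spans `end − pos` bp. Insertions carry their inserted
  length and `end == pos`.
- Control frequency is a carrier frequency over individuals, not an allele
  frequency.
- Cross-sample SV matching: same type and chromosome, ≥50% reciprocal
  overlap and both breakpoints within ±50 bp (insertions: position within
  tolerance and length ratio ≥0.5); single-linkage; all thresholds
  configurable via `MatchParams`.
- Report rounding is half-away-from-zero to 4 decimals (one significant
  digit below 0.0001).
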