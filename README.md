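# lineagedyn

Lineage-dynamics analysis of time-lapse embryonic stem cell tracking data:
lineage-tree statistics (compartments, transitions, residence times, survival
and division times, cell-cycle inheritance, G1 metrics), a two-population
growth/transition/survival model, and a bootstrap cluster-alignment tool for
clustered expression matrices. A synthetic lineage-forest generator with the
same statistical structure replaces raw imaging data, so the whole pipeline
is testable offline.

## Modules

| Module | Purpose |
| --- | --- |
| `lineagedyn.tracks_io` | Read/write long-format track tables, assemble and validate lineage forests, prune to complete cell cycles, per-cell intensity and division-time summaries |
| `lineagedyn.compartments` | High/Mid/Low quartile compartments and two-way k-means fate split (PrE vs NEDiff) |
| `lineagedyn.lineage_stats` | Survival/death tables, mother→daughter transition matrices (per generation and per 24 h), residence times, fate-conversion fractions, prospective-fate comparison, FUCCI G1 metrics |
| `lineagedyn.inheritance` | Sister/cousin/mother–daughter cycle-length correlations with permutation p-values and bootstrap CIs; bootstrap median differences |
| `lineagedyn.growth_model` | Two-population exponential growth model: closed form, generation sum, stochastic branching oracle, composition predictions, sensitivity sweeps |
| `lineagedyn.synthetic_data` | Forward simulators for steady-state and differentiation forests (state-dependent cycles, death, transitions, kin-correlated cycle lengths, reporter traces) and toy clustered expression matrices |
| `lineagedyn.cluster_align` | Non-zero-median normalization and bootstrap Euclidean cluster alignment between two clustered matrices |

## CLI

```bash
# simulate a steady-state forest and write the track table
lineagedyn simulate --preset nacl --seed 7 --out tracks.csv

# ingest -> label -> tables
lineagedyn ingest --tracks tracks.csv --out forest.json --condition NACL
lineagedyn label --forest forest.json --method quartile --out labels.csv
lineagedyn stats --forest forest.json --labels labels.csv \
    --tables survival,transitions,residence --out tables/

# kin cycle-length correlations
lineagedyn inherit --forest forest.json --relations sister,cousin \
    --n-boot 10000 --seed 7 --out kin.csv

# growth model composition (params.json holds N, t, s1, s2, d1, d2)
lineagedyn model --params params.json --days 1,2,3,4,5 --out composition.csv

# bootstrap cluster alignment
lineagedyn align --query q.csv --query-labels q_labels.csv \
    --reference r.csv --reference-labels r_labels.csv \
    --n-boot 1000 --sigma 1.6 --seed 7 --out align.csv
```

Track tables are long-format CSV/TSV, one row per (cell, frame), with columns
`cell_id, parent_id, time_h, intensity[, phase], fate` where `fate` is one of
`divided`, `died`, `censored`.

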