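# doubleread

Inter-reader discordance analysis for double-read RECIST 1.1 clinical
trials.

In blinded independent central review (BICR) with double reads, two
radiologists independently score each patient's scans under RECIST 1.1 and
an adjudicator resolves pre-defined disagreements. This package derives
per-visit responses from lesion-level reads, extracts the four standard
kinds of inter-reader discrepancy, models discrepancy rates over time,
screens baseline risk factors, and evaluates how well discordance can be
predicted from baseline features — all exercisable end-to-end on a
built-in synthetic double-read trial generator with known ground truth.

## The four kinds of discrepancy (KoDs)

For each patient the two readers' timelines are compared on:

| Flag   | Definition |
|--------|------------|
| `pdd`  | only one of the readers ever declared progressive disease (PD) |
| `dopd` | one reader has no PD, or both declared PD on different dates |
| `bor`  | the best timepoint responses differ (ordering CR > PR > SD > PD, no confirmation rule) |
| `dofr` | one reader has no CR/PR, or the first CR/PR dates differ |

`pdd` always implies `dopd`.

## Modules

- `doubleread.recist` — RECIST 1.1 per-visit overall responses
  (CR/PR/SD/PD/NE) from long-format lesion observations: target-lesion sum
  of diameters with per-reader nadir tracking, non-target status
  integration, new-lesion handling.
- `doubleread.kod` — per-reader endpoints (best response, first-response
  date, first-PD date) and the four discrepancy flags with configurable
  determination-day attribution (`late`/`early`).
- `doubleread.temporal` — cumulative discrepancy rate on the trial clock,
  discrepancy distribution and discrete hazard on the follow-up clock
  (monthly grid of 30.4375 days), exact Clopper–Pearson bounds, and a
  model-based expected rate from (accrual, survival, hazard) components.
- `doubleread.risk_factors` — baseline features per reader pair (relative
  burden difference, organ-overlap flags, non-measurable disease, lung
  target absence, reader-specific burden share, infrequent locations) and
  univariate odds-ratio / rank-sum screening with best-case threshold
  optimization.
- `doubleread.stats` — exact binomial CIs, Marascuilo simultaneous
  proportion comparisons, Dunnett-C pairwise mean intervals, rank-sum test
  (exact for small samples), odds ratios, percentile bootstrap, McNemar.
- `doubleread.classify` — repeated stratified 80:20 cross-validation of a
  random forest (with recursive feature elimination) and a feed-forward
  classifier; AUC/Acc/Se/Sp/PPV/NPV as percentages with bootstrap CIs.
- `doubleread.simulate` — synthetic trial generator: staggered accrual,
  per-trial visit schedules (five presets), latent lesion pools, response
  and progression dynamics, and a two-reader observation model with
  selection, measurement and detection disagreement knobs. Also a direct
  discrepancy-process generator for validating the temporal estimators.
- `doubleread.cli` — the `doubleread` command (below).

## Command line

```bash
# generate a synthetic trial (preset schedules trial1..trial5, or a YAML design)
doubleread simulate --preset trial3 --seed 1 --out runs/sim

# full discordance pipeline: responses -> KoD flags -> rate curves -> risk screen
doubleread analyze --lesions runs/sim/lesions.csv --out runs/analysis

# response-level input (skips the lesion-to-response step)
doubleread analyze --responses responses.csv --out runs/analysis2

# cross-validated discordance prediction from baseline features
doubleread classify --features runs/analysis/features.csv \
    --kods runs/analysis/kods.csv --kod bor --model forest --out runs/clf
```

All tables are comma-separated UTF-8 with a header row; every command
writes a machine-readable `run_log.json`. Lesion tables need the columns
`patient_id, reader_id, lesion_id, organ, category, is_lymph_node,
visit_index, visit_day, diameter_mm, ntl_status` (plus an optional
`inclusion_day` for trial-clock curves); response tables need
`patient_id, reader_id, visit_index, visit_day, overall`.

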