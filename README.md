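# pcto — precision-cohort treatment options

`pcto` turns longitudinal clinical event tables into personalized
treatment-option reports. The workflow has four stages:

1. **Data extraction** — identify disease-specific *decision points*
   (encounter dates where the disease is measurably uncontrolled),
   the treatment decision observed at each one, and the follow-up
   controlled/not-controlled outcome (`pcto.decision_points`), then build
   baseline variables over each decision point's history and rank them by
   stability selection with L1-penalized logistic regression
   (`pcto.variables`).
2. **Similarity model training** — locally supervised metric learning:
   a transformation `W` maximizing the average neighborhood margin
   between same-outcome and different-outcome neighbors, yielding the
   distance `sqrt((a-b)^T W W^T (a-b))` and per-variable weights
   `1^T W W^T` (`pcto.lsml`).
3. **Precision-cohort identification** — exact-match filtering on
   designated filter variables, similarity scoring (distances normalized
   to [0, 1]), and a grid search for the largest score threshold whose
   cohort is large and well balanced by standardized bias
   (`pcto.cohort`).
4. **Treatment-options analysis** — group the cohort by observed
   decision, compare each option with the "no change" baseline via
   Bonferroni-corrected 2x2 chi-square tests, annotate medication
   complexity, and serialize a Sankey diagram (`pcto.options`).

A leave-one-out evaluation harness (`pcto.evaluate`) runs the full
pipeline for every scoring decision point and aggregates per-filter-cohort
summaries. Because real clinical data of this kind is restricted,
`pcto.simulate` generates synthetic longitudinal EHR populations with
known ground truth — confounded treatment policies and heterogeneous
planted effects — so every stage is testable end to end.

## Command-line interface

```bash
pcto simulate --config sim.yaml --out events.csv --truth truth.json \
     --attributes attrs.json --codemap codes.json
pcto extract --events events.csv --disease-config src/pcto/configs/htn.yaml \
     --codemap codes.json --attributes attrs.json \
     --templates templates.yaml --out dps.csv --variables-out X.csv
pcto select-variables --variables X.csv --dps dps.csv --out stability.csv
pcto train --variables X.csv --dps dps.csv --out model.json
pcto score --model model.json --variables X.csv --filters F.csv \
     --dps dps.csv --index-dp <dp_id> --out cohort.json
pcto report --cohort cohort.json --dps dps.csv --out report.json --sankey sankey.json
pcto evaluate --model model.json --variables X.csv --filters F.csv \
     --dps dps.csv --out-dir eval/
```

Ready-made decision-point configurations for a hypertension-style paired
blood-pressure rule (`htn.yaml`) and two diagnosis-then-lab rules
(`t2dm.yaml`, `hl.yaml`) ship in `src/pcto/configs/`.

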