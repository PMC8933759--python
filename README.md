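# hemifc

ROI-to-ROI functional connectivity networks, hemispheric aggregate
connectivity (rFC / lFC), the asymmetry index (AI), and the associated
group statistics — implemented as a fully testable pipeline exercised on
synthetic multi-subject ROI time series with controllable connectivity
structure and asymmetry.

## What it does

* **atlas** — a lateralized ROI catalogue (hemisphere L/R/M, homotopic
  pairing) with validation; ships a 105-ROI reconstruction of a standard
  cortical + subcortical parcellation (50 left, 50 right, 5 midline).
  Midline ROIs are excluded from all hemispheric statistics.
* **synthetic** — multi-group cohort simulation: block-structured
  population correlation matrices (within-hemisphere, homotopic and
  cross-hemisphere baselines), additive group-specific edge effects,
  per-ROI AI targeting via bisection, nearest-correlation repair, AR(1)
  temporal structure, truncated-normal clinical covariates. Fully
  reproducible from one seed.
* **connectivity** — per-subject Pearson correlation matrices with the
  Fisher z transform, and edge-wise between-group two-sample t-tests with
  a two-level significance rule (uncorrected height threshold p < .01,
  then per-seed Benjamini–Hochberg FDR at q < .05; matrix-wide BH
  available).
* **asymmetry** — per-ROI rFC / lFC (sums of supra-threshold |weights|
  toward each hemisphere, default threshold r > 0.25) and
  `AI = 100 (rFC − lFC) / ((rFC + lFC) / 2)`, bounded in [−200, 200],
  undefined when both sums are zero.
* **stats** — paired t (rFC vs lFC lateralization), one-way ANOVA with
  Bonferroni post hoc on AI, BH-FDR, Pearson clinical correlations,
  cohort demographic tests (ANOVA / χ² / Mann–Whitney U).
* **report** — significant-ROI counts and half-up-rounded percentages,
  rightward/leftward direction tallies, Markdown summary.

## CLI

```bash
hemifc simulate  --config examples/design_mtle.yaml --out cohort/ --seed 17
hemifc connect   --cohort cohort/ --out conn/
hemifc compare   --conn conn/ --groups RMTLE,HC --out results/edges_RMTLE_HC.tsv
hemifc asymmetry --conn conn/ --threshold 0.25 --mode signed --weight z \
                 --out results/asymmetry.tsv
hemifc stats     --asymmetry results/asymmetry.tsv --out results/
hemifc report    --results results/ --out report.md
```

All intermediate artifacts are plain TSV: one time-series table per
subject plus a `manifest.tsv`, square r/z matrices per subject, tidy
long-format result tables (missing AI written as `NA`, thresholds logged
as `# alpha=...` header comments).

## Reproducibility notes

* Every random draw flows from a single seed via `numpy.random.SeedSequence`
  spawning; per-subject streams are independent and stable across runs.
* Cohort TSVs are written with fixed formatting, so identical seeds give
  byte-identical outputs.
* The AI-targeting search evaluates the asymmetry module itself on the
  candidate population matrix (after PSD repair), so targets are honored
  on the matrices subjects are actually drawn from.
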