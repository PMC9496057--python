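# ampcurve

Analysis core for qPCR fluorescence amplification curves, as used in
point-of-care nucleic-acid testing instruments:

- **`ampcurve.simgen`** — seeded generator for six curve-morphology classes
  (`class_A`/`class_B` positive sigmoids, `class_C` flat negative,
  `class_D` end-jump, `class_E` rise-then-decline hook, `class_F` linear
  drift), 100 curves per class by default (600 total, 40 cycles each), with
  CSV serialization (`label,c1..c40`).
- **`ampcurve.preprocess`** — per-feature z-score normalization fitted on
  the training split, and a sign-fixed 2-D principal-component projection
  for visual class checking.
- **`ampcurve.classify`** — stratified 7:3 split, exhaustive grid search
  with stratified 5-fold cross-validation over five classifier families
  (SVC, logistic regression, kNN, decision tree, LDA), macro-averaged
  metrics and a 6×6 confusion matrix (rows = true). On the default corpus
  the search selects the SVC at C=0.5, RBF kernel, gamma=1.
- **`ampcurve.ctcall`** — five-parameter logistic model
  `F(x) = F_b + (F_max − F_b) / (1 + exp(−(x − x0)/k))^s`, fitted by a
  from-scratch Gauss–Newton iteration (analytic Jacobian, Levenberg
  damping fallback), with Ct reported as the abscissa of the
  second-derivative maximum (SDM) of the fitted curve.
- **`ampcurve.pipeline`** — end-to-end run analysis
  (normalize → classify → Ct or abnormal cause → report), abnormal-cause
  lookup, four-level risk binning of positive counts, Pearson agreement
  validation against a reference instrument, and JSON/HTML report
  rendering.

## Command-line interface

```bash
# generate the default 600-curve labeled corpus
ampcurve simulate --seed 0 --out data.csv

# 2-D principal-component projection (label,pc1,pc2)
ampcurve project --in data.csv --out coords.csv

# grid-search + train a classifier, store model/normalizer/metrics
ampcurve train --in data.csv --model svc --out model.bin \
    --norm norm.json --metrics metrics.json

# Ct calls for a plate export (wells.csv: header cycle,w1,w2,...)
ampcurve ct --in wells.csv --out ct.json

# full analysis with JSON + HTML reports
ampcurve analyze --in wells.csv --model model.bin --norm norm.json \
    --out report.json --html report.html

# Pearson agreement between reference and algorithm Ct columns
ampcurve validate              # built-in 8-sample HBV comparison table
ampcurve validate --pairs pairs.csv
```

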