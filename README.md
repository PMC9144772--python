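# extractopt

Design-of-experiments toolkit for optimizing a multi-analyte extraction
process: Box–Behnken designs, precedence-chart composite scoring,
quadratic response-surface modelling with full ANOVA (lack-of-fit,
PRESS-based predicted R²), least-squares SVM regression with
cross-validated hyperparameter search, constrained surface maximization,
and validation-based model comparison. Ships the complete printed dataset
of a published ultrasound-assisted extraction study as checksum-guarded
fixtures, plus a synthetic-data generator so every stage is testable
without them.

## Quick tour

```python
import extractopt as eo

factors = eo.load_fixture("table1")          # 4 factors, 3 levels each
table = eo.load_fixture("table2")            # 30 Box-Behnken runs

weights = eo.WeightScheme(weights={"DISS": 0.75, "PolyIII": 0.25})
table = eo.add_composite(table, weights)     # Y = 0.75*DISS + 0.25*PolyIII

model = eo.fit_quadratic(table, "composite") # full second-order fit, coded units
anova = eo.anova_quadratic(model, table)     # partial SS, lack of fit, R2 family

best = eo.maximize_quadratic(model, factors) # analytic stationary point
print(best.argmax_natural, best.predicted_value)

avg = eo.aggregate_replicates(table)         # 30 -> 25 (center replicates averaged)
svm = eo.fit_lssvm(avg.coded, avg.composite, g=0.1, C=10.4)
```

## CLI

```sh
extractopt simulate --config surface.json --seed 1 --out table.csv
extractopt score --data table.csv --out scored.csv
extractopt fit-rsm --data table.csv --out-dir out/
extractopt fit-lssvm --data table.csv --g-grid 0.01,0.1,1 --c-grid 1,10,100 --out-dir out/
extractopt optimize --model rsm --data table.csv
extractopt compare --validation validation.csv
extractopt reproduce-paper --out report/
```

`reproduce-paper` reruns the whole packaged analysis and checks every
recomputed quantity (composite column, refit coefficients, ANOVA
statistics, prediction MSE, surface optimum, validation deviations)
against its published value at a stored tolerance; it exits non-zero if
any check fails.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests
(coding round-trips, kernel/KKT identities, monotonicities) and
`tests/test_acceptance.py`, which asserts the published reproduction
targets at their stated tolerances.

## Layout

- `src/extractopt/design.py` — factors, coding, BBD construction, composite scoring, replicate aggregation, CSV/JSON I/O
- `src/extractopt/rsm.py` — quadratic fitting, ANOVA, significance marks, report writers
- `src/extractopt/lssvm.py` — RBF/linear kernels, dual solve, LOO/k-fold grid search, MSE
- `src/extractopt/optimize.py` — surface maximization, relative deviation, validation reports, model comparison
- `src/extractopt/assays.py` — radical-scavenging percent, calibration lines
- `src/extractopt/synthetic.py` — BBD simulator, fixture loaders
- `src/extractopt/report.py`, `cli.py` — reproduction bundle, logging, CLI
- `src/extractopt/data/` — transcribed experiment fixtures (checksum-guarded)

Notes on conventions: the RBF kernel defaults to `exp(-||u-v||²/g)`
(classic LS-SVM toolbox convention, `g` a squared bandwidth) with
`convention="gamma"` available for `exp(-g·||u-v||²)`; validation SDs use
the population (n) denominator, matching the published summaries.
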