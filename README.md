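# combosyn

Biologically informed machine learning for anti-cancer **drug-combination
synergy prediction**. Given a combination screen — one Loewe-excess synergy
score per (drug pair, cell line) experiment, with per-drug monotherapy
dose-response summaries — plus drug annotations (SMILES, putative targets)
and cell-line omics (expression, mutations, copy number), the package

1. engineers a compact, interpretable feature matrix: MACCS structural
   keys and target/domain/pathway sets in a symmetric 0/1/2 pair-sum
   encoding, link-prediction features on a drug synergy network,
   monotherapy parameters, co-expression module summaries, and filtered
   mutation/CNV features;
2. fits any of five regression backends (linear, Lasso, RBF-SVR, random
   forest, gradient-boosted trees) to the synergy scores;
3. evaluates with the screen's primary metric — the **weighted average
   Pearson correlation coefficient**,
   `WAPCC = Σᵢ √(nᵢ−1)·ρᵢ / Σᵢ √(nᵢ−1)`, where ρᵢ is the per-combination
   correlation between observed and predicted scores over the nᵢ cell
   lines of combination i — under ten repetitions of 10-fold
   cross-validation, with bootstrap confidence intervals and two-sample
   z-tests for model comparison;
4. interprets the boosted-tree model through normalized split-gain
   importances aggregated over feature classes, and tests
   target-synergy associations with two-sample Kolmogorov–Smirnov
   statistics.

Because large combination screens are access-gated, the package ships a
fully specified synthetic-screen generator (`combosyn.simulate`) with
planted co-expression modules, planted CNV–expression coupling, and a
synergy score generated as a stated function of drug/cell-line features
plus Gaussian noise — every pipeline stage is testable against known
ground truth. See `docs/methods.md` for the model, conventions and
limitations.

It is aimed at computational pharmacology researchers benchmarking
synergy-prediction feature sets and evaluation protocols.

## Worked example

```python
import numpy as np
import combosyn as cs
from combosyn.interpretation import importance_report
from combosyn.modeling import fit

cohort = cs.generate_cohort(cs.SimConfig(seed=7))   # 60 drugs, 40 cell lines
X = cs.featurize_cohort(cohort)
y = np.array([e.synergy for e in cohort.experiments])
print(f"experiments: {len(y)}   features: {X.n_features}")

res = cs.repeated_kfold_cv(
    cs.ModelSpec.xgboost_preset("paper-tuned", seed=7), X, y,
    k=10, reps=2, seed=7, experiments=cohort.experiments)
pairs = list(zip(res.per_combination["RHO"], res.per_combination["N"]))
lo, hi = cs.bootstrap_ci(pairs, seed=7)
print(f"WAPCC = {res.wapcc:.3f}   (bootstrap 95% CI {lo:.3f}..{hi:.3f})")

model = fit(cs.ModelSpec.xgboost_preset("paper-tuned", seed=7), X, y)
report = importance_report(model, X.groups)
for group, share in report.per_group_gain.head(5).items():
    print(f"{group:28s} {share:.3f}")
```

prints

```
experiments: 1200   features: 337
WAPCC = 0.390   (bootstrap 95% CI 0.333..0.445)
chemical structure           0.307
monotherapy                  0.292
gene expression modules      0.235
copy number                  0.049
target protein domains       0.033
```

The cohort screens 20% of a 150-combination × 40-cell-line grid. The
tuned boosting preset recovers a cross-validated WAPCC of 0.39 from a
signal planted to explain about half of the score variance; the group
importances show where the fitted model found it (on synthetic data the
random fingerprints partly act as combination identifiers, which is why
the chemical class ranks high on training gain). Passing `experiments=`
activates the leakage guard: synergy-network features are rebuilt from
each training fold so no test label reaches a feature.

A thin CLI covers the same flow:

```bash
combosyn simulate --seed 7 --out cohort/         # writes CSV/GMT + truth.json
combosyn cv --seed 7 --out results/              # per-combination CSV + metrics
combosyn train --seed 7 --model xgboost --preset paper-tuned --out model.pkl
combosyn importance --model model.pkl --out importance.csv
```

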