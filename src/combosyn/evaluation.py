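"""Evaluation: the weighted average Pearson correlation (WAPCC), repeated
k-fold cross-validation, ROC-AUC, bootstrap intervals and model comparison.

The screen's primary metric weights each drug combination's Pearson
correlation between observed and predicted synergy by the square root of
its cell-line count minus one:

    WAPCC = sum_i sqrt(n_i - 1) * rho_i / sum_i sqrt(n_i - 1)

so a combination measured on a single cell line carries zero weight and the
metric is bounded by the extreme per-combination correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from . import network as network_mod
from .data_model import ExperimentRecord, FeatureMatrix
from .errors import InsufficientSampleError, MetricUndefinedError
from .modeling import FittedModel, ModelSpec, fit

logger = logging.getLogger(__name__)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; 0 by convention when a vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientSampleError("vectors differ in length")
    if x.size < 2:
        raise InsufficientSampleError("correlation needs at least 2 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def wapcc(per_combination: Sequence[tuple[float, int]]) -> float:
    """Weighted average Pearson correlation over (rho_i, n_i) pairs."""
    if len(per_combination) == 0:
        raise MetricUndefinedError("no combinations")
    weights = np.array([np.sqrt(n - 1) for _, n in per_combination], dtype=float)
    rhos = np.array([r for r, _ in per_combination], dtype=float)
    total = weights.sum()
    if total == 0:
        raise MetricUndefinedError("all combinations have a single cell line")
    return float(np.dot(weights, rhos) / total)


def per_combination_correlations(
    combo_ids: Sequence[str],
    y_true: Sequence[float],
    y_pred: Sequence[float],
) -> list[tuple[str, float, int]]:
    """(combo_id, rho_i, n_i) per combination; singleton combos get rho 0."""
    df = pd.DataFrame({"combo": combo_ids,
                       "y": np.asarray(y_true, dtype=float),
                       "p": np.asarray(y_pred, dtype=float)})
    out = []
    for combo, grp in df.groupby("combo", sort=True):
        rho = pearson(grp["y"], grp["p"]) if len(grp) >= 2 else 0.0
        out.append((combo, rho, len(grp)))
    return out


@dataclass
class CVResult:
    predictions: pd.DataFrame  # rows x repetitions, out-of-fold predictions
    per_combination: pd.DataFrame  # COMBINATION_ID, RHO (mean over reps), N
    repetitions: list[float]  # per-repetition WAPCC
    wapcc: float  # mean over repetitions
    seed: int


def _network_feature_update(
    values: pd.DataFrame,
    experiments: Sequence[ExperimentRecord],
    train_idx: np.ndarray,
    threshold: float,
    leakage_guard: bool,
) -> pd.DataFrame:
    """Replace the synergy-network columns with fold-safe recomputed values."""
    cols = [c for c in network_mod.NETWORK_FEATURES if c in values.columns]
    if not cols:
        return values
    train_exps = [experiments[i] for i in train_idx]
    combos = sorted({e.combo for e in experiments}, key=lambda c: c.combo_id)
    block = network_mod.pair_network_features(
        train_exps, [(c.combo_id, c.drug_a, c.drug_b) for c in combos],
        threshold=threshold, leakage_guard=leakage_guard)
    updated = values.copy()
    combo_of_row = [e.combo.combo_id for e in experiments]
    updated.loc[:, cols] = block.values.loc[combo_of_row, cols].to_numpy()
    return updated


def repeated_kfold_cv(
    spec: ModelSpec,
    matrix: FeatureMatrix,
    y: Sequence[float],
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    experiments: Sequence[ExperimentRecord] | None = None,
    network_threshold: float = network_mod.SYNERGY_THRESHOLD,
    leakage_guard: bool = True,
) -> CVResult:
    """Repeated k-fold CV with per-combination correlation bookkeeping.

    Every row is predicted exactly once per repetition.  Per-combination
    correlations pool a combination's out-of-fold predictions within a
    repetition (many combinations span folds), the repetition's WAPCC is
    computed from those, and the reported metric is the mean over
    repetitions.  When ``experiments`` is given and the leakage guard is on,
    the synergy-network feature columns are rebuilt from each training fold
    so no test-fold synergy label leaks into a feature.
    """
    y = np.asarray(y, dtype=float)
    n = matrix.values.shape[0]
    if n < k:
        raise InsufficientSampleError(f"{n} rows cannot be split into {k} folds")
    if experiments is not None and len(experiments) != n:
        raise InsufficientSampleError("experiments do not align with matrix rows")
    combo_ids = [key[0] for key in matrix.row_keys]

    rng = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(reps)]
    preds = pd.DataFrame(
        index=pd.MultiIndex.from_tuples(matrix.row_keys,
                                        names=["COMBINATION_ID", "CELL_LINE"]),
        columns=[f"rep{r}" for r in range(reps)], dtype=float)
    rep_wapcc: list[float] = []
    rho_sums: dict[str, float] = {}
    combo_n: dict[str, int] = {}

    for r, rep_seed in enumerate(rep_seeds):
        kf = KFold(n_splits=k, shuffle=True, random_state=rep_seed)
        y_hat = np.empty(n)
        for train_idx, test_idx in kf.split(matrix.values):
            values = matrix.values
            if experiments is not None and leakage_guard:
                values = _network_feature_update(
                    values, experiments, train_idx, network_threshold, True)
            model = fit(spec, values.iloc[train_idx], y[train_idx])
            y_hat[test_idx] = model.predict(values.iloc[test_idx])
        preds.iloc[:, r] = y_hat
        per_combo = per_combination_correlations(combo_ids, y, y_hat)
        rep_wapcc.append(wapcc([(rho, n_i) for _, rho, n_i in per_combo]))
        for combo, rho, n_i in per_combo:
            rho_sums[combo] = rho_sums.get(combo, 0.0) + rho
            combo_n[combo] = n_i

    per_combination = pd.DataFrame(
        {
            "COMBINATION_ID": sorted(rho_sums),
            "RHO": [rho_sums[c] / reps for c in sorted(rho_sums)],
            "N": [combo_n[c] for c in sorted(rho_sums)],
        }
    )
    return CVResult(predictions=preds, per_combination=per_combination,
                    repetitions=rep_wapcc, wapcc=float(np.mean(rep_wapcc)),
                    seed=seed)


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """ROC-AUC (Mann-Whitney normalization; ties contribute one half)."""
    y_true = np.asarray(y_true, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise MetricUndefinedError("ROC-AUC needs both classes present")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def bootstrap_ci(
    per_combination: Sequence[tuple[float, int]],
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the WAPCC, resampling combinations.

    The combination is the weight-bearing unit of the metric, so replicates
    resample (rho_i, n_i) pairs with replacement.  A replicate whose draw
    has zero total weight is redrawn.
    """
    rng = np.random.default_rng(seed)
    per_combination = list(per_combination)
    m = len(per_combination)
    stats = []
    while len(stats) < B:
        idx = rng.integers(0, m, size=m)
        sample = [per_combination[i] for i in idx]
        try:
            stats.append(wapcc(sample))
        except MetricUndefinedError:
            logger.info("bootstrap replicate with zero total weight redrawn")
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def two_sample_z_test(
    m1: float, s1: float, k1: int, m2: float, s2: float, k2: int
) -> tuple[float, float]:
    """Two-sample z-test on repetition-level metric summaries.

    z = (m1 - m2) / sqrt(s1^2/k1 + s2^2/k2), two-sided p from the normal CDF.
    """
    if k1 < 2 or k2 < 2:
        raise InsufficientSampleError("z-test needs k >= 2 per sample")
    if s1 < 0 or s2 < 0:
        raise MetricUndefinedError("standard deviations must be non-negative")
    se = np.sqrt(s1**2 / k1 + s2**2 / k2)
    if se == 0:
        if m1 == m2:
            return 0.0, 1.0
        return float(np.sign(m1 - m2) * np.inf), 0.0
    z = (m1 - m2) / se
    return float(z), float(2.0 * norm.sf(abs(z)))
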