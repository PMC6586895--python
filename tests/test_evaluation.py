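"""The weighted-correlation metric, CV protocol, ROC-AUC and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import combosyn as cs
from combosyn.errors import InsufficientSampleError, MetricUndefinedError
from combosyn.evaluation import per_combination_correlations
from combosyn.modeling import ModelSpec


def test_pearson_examples():
    x = np.arange(5, dtype=float)
    assert cs.pearson(x, 3 * x + 1) == pytest.approx(1.0)
    assert cs.pearson([1, 2, 3], [6, 4, 5]) == pytest.approx(-0.5)
    assert cs.pearson([1, 2, 3], [7, 7, 7]) == 0.0
    with pytest.raises(InsufficientSampleError):
        cs.pearson([1.0], [2.0])


def test_wapcc_closed_forms():
    assert cs.wapcc([(0.7, 10)]) == pytest.approx(0.7)
    # sqrt(4)*1 + sqrt(1)*0 over sqrt(4)+sqrt(1)
    assert cs.wapcc([(1.0, 5), (0.0, 2)]) == pytest.approx(2 / 3)
    base = [(0.5, 4), (0.2, 9)]
    assert cs.wapcc(base + [(0.99, 1)]) == pytest.approx(cs.wapcc(base))
    with pytest.raises(MetricUndefinedError):
        cs.wapcc([(0.5, 1), (0.9, 1)])
    with pytest.raises(MetricUndefinedError):
        cs.wapcc([])


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.tuples(st.floats(-1, 1), st.integers(2, 30)),
                min_size=1, max_size=12))
def test_wapcc_invariances(pairs):
    value = cs.wapcc(pairs)
    rhos = [r for r, _ in pairs]
    assert min(rhos) - 1e-12 <= value <= max(rhos) + 1e-12
    shuffled = list(reversed(pairs))
    assert cs.wapcc(shuffled) == pytest.approx(value)
    if len({n for _, n in pairs}) == 1:  # equal weights -> plain mean
        assert value == pytest.approx(np.mean(rhos))


def test_per_combination_bookkeeping():
    combos = ["C1", "C1", "C1", "C2"]
    y = [1.0, 2.0, 3.0, 5.0]
    pred = [1.1, 2.2, 2.9, 0.0]
    rows = per_combination_correlations(combos, y, pred)
    assert [(c, n) for c, _, n in rows] == [("C1", 3), ("C2", 1)]
    assert rows[1][1] == 0.0  # singleton combo gets rho 0 (zero weight anyway)


def test_cv_perfect_predictor_ceiling(small_cohort, small_matrix, small_y):
    leaked = cs.FeatureMatrix(
        row_keys=small_matrix.row_keys,
        values=small_matrix.values.assign(LEAK=small_y),
        groups={**small_matrix.groups, "LEAK": "monotherapy"},
    )
    res = cs.repeated_kfold_cv(
        ModelSpec(kind="xgboost", params={"n_estimators": 60}, seed=0),
        leaked, small_y, k=5, reps=2, seed=0)
    assert res.wapcc >= 0.99


def test_cv_is_deterministic(small_matrix, small_y):
    spec = ModelSpec(kind="linear")
    a = cs.repeated_kfold_cv(spec, small_matrix, small_y, k=5, reps=2, seed=4)
    b = cs.repeated_kfold_cv(spec, small_matrix, small_y, k=5, reps=2, seed=4)
    assert a.repetitions == b.repetitions
    pd.testing.assert_frame_equal(a.predictions, b.predictions)
    assert a.wapcc == b.wapcc


def test_cv_every_row_predicted_each_repetition(small_matrix, small_y):
    res = cs.repeated_kfold_cv(ModelSpec(kind="linear"), small_matrix,
                               small_y, k=5, reps=3, seed=1)
    assert res.predictions.shape == (len(small_y), 3)
    assert np.isfinite(res.predictions.to_numpy()).all()
    assert res.wapcc == pytest.approx(np.mean(res.repetitions))


def test_cv_network_guard_recomputes_from_training_subset(small_cohort,
                                                          small_matrix):
    """The fold update rebuilds the synergy network from the training subset
    only: removing all experiments of a synergistic combination from the
    training rows must change some recomputed network feature."""
    from combosyn.evaluation import _network_feature_update

    exps = small_cohort.experiments
    net = cs.build_network(exps, 20.0)
    edge = sorted(next(iter(net.edges)))
    assert net.edges, "small cohort must contain at least one synergistic edge"
    full_idx = np.arange(len(exps))
    without_idx = np.array([
        i for i, e in enumerate(exps)
        if {e.combo.drug_a, e.combo.drug_b} != set(edge)])
    full = _network_feature_update(small_matrix.values, exps, full_idx,
                                   20.0, True)
    reduced = _network_feature_update(small_matrix.values, exps, without_idx,
                                      20.0, True)
    cols = [c for c in full.columns if c.startswith("NET_")]
    assert not np.allclose(full[cols].to_numpy(), reduced[cols].to_numpy())
    # the non-network columns are left untouched by the update
    other = [c for c in full.columns if not c.startswith("NET_")]
    assert np.array_equal(full[other].to_numpy(), reduced[other].to_numpy())


def test_roc_auc_examples():
    assert cs.roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert cs.roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    assert cs.roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)
    with pytest.raises(MetricUndefinedError):
        cs.roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=4,
                max_size=40))
def test_roc_auc_complement_identity(pairs):
    y = np.array([p[0] for p in pairs])
    s = np.array([p[1] for p in pairs])
    if len(np.unique(y)) < 2:
        return
    assert cs.roc_auc(1 - y, s) == pytest.approx(1 - cs.roc_auc(y, s))


def test_bootstrap_degenerate_and_coverage():
    lo, hi = cs.bootstrap_ci([(0.4, 5), (0.4, 9), (0.4, 3)], B=200, seed=0)
    assert lo == pytest.approx(0.4) and hi == pytest.approx(0.4)
    rng = np.random.default_rng(1)
    for trial in range(20):
        pairs = [(float(rng.uniform(-1, 1)), int(rng.integers(2, 20)))
                 for _ in range(8)]
        point = cs.wapcc(pairs)
        lo, hi = cs.bootstrap_ci(pairs, B=400, seed=trial)
        assert lo - 1e-9 <= point <= hi + 1e-9


def test_bootstrap_width_scales_with_combination_count():
    rng = np.random.default_rng(2)
    small = [(float(rng.normal(0.4, 0.2)), 10) for _ in range(25)]
    large = [(float(rng.normal(0.4, 0.2)), 10) for _ in range(100)]

    def width(pairs):
        lo, hi = cs.bootstrap_ci(pairs, B=600, seed=5)
        return hi - lo

    ratio = width(large) / width(small)
    assert 0.25 <= ratio <= 0.75  # ~1/2 from sqrt(4x combinations)


def test_two_sample_z_test_values():
    z, p = cs.two_sample_z_test(0.5, 0.1, 10, 0.5, 0.1, 10)
    assert z == 0.0 and p == 1.0
    z, p = cs.two_sample_z_test(0.39, 0.02, 10, 0.36, 0.02, 10)
    assert z == pytest.approx(3.354, abs=1e-3)
    assert p == pytest.approx(0.000796, abs=5e-5)
    z2, p2 = cs.two_sample_z_test(0.36, 0.02, 10, 0.39, 0.02, 10)
    assert z2 == pytest.approx(-z) and p2 == pytest.approx(p)
    assert cs.two_sample_z_test(0.3, 0.0, 5, 0.2, 0.0, 5) == (np.inf, 0.0)
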