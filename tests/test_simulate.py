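"""The synthetic screen generator: determinism, planted structure, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import combosyn as cs
from combosyn.cellline_features import spearman_or_zero
from combosyn.errors import ConfigError
from combosyn.simulate import (
    generate_cnv,
    generate_expression,
    module_partition,
    true_design_matrix,
)


def test_same_seed_gives_identical_cohorts():
    a = cs.generate_cohort(cs.SimConfig(seed=42))
    b = cs.generate_cohort(cs.SimConfig(seed=42))
    assert [e.key for e in a.experiments] == [e.key for e in b.experiments]
    assert [e.synergy for e in a.experiments] == [e.synergy for e in b.experiments]
    pd.testing.assert_frame_equal(a.expression, b.expression)
    pd.testing.assert_frame_equal(a.cnv, b.cnv)
    pd.testing.assert_frame_equal(a.mutations, b.mutations)


def test_experiment_counts_under_coverage():
    cfg = cs.SimConfig(n_drugs=20, n_cell_lines=5, n_combos=10, n_genes=30,
                       n_modules=2, coverage=1.0, seed=0)
    assert len(cs.generate_cohort(cfg).experiments) == 10 * 5
    # floor rounding of coverage * |grid|
    cfg = cs.SimConfig(n_combos=150, n_cell_lines=40, coverage=0.2, seed=0)
    assert len(cs.generate_cohort(cfg).experiments) == 1200


def test_infeasible_combo_count_raises():
    with pytest.raises(ConfigError, match="n_combos"):
        cs.generate_cohort(cs.SimConfig(n_drugs=5, n_combos=11, seed=0))


def test_invalid_module_signal_var_raises():
    with pytest.raises(ConfigError, match="module_signal_var"):
        cs.SimConfig(module_signal_var=1.2).validate()


def _pairwise_corrs(expression, genes):
    corr = np.corrcoef(expression.loc[genes].to_numpy())
    iu = np.triu_indices(len(genes), k=1)
    return corr[iu]


def test_expression_within_module_correlation_matches_signal_var():
    cfg = cs.SimConfig(n_genes=150, n_modules=5, n_cell_lines=50,
                       module_signal_var=0.8, seed=7)
    truth = module_partition(cfg)
    expr = generate_expression(cfg, truth, np.random.default_rng(7))
    genes_m1 = [g for g, m in truth.items() if m == "M01"][:30]
    within = _pairwise_corrs(expr, genes_m1)
    assert 0.7 <= within.mean() <= 0.9


def test_expression_no_signal_limit():
    cfg = cs.SimConfig(n_genes=150, n_modules=5, n_cell_lines=50,
                       module_signal_var=0.0, seed=7)
    truth = module_partition(cfg)
    expr = generate_expression(cfg, truth, np.random.default_rng(7))
    genes_m1 = [g for g, m in truth.items() if m == "M01"]
    genes_m2 = [g for g, m in truth.items() if m == "M02"]
    within = np.abs(_pairwise_corrs(expr, genes_m1)).mean()
    cross = np.abs(np.corrcoef(expr.loc[genes_m1].to_numpy(),
                               expr.loc[genes_m2].to_numpy())
                   [:len(genes_m1), len(genes_m1):]).mean()
    assert abs(within - cross) < 0.1


def test_single_module_pc1_explains_signal_var():
    cfg = cs.SimConfig(n_genes=120, n_modules=1, n_cell_lines=60,
                       module_signal_var=0.6, seed=3)
    truth = module_partition(cfg)
    expr = generate_expression(cfg, truth, np.random.default_rng(3))
    x = expr.to_numpy()
    x = x - x.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(x, compute_uv=False)
    explained = sv[0] ** 2 / (sv**2).sum()
    assert abs(explained - 0.6) < 0.1


def test_cnv_coupling_spearman_distributions():
    cfg = cs.SimConfig(n_genes=200, n_modules=4, n_cell_lines=85,
                       module_signal_var=0.3, cnv_target_r=0.6, seed=5)
    truth = module_partition(cfg)
    rng = np.random.default_rng(5)
    expr = generate_expression(cfg, truth, rng)
    genes = list(expr.index)
    coupled = set(genes[:100])
    cnv = generate_cnv(cfg, coupled, expr, np.random.default_rng(6))
    r_coupled = [spearman_or_zero(cnv.loc[g], expr.loc[g]) for g in genes[:100]]
    r_uncoupled = [spearman_or_zero(cnv.loc[g], expr.loc[g]) for g in genes[100:]]
    assert np.mean([(0.4 <= r <= 0.8) for r in r_coupled]) >= 0.95
    assert np.mean([abs(r) < 0.3 for r in r_uncoupled]) >= 0.95


def test_constant_copy_number_has_zero_spearman():
    assert spearman_or_zero(np.full(10, 2.0), np.arange(10)) == 0.0


def test_copy_numbers_are_bounded_integers(small_cohort):
    cnv = small_cohort.cnv.to_numpy()
    assert cnv.dtype.kind == "i"
    assert cnv.min() >= 0 and cnv.max() <= 8


def test_zero_coefficients_give_standard_normal_scores():
    cfg = cs.SimConfig(
        n_drugs=40, n_cell_lines=30, n_combos=100, n_genes=40, n_modules=2,
        coverage=1.0, noise_sd=1.0,
        effect_sizes=cs.EffectSizes(intercept=0, pathway=0, module=0,
                                    mutation=0, monotherapy=0),
        seed=13,
    )
    scores = np.array([e.synergy for e in cs.generate_cohort(cfg).experiments])
    assert scores.size == 3000
    assert abs(scores.mean()) < 0.1
    assert abs(scores.std() - 1.0) < 0.1


def test_pathway_effect_is_exact_in_noiseless_limit():
    cfg = cs.SimConfig(
        n_drugs=30, n_cell_lines=10, n_combos=60, n_genes=40, n_modules=2,
        coverage=1.0, noise_sd=0.0,
        effect_sizes=cs.EffectSizes(intercept=0, pathway=10, module=0,
                                    mutation=0, monotherapy=0),
        seed=21,
    )
    cohort = cs.generate_cohort(cfg)
    overlap = set(cohort.truth.pathway_overlap_combos)
    scores = {True: set(), False: set()}
    for e in cohort.experiments:
        scores[e.combo.combo_id in overlap].add(round(e.synergy, 9))
    assert scores[True] == {10.0} and scores[False] == {0.0}


def test_ols_on_true_design_recovers_coefficients():
    cohort = cs.generate_cohort(cs.SimConfig(seed=17))
    design = true_design_matrix(cohort)
    y = np.array([e.synergy for e in cohort.experiments])
    fit = sm.OLS(y, design).fit()
    for name, beta in cohort.truth.coefficients.items():
        assert abs(fit.params[name] - beta) <= 2 * fit.bse[name] + 1e-9, name


def test_screen_sample_independent_of_gene_count():
    a = cs.generate_cohort(cs.SimConfig(n_genes=100, n_modules=2, seed=9))
    b = cs.generate_cohort(cs.SimConfig(n_genes=200, n_modules=2, seed=9))
    assert [e.key for e in a.experiments] == [e.key for e in b.experiments]


def test_write_cohort_round_trips_screen(tmp_path, small_cohort):
    cs.write_cohort(small_cohort, tmp_path)
    reloaded = cs.load_screen(tmp_path / "screen.csv")
    assert [r.key for r in reloaded] == [e.key for e in small_cohort.experiments]
    assert (tmp_path / "truth.json").exists()
    gmt = cs.data_model.read_gmt(tmp_path / "pathways.gmt")
    assert gmt  # every protein mapped to at least one pathway
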