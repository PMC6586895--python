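"""Co-expression modules, enrichment, mutation and CNV filtering rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm
from sklearn.metrics import adjusted_rand_score

import combosyn as cs
from combosyn.cellline_features import (
    cnv_feature_block,
    detect_coexpression_modules,
    export_module_assignments,
    filter_snps,
    fisher_r_to_z_pvalue,
    module_enrichment,
    module_mean_features,
    select_cnv_genes,
    spearman_or_zero,
)
from combosyn.errors import ConfigError, InsufficientSampleError
from combosyn.simulate import generate_expression, module_partition


def _recovery_ari(signal_var, seed=7):
    cfg = cs.SimConfig(n_genes=150, n_modules=5, n_cell_lines=50,
                       module_signal_var=signal_var, seed=seed)
    truth = module_partition(cfg)
    expr = generate_expression(cfg, truth, np.random.default_rng(seed))
    modules = detect_coexpression_modules(expr, n_modules=5)
    genes = sorted(truth)
    return adjusted_rand_score([truth[g] for g in genes],
                               [modules.assignment[g] for g in genes])


def test_module_recovery_with_strong_signal():
    assert _recovery_ari(0.8) >= 0.8


def test_module_recovery_null_control():
    assert _recovery_ari(0.0) < 0.2


def test_perfectly_correlated_genes_share_a_module():
    rng = np.random.default_rng(0)
    base = rng.standard_normal(20)
    expr = pd.DataFrame(
        [base, 2 * base + 1, rng.standard_normal(20), rng.standard_normal(20)],
        index=["GA", "GB", "GC", "GD"],
        columns=[f"CL{i}" for i in range(20)])
    modules = detect_coexpression_modules(expr, n_modules=3, min_module_size=1)
    assert modules.assignment["GA"] == modules.assignment["GB"]


def test_module_detection_invariant_to_input_order():
    cfg = cs.SimConfig(n_genes=60, n_modules=3, n_cell_lines=30,
                       module_signal_var=0.7, seed=4)
    truth = module_partition(cfg)
    expr = generate_expression(cfg, truth, np.random.default_rng(4))
    shuffled = expr.sample(frac=1, axis=0, random_state=1).sample(
        frac=1, axis=1, random_state=2)
    a = detect_coexpression_modules(expr, n_modules=3)
    b = detect_coexpression_modules(shuffled, n_modules=3)
    assert a.assignment == b.assignment


def test_too_many_modules_raises():
    expr = pd.DataFrame(np.random.default_rng(0).standard_normal((4, 6)))
    with pytest.raises(ConfigError):
        detect_coexpression_modules(expr, n_modules=10)


def test_module_mean_features_identities():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.standard_normal((6, 8)),
                        index=[f"G{i}" for i in range(6)],
                        columns=[f"CL{i}" for i in range(8)])
    modules = detect_coexpression_modules(expr, n_modules=2, min_module_size=1)
    means = modules.module_means
    # single-gene module equals that gene's profile
    for mid in means.index:
        genes = [g for g, m in modules.assignment.items() if m == mid]
        if len(genes) == 1:
            assert np.allclose(means.loc[mid], expr.loc[genes[0]])
    # size-weighted mean of module rows equals the grand gene mean
    sizes = pd.Series({m: sum(v == m for v in modules.assignment.values())
                       for m in means.index})
    if sizes.sum() == expr.shape[0]:  # all genes assigned
        weighted = (means.mul(sizes, axis=0)).sum(axis=0) / sizes.sum()
        assert np.allclose(weighted, expr.mean(axis=0))


def test_module_assignment_export(tmp_path):
    cfg = cs.SimConfig(n_genes=30, n_modules=2, n_cell_lines=20,
                       module_signal_var=0.8, seed=2)
    truth = module_partition(cfg)
    expr = generate_expression(cfg, truth, np.random.default_rng(2))
    modules = detect_coexpression_modules(expr, n_modules=2)
    path = tmp_path / "modules.csv"
    export_module_assignments(modules, path)
    table = pd.read_csv(path)
    assert list(table.columns) == ["GENE", "MODULE"]
    assert len(table) == 30


def test_enrichment_exhaustive_worked_example():
    universe = [f"G{i}" for i in range(10)]
    annotation = {"T1": set(universe[:5])}
    table = module_enrichment(set(universe[:4]), annotation, universe)
    assert table.loc[0, "p_raw"] == pytest.approx(5 / 210)
    assert table.loc[0, "p_bonferroni"] == pytest.approx(5 / 210)  # one term


def test_enrichment_zero_overlap_and_bonferroni_bound():
    universe = [f"G{i}" for i in range(10)]
    annotation = {"T1": set(universe[5:]), "T2": set(universe[:2]), "EMPTY": set()}
    table = module_enrichment(set(universe[:4]), annotation, universe)
    assert "EMPTY" not in set(table["term"])
    t1 = table.set_index("term").loc["T1"]
    assert t1["k"] == 0 and t1["p_raw"] == pytest.approx(1.0)
    assert (table["p_bonferroni"] >= table["p_raw"] - 1e-12).all()
    assert ((table["p_raw"] > 0) & (table["p_raw"] <= 1)).all()


def test_filter_snps_rules():
    mutations = pd.DataFrame({
        "CELL_LINE": ["CL1", "CL1", "CL2", "CL9"],
        "GENE": ["BRAF", "HOUSEKEEPER", "TP53", "BRAF"],
        "VARIANT_ID": ["VAR_BRAF_1", "VAR_HK_1", "VAR_TP53_1", "VAR_BRAF_2"],
    })
    block = filter_snps(mutations, {"BRAF", "TP53"}, ["CL1", "CL2"])
    # non-cancer gene excluded; variant only in unlisted CL9 excluded
    assert sorted(block.values.columns) == ["MUT_VAR_BRAF_1", "MUT_VAR_TP53_1"]
    assert block.values.loc["CL1", "MUT_VAR_BRAF_1"] == 1.0
    assert block.values.loc["CL2", "MUT_VAR_BRAF_1"] == 0.0
    per_gene = filter_snps(mutations, {"BRAF", "TP53"}, ["CL1", "CL2"],
                           per_gene=True)
    assert sorted(per_gene.values.columns) == ["MUT_BRAF", "MUT_TP53"]


def test_filter_snps_counts_planted_cancer_variants(small_cohort):
    cancer = small_cohort.vocabularies.cancer_genes
    cells = sorted(small_cohort.cell_lines)
    block = filter_snps(small_cohort.mutations, cancer, cells)
    expected = small_cohort.mutations[
        small_cohort.mutations["GENE"].isin(cancer)]["VARIANT_ID"].nunique()
    assert block.values.shape[1] == expected


def test_fisher_r_to_z_values():
    assert fisher_r_to_z_pvalue(0.0, 85) == pytest.approx(1.0)
    assert fisher_r_to_z_pvalue(0.17, 85) == pytest.approx(0.120, abs=5e-4)
    assert fisher_r_to_z_pvalue(1.0, 85) == 0.0
    # agreement with a direct normal-CDF evaluation
    r, n = 0.3, 40
    expected = 2 * (1 - norm.cdf(abs(np.arctanh(r)) * np.sqrt(n - 3)))
    assert fisher_r_to_z_pvalue(r, n) == pytest.approx(expected)
    with pytest.raises(InsufficientSampleError):
        fisher_r_to_z_pvalue(0.5, 3)


def test_fisher_p_monotone_in_correlation_magnitude():
    grid = np.linspace(0.0, 0.95, 20)
    ps = [fisher_r_to_z_pvalue(r, 50) for r in grid]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def _cnv_cohort():
    return cs.generate_cohort(cs.SimConfig(n_cell_lines=85, seed=23))


def test_select_cnv_genes_gates():
    rng = np.random.default_rng(0)
    cells = [f"CL{i}" for i in range(85)]
    expr = pd.DataFrame(rng.standard_normal((3, 85)),
                        index=["CONST", "PERFECT", "NULL"], columns=cells)
    cnv = pd.DataFrame(
        [np.full(85, 2.0), np.round(2 + expr.loc["PERFECT"] / 2).clip(0, 8),
         rng.integers(0, 8, 85)],
        index=["CONST", "PERFECT", "NULL"], columns=cells)
    table = select_cnv_genes(cnv, expr, cancer_genes={"CONST", "NULL"})
    assert table.loc["CONST", "spearman_r"] == 0.0
    assert not table.loc["CONST", "selected"]
    # perfect correlation but outside the cancer list -> not selected
    assert table.loc["PERFECT", "p_value"] < 0.01
    assert not table.loc["PERFECT", "selected"]


def test_select_cnv_recovers_planted_coupling():
    cohort = _cnv_cohort()
    table = select_cnv_genes(cohort.cnv, cohort.expression,
                             cohort.vocabularies.cancer_genes)
    coupled = set(cohort.truth.cnv_coupled_genes)
    cancer = cohort.vocabularies.cancer_genes
    tp = sum(table.loc[g, "selected"] for g in cancer if g in coupled)
    fp = sum(table.loc[g, "selected"] for g in cancer if g not in coupled)
    pos = len(cancer & coupled)
    neg = len(cancer - coupled)
    assert pos > 0 and neg > 0
    assert tp / pos >= 0.9  # sensitivity
    assert (neg - fp) / neg >= 0.9  # specificity


def test_select_cnv_filter_is_monotone():
    cohort = _cnv_cohort()
    cancer = cohort.vocabularies.cancer_genes
    strict = select_cnv_genes(cohort.cnv, cohort.expression, cancer,
                              alpha=0.01, r_min=0.17)
    loose = select_cnv_genes(cohort.cnv, cohort.expression, cancer,
                             alpha=0.05, r_min=0.05)
    assert set(strict.index[strict["selected"]]) <= \
        set(loose.index[loose["selected"]])


def test_select_cnv_too_few_cells_raises():
    expr = pd.DataFrame(np.ones((2, 3)), columns=list("abc"))
    with pytest.raises(InsufficientSampleError):
        select_cnv_genes(expr, expr, set())


def test_cnv_feature_block_uses_selected_rows():
    cohort = _cnv_cohort()
    table = select_cnv_genes(cohort.cnv, cohort.expression,
                             cohort.vocabularies.cancer_genes)
    block = cnv_feature_block(cohort.cnv, table)
    selected = sorted(table.index[table["selected"]])
    assert list(block.values.columns) == [f"CNV_{g}" for g in selected]
    assert spearman_or_zero(np.ones(5), np.ones(5)) == 0.0
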