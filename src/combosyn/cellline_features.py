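"""Cell-line features: co-expression modules, enrichment, mutation and CNV
filters.

Expression is summarised by modules of mutually correlated genes found by
average-linkage hierarchical clustering of the gene-gene correlation matrix
(dissimilarity 1 − |r|), with each module represented per cell line by the
mean expression of its member genes.  Somatic variants are kept only when
they fall in a cancer-pathway gene and occur in at least one cell line.
Copy-number features are restricted to cancer genes whose copy number tracks
their own expression: Spearman correlation above both the genome-wide median
and a floor of 0.17, with a Fisher r-to-z p-value below 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, norm, spearmanr

from .data_model import GROUP_CNV, GROUP_EXPRESSION, GROUP_MUTATIONS, FeatureBlock
from .errors import ConfigError, InsufficientSampleError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

#: Defaults of the copy-number selection rule.
CNV_ALPHA = 0.01
CNV_R_MIN = 0.17


@dataclass
class ExpressionModuleSet:
    assignment: dict[str, str]  # gene -> module id or UNASSIGNED
    module_means: pd.DataFrame  # modules x cell lines
    n_modules: int


def detect_coexpression_modules(
    expression: pd.DataFrame,
    n_modules: int,
    min_module_size: int = 5,
) -> ExpressionModuleSet:
    """Cluster genes into co-expression modules.

    Parameters
    ----------
    expression
        Genes x cell lines matrix; needs at least 3 cell lines.
    n_modules
        Target number of clusters for the tree cut.
    min_module_size
        Clusters smaller than this are merged into ``"unassigned"``.

    Genes with zero variance across cell lines are pre-assigned to
    ``"unassigned"`` (their correlation with anything is undefined).  The
    procedure is deterministic and invariant to gene and cell-line order:
    modules are renamed M01, M02, ... by the rank of their first member gene
    in sorted gene order.
    """
    if expression.shape[1] < 3:
        raise InsufficientSampleError("module detection needs >= 3 cell lines")
    if n_modules > expression.shape[0]:
        raise ConfigError(
            f"n_modules={n_modules} exceeds the {expression.shape[0]} genes"
        )
    expression = expression.sort_index()
    variable = expression.index[expression.std(axis=1) > 0]
    assignment: dict[str, str] = {g: UNASSIGNED for g in expression.index}
    if len(variable) >= 2:
        sub = expression.loc[variable]
        corr = np.corrcoef(sub.to_numpy())
        dissim = 1.0 - np.abs(corr)
        np.fill_diagonal(dissim, 0.0)
        dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)  # enforce symmetry
        tree = linkage(squareform(dissim, checks=False), method="average")
        labels = fcluster(tree, t=min(n_modules, len(variable)), criterion="maxclust")
        by_label: dict[int, list[str]] = {}
        for gene, lab in zip(sub.index, labels):
            by_label.setdefault(int(lab), []).append(gene)
        kept = [genes for genes in by_label.values() if len(genes) >= min_module_size]
        kept.sort(key=lambda genes: min(genes))
        for i, genes in enumerate(kept):
            for g in genes:
                assignment[g] = f"M{i + 1:02d}"
    modules = ExpressionModuleSet(assignment=assignment,
                                  module_means=pd.DataFrame(),
                                  n_modules=0)
    modules.module_means = module_mean_features(expression, modules)
    modules.n_modules = modules.module_means.shape[0]
    return modules


def module_mean_features(
    expression: pd.DataFrame, modules: ExpressionModuleSet
) -> pd.DataFrame:
    """Mean expression of each module's member genes per cell line."""
    rows = {}
    module_ids = sorted({m for m in modules.assignment.values() if m != UNASSIGNED})
    for mid in module_ids:
        genes = [g for g, m in modules.assignment.items() if m == mid]
        genes = [g for g in genes if g in expression.index]
        if not genes:
            logger.warning("module %s has no genes in the expression matrix", mid)
            continue
        rows[mid] = expression.loc[genes].mean(axis=0)
    return pd.DataFrame(rows).T if rows else pd.DataFrame(columns=expression.columns)


def module_eigengene_features(
    expression: pd.DataFrame, modules: ExpressionModuleSet
) -> pd.DataFrame:
    """First-principal-component module summaries (alternative to the mean).

    The eigengene sign is fixed so that it correlates positively with the
    module mean.
    """
    rows = {}
    for mid in sorted({m for m in modules.assignment.values() if m != UNASSIGNED}):
        genes = [g for g, m in modules.assignment.items()
                 if m == mid and g in expression.index]
        if not genes:
            continue
        sub = expression.loc[genes].to_numpy()
        centered = sub - sub.mean(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        eig = vt[0]
        if np.corrcoef(eig, sub.mean(axis=0))[0, 1] < 0:
            eig = -eig
        rows[mid] = pd.Series(eig, index=expression.columns)
    return pd.DataFrame(rows).T if rows else pd.DataFrame(columns=expression.columns)


def export_module_assignments(modules: ExpressionModuleSet, path) -> None:
    """Write the gene -> module table as a two-column CSV (GENE, MODULE)."""
    pd.DataFrame(
        {"GENE": sorted(modules.assignment),
         "MODULE": [modules.assignment[g] for g in sorted(modules.assignment)]}
    ).to_csv(path, index=False)


def module_enrichment(
    module_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a module.

    p_raw is the upper-tail probability of observing at least the seen number
    of annotated genes in a module of this size drawn from the universe;
    p_bonferroni multiplies by the number of (non-empty) terms tested.
    """
    universe = set(universe)
    module = set(module_genes)
    if not module <= universe:
        raise ConfigError("module genes must be a subset of the universe")
    terms = {t: set(g) & universe for t, g in annotation.items()}
    terms = {t: g for t, g in terms.items() if g}
    n_tests = len(terms)
    rows = []
    for term in sorted(terms):
        annotated = terms[term]
        k = len(module & annotated)
        p_raw = float(hypergeom.sf(k - 1, len(universe), len(annotated), len(module)))
        rows.append({
            "term": term,
            "k": k,
            "K": len(annotated),
            "p_raw": p_raw,
            "p_bonferroni": min(1.0, p_raw * n_tests),
        })
    return pd.DataFrame(rows, columns=["term", "k", "K", "p_raw", "p_bonferroni"])


def filter_snps(
    mutations: pd.DataFrame,
    cancer_genes: Iterable[str],
    cell_lines: Sequence[str],
    per_gene: bool = False,
) -> FeatureBlock:
    """Binary mutation features restricted to cancer-pathway genes.

    Keeps variant ids whose gene is in the cancer-gene list and which occur
    in at least one of the given cell lines.  ``per_gene=True`` aggregates to
    one any-variant indicator per gene instead of one column per variant.
    """
    cancer = set(cancer_genes)
    sub = mutations[mutations["GENE"].isin(cancer)
                    & mutations["CELL_LINE"].isin(set(cell_lines))]
    key = "GENE" if per_gene else "VARIANT_ID"
    kept = sorted(sub[key].unique())
    values = pd.DataFrame(0.0, index=list(cell_lines),
                          columns=[f"MUT_{k}" for k in kept])
    for row in sub.itertuples(index=False):
        values.loc[row.CELL_LINE, f"MUT_{getattr(row, key)}"] = 1.0
    return FeatureBlock(values=values,
                        groups={c: GROUP_MUTATIONS for c in values.columns},
                        key="cell")


def fisher_r_to_z_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a correlation via the Fisher r-to-z transform.

    z = atanh(r)·sqrt(n−3); p = 2(1−Φ(|z|)).  |r| = 1 gives p = 0.
    """
    if n < 4:
        raise InsufficientSampleError(f"correlation test needs n >= 4, got {n}")
    if abs(r) >= 1.0:
        return 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    return float(2.0 * norm.sf(abs(z)))


def spearman_or_zero(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties); 0 for constants."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    r = spearmanr(x, y).statistic
    return 0.0 if np.isnan(r) else float(r)


def select_cnv_genes(
    cnv: pd.DataFrame,
    expression: pd.DataFrame,
    cancer_genes: Iterable[str],
    alpha: float = CNV_ALPHA,
    r_min: float = CNV_R_MIN,
) -> pd.DataFrame:
    """Per-gene CNV-expression coupling statistics and the selection flag.

    Returns a DataFrame indexed by gene with columns ``spearman_r``,
    ``p_value`` and ``selected``.  A gene is selected when it is a cancer
    gene, its Fisher-test p-value is below ``alpha``, and its Spearman
    correlation exceeds both the median over *all* genes and ``r_min``.
    """
    genes = [g for g in cnv.index if g in expression.index]
    cells = [c for c in cnv.columns if c in expression.columns]
    if len(cells) < 4:
        raise InsufficientSampleError(
            f"CNV-expression correlation needs >= 4 shared cell lines, got {len(cells)}"
        )
    cancer = set(cancer_genes)
    n = len(cells)
    stats = []
    for g in genes:
        r = spearman_or_zero(cnv.loc[g, cells].to_numpy(),
                             expression.loc[g, cells].to_numpy())
        stats.append((g, r, fisher_r_to_z_pvalue(r, n)))
    table = pd.DataFrame(stats, columns=["gene", "spearman_r", "p_value"]).set_index("gene")
    median_r = float(table["spearman_r"].median())
    table["selected"] = (
        table.index.isin(cancer)
        & (table["p_value"] < alpha)
        & (table["spearman_r"] > median_r)
        & (table["spearman_r"] > r_min)
    )
    return table


def cnv_feature_block(cnv: pd.DataFrame, selection: pd.DataFrame) -> FeatureBlock:
    """Copy-number rows of the selected genes as cell-line features."""
    genes = sorted(selection.index[selection["selected"]])
    values = cnv.loc[genes].T.astype(float)
    values.columns = [f"CNV_{g}" for g in genes]
    return FeatureBlock(values=values,
                        groups={c: GROUP_CNV for c in values.columns},
                        key="cell")


def expression_module_block(modules: ExpressionModuleSet) -> FeatureBlock:
    """Module-mean summaries as cell-line features."""
    values = modules.module_means.T.astype(float)
    values.columns = [f"EXPR_{m}" for m in modules.module_means.index]
    return FeatureBlock(values=values,
                        groups={c: GROUP_EXPRESSION for c in values.columns},
                        key="cell")
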