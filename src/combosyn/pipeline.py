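"""Composition of all feature providers into the assembled feature matrix."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from . import cellline_features, drug_features, network
from .data_model import (
    CellLineRecord,
    DrugRecord,
    ExperimentRecord,
    FeatureMatrix,
    assemble_feature_matrix,
    categorical_block,
)
from .simulate import DOMAIN_SOURCES, Cohort


@dataclass
class FeaturizeConfig:
    n_modules: int = 5
    min_module_size: int = 5
    cnv_alpha: float = cellline_features.CNV_ALPHA
    cnv_r_min: float = cellline_features.CNV_R_MIN
    synergy_threshold: float = network.SYNERGY_THRESHOLD
    network_leakage_guard: bool = True
    mutations_per_gene: bool = False
    module_summary: str = "mean"  # or "eigengene"


def featurize_cohort(
    cohort: Cohort,
    config: FeaturizeConfig | None = None,
    network_experiments: Sequence[ExperimentRecord] | None = None,
) -> FeatureMatrix:
    """Assemble the experiment-level feature matrix for a synthetic cohort.

    ``network_experiments`` restricts the synergy network to a training
    subset; by default the cohort's own experiments are used with the
    leakage guard on (each pair's own edge removed before its features are
    read).  During cross-validation the network columns are recomputed per
    training fold by :func:`combosyn.evaluation.repeated_kfold_cv`.
    """
    config = config or FeaturizeConfig()
    experiments = cohort.experiments
    vocab = cohort.vocabularies

    combos = sorted({e.combo for e in experiments}, key=lambda c: c.combo_id)
    target_vocab = list(vocab.proteins)
    domain_vocab = drug_features.concat_domain_vocabulary(vocab.domain_vocabs)
    pathway_vocab = list(vocab.pathways)
    drug_block = drug_features.combo_drug_block(
        combos, cohort.drugs, target_vocab, domain_vocab, pathway_vocab)

    net_block = network.pair_network_features(
        list(network_experiments) if network_experiments is not None else experiments,
        [(c.combo_id, c.drug_a, c.drug_b) for c in combos],
        threshold=config.synergy_threshold,
        leakage_guard=config.network_leakage_guard,
    )

    modules = cellline_features.detect_coexpression_modules(
        cohort.expression, n_modules=config.n_modules,
        min_module_size=config.min_module_size)
    if config.module_summary == "eigengene":
        modules.module_means = cellline_features.module_eigengene_features(
            cohort.expression, modules)
    expr_block = cellline_features.expression_module_block(modules)

    cells = sorted(cohort.cell_lines)
    mut_block = cellline_features.filter_snps(
        cohort.mutations, vocab.cancer_genes, cells,
        per_gene=config.mutations_per_gene)
    selection = cellline_features.select_cnv_genes(
        cohort.cnv, cohort.expression, vocab.cancer_genes,
        alpha=config.cnv_alpha, r_min=config.cnv_r_min)
    cnv_block = cellline_features.cnv_feature_block(cohort.cnv, selection)

    mono_block = drug_features.monotherapy_block(experiments)
    cat_block = categorical_block(experiments, cohort.cell_metadata)

    return assemble_feature_matrix(
        experiments,
        [drug_block, net_block, expr_block, mut_block, cnv_block,
         mono_block, cat_block],
    )


def drug_records_from_tables(
    annotations: Mapping[str, tuple[str | None, set[str]]],
    domain_maps: Mapping[str, Mapping[str, set[str]]],
    pathway_map: Mapping[str, set[str]],
    fingerprinter=None,
) -> dict[str, DrugRecord]:
    """Build DrugRecords from annotation tables and vocabulary maps."""
    drugs: dict[str, DrugRecord] = {}
    for drug_id, (smiles, targets) in annotations.items():
        fp, missing = drug_features.maccs_fingerprint(
            smiles, drug_id, provider=fingerprinter)
        domains, pathways = drug_features.derive_domains_pathways(
            targets, domain_maps, pathway_map)
        drugs[drug_id] = DrugRecord(
            drug_id=drug_id, smiles=smiles,
            fingerprint=None if missing else fp,
            targets=targets, domains=domains, pathways=pathways)
    return drugs
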