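"""Synthetic combination-screen generator with planted, recoverable structure.

The generator emulates the shape of a large pharma combination screen at
desk scale: a sparse (~20%) sampling of the drug-combination x cell-line
grid, monotherapy dose-response summaries per experiment, drug annotations
(targets, domains, pathways, fingerprints), and cell-line omics with two
planted structures the pipeline exploits —

* co-expression modules: gene g in module m on cell line c follows
  ``x_gc = sqrt(v) * F_mc + sqrt(1 - v) * eps_gc`` with F and eps standard
  normal, so the expected within-module pairwise correlation equals the
  module signal variance fraction v;
* CNV-expression coupling: a fraction of genes get integer copy numbers in
  [0, 8] whose ranks track their own expression with a target Spearman
  correlation (default 0.6), the rest get independent copy numbers.

The synergy score of each experiment is a stated linear function of
drug/cell-line features plus Gaussian noise:

    synergy = intercept
              + beta_pathway * 1[the two drugs share a pathway]
              + beta_module  * (mean expression of a designated module)
              + beta_mut     * 1[pair targets protein P* and cell mutates G*]
              + beta_mono    * |Einf_a - Einf_b|
              + N(0, noise_sd^2)

With ``noise_sd=None`` the noise standard deviation is set to the standard
deviation of the deterministic part, so the planted signal explains about
half of the score variance.  A ``truth`` record carries everything needed to
recompute the planted quantities from scratch.

Randomness is split into fixed, independent substreams (drugs, screen
sampling, expression, CNV, monotherapy, mutations, noise), so e.g. changing
the gene count does not perturb which grid cells are screened.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import drug_features
from .data_model import (
    CellLineRecord,
    CombinationKey,
    DrugRecord,
    ExperimentRecord,
    MonotherapyBlock,
    write_gmt,
    write_screen,
)
from .errors import ConfigError

DOMAIN_SOURCES = ["pfam", "prosite", "smart", "superfamily"]


@dataclass
class EffectSizes:
    """Coefficients of the planted synergy-generating function."""

    intercept: float = 5.0
    pathway: float = 6.0
    module: float = 8.0
    mutation: float = 20.0
    monotherapy: float = 0.3


@dataclass
class SimConfig:
    """Study conditions of the synthetic screen.

    Defaults give a desk-scale cohort: 60 drugs, 40 cell lines, 150 distinct
    combinations with 20% of the grid screened (1200 experiments), 250 genes
    in 5 planted modules, and a synergy signal explaining about half of the
    score variance.
    """

    n_drugs: int = 60
    n_cell_lines: int = 40
    n_combos: int = 150
    n_genes: int = 250
    n_modules: int = 5
    n_proteins: int = 60
    n_pathways: int = 15
    n_domains: int = 40
    coverage: float = 0.2
    module_signal_var: float = 0.8
    cnv_coupled_fraction: float = 0.2
    cnv_target_r: float = 0.6
    cancer_gene_fraction: float = 0.2
    mutation_rate: float = 0.3
    fingerprint_density: float = 0.3
    noise_sd: float | None = None  # None -> sd of the deterministic signal
    effect_sizes: EffectSizes = field(default_factory=EffectSizes)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_drugs", "n_cell_lines", "n_combos", "n_genes",
                     "n_modules", "n_proteins", "n_pathways", "n_domains"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0.0 < self.coverage <= 1.0:
            raise ConfigError(f"coverage must lie in (0, 1], got {self.coverage}")
        if not 0.0 <= self.module_signal_var < 1.0:
            raise ConfigError(
                f"module_signal_var must lie in [0, 1), got {self.module_signal_var}"
            )
        max_pairs = self.n_drugs * (self.n_drugs - 1) // 2
        if self.n_combos > max_pairs:
            raise ConfigError(
                f"n_combos={self.n_combos} exceeds the {max_pairs} distinct pairs "
                f"of {self.n_drugs} drugs"
            )
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


@dataclass
class Vocabularies:
    proteins: list[str]
    pathways: list[str]
    domain_vocabs: dict[str, list[str]]
    domain_maps: dict[str, dict[str, set[str]]]
    pathway_map: dict[str, set[str]]
    cancer_genes: set[str]


@dataclass
class Truth:
    """Everything needed to recompute the planted structure from scratch."""

    module_assignment: dict[str, str]
    cnv_coupled_genes: list[str]
    coefficients: dict[str, float]
    noise_sd: float
    signal_module: str
    interaction_protein: str
    interaction_gene: str
    mutated_cells: list[str]
    pathway_overlap_combos: list[str]
    interaction_combos: list[str]


@dataclass
class Cohort:
    config: SimConfig
    drugs: dict[str, DrugRecord]
    cell_lines: dict[str, CellLineRecord]
    experiments: list[ExperimentRecord]
    vocabularies: Vocabularies
    expression: pd.DataFrame  # genes x cells
    cnv: pd.DataFrame  # genes x cells
    mutations: pd.DataFrame  # CELL_LINE, GENE, VARIANT_ID
    cell_metadata: pd.DataFrame  # indexed by CELL_LINE
    truth: Truth


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["vocab", "drugs", "screen", "expression", "cnv", "monotherapy",
             "mutations", "noise", "metadata"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def module_partition(config: SimConfig) -> dict[str, str]:
    """Equal-size contiguous module assignment over the gene universe."""
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    per = config.n_genes // config.n_modules
    assignment = {}
    for i, g in enumerate(genes):
        m = min(i // per, config.n_modules - 1) if per > 0 else config.n_modules - 1
        assignment[g] = f"M{m + 1:02d}"
    return assignment


def generate_expression(
    config: SimConfig,
    module_truth: Mapping[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Factor-model expression with planted co-expression modules."""
    v = config.module_signal_var
    genes = sorted(module_truth)
    cells = [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]
    modules = sorted(set(module_truth.values()))
    factors = pd.DataFrame(rng.standard_normal((len(modules), len(cells))),
                           index=modules, columns=cells)
    eps = rng.standard_normal((len(genes), len(cells)))
    x = np.sqrt(v) * factors.loc[[module_truth[g] for g in genes]].to_numpy() \
        + np.sqrt(1.0 - v) * eps
    return pd.DataFrame(x, index=genes, columns=cells)


def generate_cnv(
    config: SimConfig,
    coupled_genes: set[str],
    expression: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Integer copy numbers in [0, 8]; coupled genes track their expression.

    For a coupled gene a latent Gaussian mixes the gene's standardized
    expression with noise at the Pearson loading that maps to the target
    Spearman correlation under bivariate normality (rho_s = 6/pi * asin(r/2));
    rounding to integer copy levels introduces ties that leave the realised
    Spearman close to, slightly below, the target.
    """
    r_target = config.cnv_target_r
    loading = 2.0 * np.sin(np.pi * r_target / 6.0)
    rows = {}
    for g in expression.index:
        e = expression.loc[g].to_numpy()
        sd = e.std()
        z = rng.standard_normal(e.size)
        if g in coupled_genes and sd > 0:
            latent = loading * (e - e.mean()) / sd + np.sqrt(1 - loading**2) * z
        else:
            latent = z
        rows[g] = np.clip(np.round(2.0 + 1.5 * latent), 0, 8).astype(int)
    return pd.DataFrame(rows, index=expression.columns).T


def _generate_vocabularies(config: SimConfig, rng: np.random.Generator,
                           genes: list[str]) -> Vocabularies:
    proteins = [f"P{i + 1:03d}" for i in range(config.n_proteins)]
    pathways = [f"PW{i + 1:02d}" for i in range(config.n_pathways)]
    per_source = np.array_split(np.arange(config.n_domains), len(DOMAIN_SOURCES))
    domain_vocabs = {
        src: [f"D{j + 1:03d}" for j in idx]
        for src, idx in zip(DOMAIN_SOURCES, per_source)
    }
    domain_maps: dict[str, dict[str, set[str]]] = {s: {} for s in DOMAIN_SOURCES}
    pathway_map: dict[str, set[str]] = {}
    for p in proteins:
        pathway_map[p] = set(rng.choice(pathways, size=rng.integers(1, 3),
                                        replace=False))
        for src in DOMAIN_SOURCES:
            vocab = domain_vocabs[src]
            if vocab and rng.random() < 0.6:
                k = int(rng.integers(1, min(3, len(vocab)) + 1))
                domain_maps[src][p] = set(rng.choice(vocab, size=k, replace=False))
    n_cancer = max(1, int(round(config.cancer_gene_fraction * len(genes))))
    cancer_genes = set(rng.choice(genes, size=n_cancer, replace=False))
    return Vocabularies(proteins=proteins, pathways=pathways,
                        domain_vocabs=domain_vocabs, domain_maps=domain_maps,
                        pathway_map=pathway_map, cancer_genes=cancer_genes)


def _generate_drugs(config: SimConfig, vocab: Vocabularies,
                    rng: np.random.Generator) -> dict[str, DrugRecord]:
    drugs = {}
    for i in range(config.n_drugs):
        drug_id = f"DRUG{i + 1:03d}"
        targets = set(rng.choice(vocab.proteins, size=int(rng.integers(1, 4)),
                                 replace=False))
        fingerprint = (rng.random(166) < config.fingerprint_density).astype(np.int8)
        domains, pathways = drug_features.derive_domains_pathways(
            targets, vocab.domain_maps, vocab.pathway_map)
        drugs[drug_id] = DrugRecord(drug_id=drug_id, smiles=None,
                                    fingerprint=fingerprint, targets=targets,
                                    domains=domains, pathways=pathways)
    return drugs


def generate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic screen; deterministic given config.seed."""
    config.validate()
    streams = _streams(config.seed)

    module_truth = module_partition(config)
    genes = sorted(module_truth)
    vocab = _generate_vocabularies(config, streams["vocab"], genes)
    drugs = _generate_drugs(config, vocab, streams["drugs"])
    drug_ids = sorted(drugs)

    expression = generate_expression(config, module_truth, streams["expression"])
    cells = list(expression.columns)

    rng_cnv = streams["cnv"]
    n_coupled = int(round(config.cnv_coupled_fraction * len(genes)))
    coupled = set(rng_cnv.choice(genes, size=n_coupled, replace=False))
    cnv = generate_cnv(config, coupled, expression, rng_cnv)

    # --- cell-line metadata and mutations -------------------------------
    rng_meta = streams["metadata"]
    tissues = ["breast", "lung", "colon", "skin"]
    diseases = ["carcinoma", "adenocarcinoma", "melanoma"]
    meta = pd.DataFrame(
        {
            "TISSUE": rng_meta.choice(tissues, size=len(cells)),
            "DISEASE": rng_meta.choice(diseases, size=len(cells)),
            "SEX": rng_meta.choice(["F", "M"], size=len(cells)),
        },
        index=pd.Index(cells, name="CELL_LINE"),
    )

    rng_mut = streams["mutations"]
    cancer_sorted = sorted(vocab.cancer_genes)
    gene_star = cancer_sorted[int(rng_mut.integers(len(cancer_sorted)))]
    # protein with the most drugs targeting it, so the interaction is screened
    target_counts = {p: sum(p in d.targets for d in drugs.values())
                     for p in vocab.proteins}
    protein_star = max(sorted(target_counts), key=lambda p: target_counts[p])
    mutated_cells = [c for c in cells if rng_mut.random() < config.mutation_rate]
    variant_pool = [(g, f"VAR_{g}_1") for g in genes]
    mut_rows = [{"CELL_LINE": c, "GENE": gene_star,
                 "VARIANT_ID": f"VAR_{gene_star}_1"} for c in mutated_cells]
    n_background = max(1, len(cells) * 3)
    idx = rng_mut.integers(0, len(variant_pool), size=n_background)
    for c, i in zip(rng_mut.choice(cells, size=n_background), idx):
        g, var = variant_pool[int(i)]
        mut_rows.append({"CELL_LINE": c, "GENE": g, "VARIANT_ID": var})
    mutations = (pd.DataFrame(mut_rows)
                 .drop_duplicates()
                 .sort_values(["CELL_LINE", "GENE", "VARIANT_ID"])
                 .reset_index(drop=True))

    cell_lines = {
        c: CellLineRecord(
            cell_id=c, tissue=meta.loc[c, "TISSUE"], disease=meta.loc[c, "DISEASE"],
            sex=meta.loc[c, "SEX"], expression=expression[c], cnv=cnv[c],
            mutations={(r.GENE, r.VARIANT_ID)
                       for r in mutations[mutations["CELL_LINE"] == c].itertuples()},
        )
        for c in cells
    }

    # --- screened grid ---------------------------------------------------
    rng_screen = streams["screen"]
    all_pairs = [(a, b) for i, a in enumerate(drug_ids) for b in drug_ids[i + 1:]]
    pick = rng_screen.choice(len(all_pairs), size=config.n_combos, replace=False)
    combos = [CombinationKey.make(*all_pairs[int(i)]) for i in sorted(pick)]
    grid = [(combo, c) for combo in combos for c in cells]
    n_screened = int(np.floor(config.coverage * len(grid)))
    chosen = rng_screen.choice(len(grid), size=n_screened, replace=False)
    screened = [grid[int(i)] for i in sorted(chosen)]

    # --- monotherapy and planted synergy ---------------------------------
    rng_mono = streams["monotherapy"]
    max_conc = {d: float(rng_mono.choice([3.16, 10.0, 31.6])) for d in drug_ids}

    def mono_block(drug_id: str) -> MonotherapyBlock:
        ic50 = float(10 ** rng_mono.uniform(np.log10(0.01), np.log10(10.0)))
        censored = ic50 > max_conc[drug_id]
        return MonotherapyBlock(
            max_conc=max_conc[drug_id],
            ic50=None if censored else ic50,
            hill_h=float(rng_mono.uniform(0.5, 3.0)),
            einf=float(rng_mono.uniform(20.0, 100.0)),
            qa=int(rng_mono.random() < 0.95),
        )

    beta = config.effect_sizes
    module_ids = sorted(set(module_truth.values()))
    signal_module = module_ids[0]
    sig_genes = [g for g, m in module_truth.items() if m == signal_module]
    module_mean = expression.loc[sig_genes].mean(axis=0)
    mutated = set(mutated_cells)

    pre: list[tuple[CombinationKey, str, MonotherapyBlock, MonotherapyBlock, float]] = []
    signals = []
    for combo, cell in screened:
        da, db = drugs[combo.drug_a], drugs[combo.drug_b]
        mono_a, mono_b = mono_block(combo.drug_a), mono_block(combo.drug_b)
        pathway_overlap = float(bool(da.pathways & db.pathways))
        pair_targets = protein_star in (da.targets | db.targets)
        interaction = float(pair_targets and cell in mutated)
        signal = (beta.intercept
                  + beta.pathway * pathway_overlap
                  + beta.module * float(module_mean[cell])
                  + beta.mutation * interaction
                  + beta.monotherapy * abs(mono_a.einf - mono_b.einf))
        pre.append((combo, cell, mono_a, mono_b, signal))
        signals.append(signal)

    noise_sd = config.noise_sd
    if noise_sd is None:
        noise_sd = float(np.std(signals)) if len(signals) > 1 else 1.0
    noise = streams["noise"].normal(0.0, noise_sd, size=len(pre)) if noise_sd > 0 \
        else np.zeros(len(pre))
    experiments = [
        ExperimentRecord(combo=combo, cell_id=cell, synergy=float(sig + eps),
                         mono_a=ma, mono_b=mb)
        for (combo, cell, ma, mb, sig), eps in zip(pre, noise)
    ]

    truth = Truth(
        module_assignment=module_truth,
        cnv_coupled_genes=sorted(coupled),
        coefficients={
            "intercept": beta.intercept,
            "pathway": beta.pathway,
            "module": beta.module,
            "mutation": beta.mutation,
            "monotherapy": beta.monotherapy,
        },
        noise_sd=noise_sd,
        signal_module=signal_module,
        interaction_protein=protein_star,
        interaction_gene=gene_star,
        mutated_cells=sorted(mutated),
        pathway_overlap_combos=sorted(
            c.combo_id for c in combos
            if drugs[c.drug_a].pathways & drugs[c.drug_b].pathways
        ),
        interaction_combos=sorted(
            c.combo_id for c in combos
            if protein_star in (drugs[c.drug_a].targets | drugs[c.drug_b].targets)
        ),
    )
    return Cohort(config=config, drugs=drugs, cell_lines=cell_lines,
                  experiments=experiments, vocabularies=vocab,
                  expression=expression, cnv=cnv, mutations=mutations,
                  cell_metadata=meta, truth=truth)


def true_design_matrix(cohort: Cohort) -> pd.DataFrame:
    """Recompute the planted design matrix (for parameter-recovery checks)."""
    truth = cohort.truth
    sig_genes = [g for g, m in truth.module_assignment.items()
                 if m == truth.signal_module]
    module_mean = cohort.expression.loc[sig_genes].mean(axis=0)
    overlap = set(truth.pathway_overlap_combos)
    inter = set(truth.interaction_combos)
    mutated = set(truth.mutated_cells)
    rows = []
    for e in cohort.experiments:
        rows.append({
            "intercept": 1.0,
            "pathway": float(e.combo.combo_id in overlap),
            "module": float(module_mean[e.cell_id]),
            "mutation": float(e.combo.combo_id in inter and e.cell_id in mutated),
            "monotherapy": abs(e.mono_a.einf - e.mono_b.einf),
        })
    return pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        [e.key for e in cohort.experiments]))


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write all tables in the reader dialects, plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_screen(cohort.experiments, out / "screen.csv")
    pd.DataFrame(
        [
            {"DRUG_ID": d.drug_id, "SMILES": d.smiles or "",
             "TARGETS": ";".join(sorted(d.targets))}
            for d in cohort.drugs.values()
        ]
    ).to_csv(out / "drugs.csv", index=False)
    pd.DataFrame(
        [
            {"DRUG_ID": d.drug_id,
             "FINGERPRINT": "".join(map(str, d.fingerprint))}
            for d in cohort.drugs.values() if d.fingerprint is not None
        ]
    ).to_csv(out / "fingerprints.csv", index=False)
    cohort.expression.to_csv(out / "expression.csv")
    cohort.cnv.to_csv(out / "cnv.csv")
    cohort.mutations.to_csv(out / "mutations.csv", index=False)
    cohort.cell_metadata.to_csv(out / "cell_lines.csv")
    vocab = cohort.vocabularies
    for src in DOMAIN_SOURCES:
        write_gmt({p: {f"{src}:{d}" for d in doms}
                   for p, doms in vocab.domain_maps[src].items()},
                  out / f"domains_{src}.gmt")
    write_gmt(vocab.pathway_map, out / "pathways.gmt")
    write_gmt({"cancer_genes": vocab.cancer_genes}, out / "cancer_genes.gmt")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(cohort.truth), fh, indent=1)
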