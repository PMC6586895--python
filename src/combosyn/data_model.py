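"""Domain types, table I/O and feature-matrix assembly.

The unit row of the learning problem is one screened (drug combination,
cell line) experiment carrying a Loewe-excess synergy score and the two
drugs' monotherapy dose-response summaries.  Drug order inside a
combination is canonicalized lexicographically so that every pair-level
feature is well defined regardless of how the screen table orders the
two drugs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AssemblyError,
    DuplicateKeyError,
    ParseError,
    ResolutionError,
    SchemaError,
)

logger = logging.getLogger(__name__)

MACCS_LENGTH = 166

SCREEN_COLUMNS = [
    "COMBINATION_ID",
    "DRUG_A",
    "DRUG_B",
    "CELL_LINE",
    "SYNERGY_SCORE",
    "MAX_CONC_A",
    "IC50_A",
    "H_A",
    "Einf_A",
    "QA_A",
    "MAX_CONC_B",
    "IC50_B",
    "H_B",
    "Einf_B",
    "QA_B",
]

#: The feature classes every assembled column belongs to.  Categorical
#: identifiers are kept as separate one-column groups ("trivial information").
GROUP_CHEMICAL = "chemical structure"
GROUP_TARGETS = "drug targets"
GROUP_DOMAINS = "target protein domains"
GROUP_PATHWAYS = "targeted pathways"
GROUP_NETWORK = "drug synergy network"
GROUP_MONOTHERAPY = "monotherapy"
GROUP_EXPRESSION = "gene expression modules"
GROUP_MUTATIONS = "mutations"
GROUP_CNV = "copy number"


@dataclass(frozen=True)
class CombinationKey:
    """Canonical identifier of a drug pair; ``drug_a < drug_b`` always."""

    combo_id: str
    drug_a: str
    drug_b: str

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError(f"combination {self.combo_id!r} pairs a drug with itself")
        if self.drug_a > self.drug_b:
            raise ValueError(
                f"combination {self.combo_id!r} is not canonically ordered: "
                f"{self.drug_a!r} > {self.drug_b!r}"
            )

    @classmethod
    def make(cls, drug_a: str, drug_b: str, combo_id: str | None = None) -> "CombinationKey":
        """Build a canonical key from drugs in any order."""
        a, b = sorted((drug_a, drug_b))
        return cls(combo_id or f"{a}.{b}", a, b)


@dataclass
class MonotherapyBlock:
    """Single-drug dose-response summary attached to one experiment.

    ``ic50`` is ``None`` when the half-maximal kill concentration was not
    reached within the tested range (censored at ``max_conc``).
    """

    max_conc: float
    ic50: float | None
    hill_h: float
    einf: float
    qa: int = 1

    def __post_init__(self) -> None:
        if not self.max_conc > 0:
            raise ValueError(f"max_conc must be positive, got {self.max_conc}")
        if not 0.0 <= self.einf <= 100.0:
            raise ValueError(f"einf must lie in [0, 100], got {self.einf}")


@dataclass
class ExperimentRecord:
    """One screened (combination, cell line) pair."""

    combo: CombinationKey
    cell_id: str
    synergy: float
    mono_a: MonotherapyBlock
    mono_b: MonotherapyBlock

    @property
    def key(self) -> tuple[str, str]:
        return (self.combo.combo_id, self.cell_id)


@dataclass
class DrugRecord:
    """A drug with its structural fingerprint and annotation-derived sets."""

    drug_id: str
    smiles: str | None = None
    fingerprint: np.ndarray | None = None
    targets: set[str] = field(default_factory=set)
    domains: set[str] = field(default_factory=set)
    pathways: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            fp = np.asarray(self.fingerprint, dtype=np.int8)
            if fp.shape != (MACCS_LENGTH,):
                raise ValueError(
                    f"fingerprint of {self.drug_id!r} has length {fp.size}, "
                    f"expected {MACCS_LENGTH}"
                )
            if not np.isin(fp, (0, 1)).all():
                raise ValueError(f"fingerprint of {self.drug_id!r} is not binary")
            self.fingerprint = fp


@dataclass
class CellLineRecord:
    """A cell line with omics profiles over a shared gene universe."""

    cell_id: str
    tissue: str
    disease: str
    sex: str
    expression: pd.Series | None = None
    cnv: pd.Series | None = None
    mutations: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class FeatureBlock:
    """One feature provider's output.

    ``values`` is indexed by combination id (``key="combo"``), cell line id
    (``key="cell"``) or the (combo_id, cell_id) experiment key
    (``key="experiment"``).  ``groups`` maps each column to its feature class.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    key: str  # "combo" | "cell" | "experiment"

    def __post_init__(self) -> None:
        if self.key not in ("combo", "cell", "experiment"):
            raise ValueError(f"unknown block key kind {self.key!r}")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise AssemblyError(f"columns without group label: {sorted(missing)}")


@dataclass
class FeatureMatrix:
    """Experiments x named features with one group label per column."""

    row_keys: list[tuple[str, str]]
    values: pd.DataFrame
    groups: dict[str, str]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def group_columns(self, group: str) -> list[str]:
        return [c for c in self.values.columns if self.groups[c] == group]

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for col in self.values.columns:
            g = self.groups[col]
            counts[g] = counts.get(g, 0) + 1
        return counts

    def drop_groups(self, groups: Iterable[str]) -> "FeatureMatrix":
        """Remove exactly the columns belonging to the given groups."""
        drop = set(groups)
        keep = [c for c in self.values.columns if self.groups[c] not in drop]
        return FeatureMatrix(
            row_keys=list(self.row_keys),
            values=self.values[keep].copy(),
            groups={c: self.groups[c] for c in keep},
        )


def screen_coverage(n_experiments: int, n_combos: int, n_cell_lines: int) -> float:
    """Fraction of the combination x cell-line grid actually screened."""
    grid = n_combos * n_cell_lines
    if grid <= 0:
        raise ValueError("empty grid")
    return n_experiments / grid


# ---------------------------------------------------------------------------
# Table readers / writers
# ---------------------------------------------------------------------------

def _parse_float(value, column: str, row: int, *, required: bool) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if required:
            raise ParseError(f"row {row}: non-numeric {column} value {value!r}")
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-numeric {column} value {value!r}") from None


def load_screen(path: str | Path) -> list[ExperimentRecord]:
    """Read a combination-screen table (CSV with header).

    Drug order within each combination is canonicalized lexicographically;
    the monotherapy A/B columns follow the drugs through the swap.  An empty
    IC50 cell marks a censored measurement and is loaded as missing.
    """
    df = pd.read_csv(path, dtype={"COMBINATION_ID": str, "DRUG_A": str, "DRUG_B": str,
                                  "CELL_LINE": str})
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"screen table missing required column(s): {missing}")

    records: list[ExperimentRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        synergy = _parse_float(row["SYNERGY_SCORE"], "SYNERGY_SCORE", i, required=True)
        blocks = {}
        for side in ("A", "B"):
            blocks[row[f"DRUG_{side}"]] = MonotherapyBlock(
                max_conc=_parse_float(row[f"MAX_CONC_{side}"], f"MAX_CONC_{side}", i, required=True),
                ic50=_parse_float(row[f"IC50_{side}"], f"IC50_{side}", i, required=False),
                hill_h=_parse_float(row[f"H_{side}"], f"H_{side}", i, required=True),
                einf=_parse_float(row[f"Einf_{side}"], f"Einf_{side}", i, required=True),
                qa=int(_parse_float(row[f"QA_{side}"], f"QA_{side}", i, required=True)),
            )
        combo = CombinationKey.make(row["DRUG_A"], row["DRUG_B"], row["COMBINATION_ID"])
        key = (combo.combo_id, row["CELL_LINE"])
        if key in seen:
            raise DuplicateKeyError(f"duplicate (combination, cell line) row: {key}")
        seen.add(key)
        records.append(
            ExperimentRecord(
                combo=combo,
                cell_id=row["CELL_LINE"],
                synergy=synergy,
                mono_a=blocks[combo.drug_a],
                mono_b=blocks[combo.drug_b],
            )
        )
    return records


def write_screen(experiments: Sequence[ExperimentRecord], path: str | Path) -> None:
    """Write experiments back to the screen-table dialect of :func:`load_screen`."""
    rows = []
    for e in experiments:
        row = {
            "COMBINATION_ID": e.combo.combo_id,
            "DRUG_A": e.combo.drug_a,
            "DRUG_B": e.combo.drug_b,
            "CELL_LINE": e.cell_id,
            "SYNERGY_SCORE": e.synergy,
        }
        for side, block in (("A", e.mono_a), ("B", e.mono_b)):
            row[f"MAX_CONC_{side}"] = block.max_conc
            row[f"IC50_{side}"] = "" if block.ic50 is None else block.ic50
            row[f"H_{side}"] = block.hill_h
            row[f"Einf_{side}"] = block.einf
            row[f"QA_{side}"] = block.qa
        rows.append(row)
    pd.DataFrame(rows, columns=SCREEN_COLUMNS).to_csv(path, index=False)


def load_drug_annotations(path: str | Path) -> dict[str, tuple[str | None, set[str]]]:
    """Read DRUG_ID, SMILES (optional), TARGETS (semicolon-separated)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("DRUG_ID", "SMILES", "TARGETS"):
        if col not in df.columns:
            raise SchemaError(f"drug annotation table missing column {col!r}")
    out: dict[str, tuple[str | None, set[str]]] = {}
    for row in df.itertuples(index=False):
        smiles = None if pd.isna(row.SMILES) or row.SMILES == "" else row.SMILES
        targets = (
            set()
            if pd.isna(row.TARGETS) or row.TARGETS == ""
            else {t for t in str(row.TARGETS).split(";") if t}
        )
        out[row.DRUG_ID] = (smiles, targets)
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: set_id <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SchemaError(f"malformed GMT line in {path}: {line!r}")
            sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            members = "\t".join(sorted(sets[set_id]))
            fh.write(f"{set_id}\t{description}\t{members}\n")


def load_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read a genes x cell-lines matrix CSV (first column = gene id)."""
    return pd.read_csv(path, index_col=0)


def load_mutations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in ("CELL_LINE", "GENE", "VARIANT_ID"):
        if col not in df.columns:
            raise SchemaError(f"mutation table missing column {col!r}")
    return df


def load_cell_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    for col in ("CELL_LINE", "TISSUE", "DISEASE", "SEX"):
        if col not in df.columns:
            raise SchemaError(f"cell-line metadata missing column {col!r}")
    return df.set_index("CELL_LINE")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def categorical_block(
    experiments: Sequence[ExperimentRecord],
    cell_metadata: pd.DataFrame,
) -> FeatureBlock:
    """Encode the five trivial identifiers as stable integer codes.

    Codes are assigned in sorted category order so they do not depend on row
    order.  Tree models split on these codes directly; one-hot expansion is
    deliberately avoided to keep the trivial-information group small.
    """
    combos = sorted({e.combo.combo_id for e in experiments})
    cells = sorted({e.cell_id for e in experiments})
    unknown = [c for c in cells if c not in cell_metadata.index]
    if unknown:
        raise ResolutionError(f"cell line(s) absent from metadata: {unknown}")
    combo_code = {c: i for i, c in enumerate(combos)}
    cell_code = {c: i for i, c in enumerate(cells)}

    def codes(column: str) -> dict[str, int]:
        cats = sorted(set(cell_metadata.loc[cells, column]))
        return {c: i for i, c in enumerate(cats)}

    tissue_code = codes("TISSUE")
    disease_code = codes("DISEASE")
    sex_code = codes("SEX")

    rows = []
    for e in experiments:
        meta = cell_metadata.loc[e.cell_id]
        rows.append(
            {
                "COMBINATION_ID_CODE": combo_code[e.combo.combo_id],
                "CELL_LINE_CODE": cell_code[e.cell_id],
                "TISSUE_CODE": tissue_code[meta["TISSUE"]],
                "DISEASE_CODE": disease_code[meta["DISEASE"]],
                "SEX_CODE": sex_code[meta["SEX"]],
            }
        )
    values = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        [e.key for e in experiments], names=["COMBINATION_ID", "CELL_LINE"]))
    groups = {
        "COMBINATION_ID_CODE": "combination id",
        "CELL_LINE_CODE": "cell line id",
        "TISSUE_CODE": "tissue",
        "DISEASE_CODE": "disease",
        "SEX_CODE": "sex",
    }
    return FeatureBlock(values=values, groups=groups, key="experiment")


def assemble_feature_matrix(
    experiments: Sequence[ExperimentRecord],
    blocks: Sequence[FeatureBlock],
) -> FeatureMatrix:
    """Join provider blocks into the experiment-level feature matrix.

    Column order is deterministic: blocks are concatenated, then columns are
    sorted by (group label, column name).  Every experiment must resolve in
    every block; a duplicate feature name across blocks is an assembly error.
    The result contains no missing values.
    """
    row_keys = [e.key for e in experiments]
    if len(set(row_keys)) != len(row_keys):
        dupes = sorted({k for k in row_keys if row_keys.count(k) > 1})
        raise DuplicateKeyError(f"duplicate experiment key(s): {dupes}")
    index = pd.MultiIndex.from_tuples(row_keys, names=["COMBINATION_ID", "CELL_LINE"])

    groups: dict[str, str] = {}
    pieces: list[pd.DataFrame] = []
    for block in blocks:
        dup_in_block = block.values.columns[block.values.columns.duplicated()]
        if len(dup_in_block):
            raise AssemblyError(f"provider returned duplicate column(s): {sorted(set(dup_in_block))}")
        clash = set(block.values.columns) & set(groups)
        if clash:
            raise AssemblyError(f"duplicate feature name(s) across providers: {sorted(clash)}")
        if block.key == "combo":
            keys = [e.combo.combo_id for e in experiments]
            kind = "combination"
        elif block.key == "cell":
            keys = [e.cell_id for e in experiments]
            kind = "cell line"
        else:
            keys = row_keys
            kind = "experiment"
        unresolved = sorted({k for k in keys if k not in block.values.index})
        if unresolved:
            raise ResolutionError(f"unknown {kind} id(s) in feature block: {unresolved}")
        piece = block.values.loc[keys]
        piece.index = index
        pieces.append(piece)
        groups.update(block.groups)

    values = pd.concat(pieces, axis=1)
    order = sorted(values.columns, key=lambda c: (groups[c], c))
    values = values[order].astype(float)
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise AssemblyError(f"missing values after assembly in column(s): {bad}")
    return FeatureMatrix(row_keys=row_keys, values=values, groups=groups)
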