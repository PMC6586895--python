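"""Combination-level drug features.

Every drug-pair feature uses the pair-sum encoding: the elementwise sum of
the two drugs' binary indicator vectors, so a 2 marks a feature shared by
both drugs, a 1 a feature of exactly one drug and a 0 a feature of neither.
The encoding is applied identically to MACCS structural keys, target sets,
target-protein domain sets and targeted-pathway sets, and is symmetric under
drug swap by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    GROUP_CHEMICAL,
    GROUP_DOMAINS,
    GROUP_MONOTHERAPY,
    GROUP_PATHWAYS,
    GROUP_TARGETS,
    MACCS_LENGTH,
    CombinationKey,
    DrugRecord,
    ExperimentRecord,
    FeatureBlock,
)
from .errors import ChemistryError, ConfigError, DimensionError

logger = logging.getLogger(__name__)


@dataclass
class PairEncodedVector:
    """0/1/2 shared-feature codes for a drug pair over an ordered vocabulary."""

    values: np.ndarray
    vocabulary: list[str]
    group: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.vocabulary),):
            raise DimensionError(
                f"pair encoding has {self.values.size} entries for a vocabulary "
                f"of {len(self.vocabulary)}"
            )
        if self.values.size and not np.isin(self.values, (0, 1, 2)).all():
            raise ValueError("pair encoding entries must be in {0, 1, 2}")


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

class RdkitFingerprinter:
    """Computes 166-key MACCS structural fingerprints with rdkit.

    rdkit emits a 167-bit vector whose bit 0 is unused padding; bits 1..166
    form the standard MACCS key dictionary and are returned here.
    """

    def __call__(self, smiles: str, drug_id: str = "?") -> np.ndarray:
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys

        mol = Chem.MolFromSmiles(smiles, sanitize=True)
        if mol is None:
            raise ChemistryError(f"unparseable SMILES for drug {drug_id!r}: {smiles!r}")
        bv = MACCSkeys.GenMACCSKeys(mol)
        arr = np.zeros(MACCS_LENGTH, dtype=np.int8)
        for bit in bv.GetOnBits():
            if bit >= 1:
                arr[bit - 1] = 1
        return arr


class TableFingerprinter:
    """File-backed provider reading a DRUG_ID -> bitstring CSV.

    Keeps the chemistry toolkit out of the loop for tests and for drugs whose
    fingerprints were precomputed elsewhere.
    """

    def __init__(self, path: str | Path):
        df = pd.read_csv(path, dtype=str)
        self._table: dict[str, np.ndarray] = {}
        for row in df.itertuples(index=False):
            bits = np.fromiter((int(ch) for ch in row.FINGERPRINT), dtype=np.int8)
            if bits.size != MACCS_LENGTH:
                raise DimensionError(
                    f"fingerprint of {row.DRUG_ID!r} has {bits.size} bits, "
                    f"expected {MACCS_LENGTH}"
                )
            self._table[row.DRUG_ID] = bits

    def __call__(self, smiles: str, drug_id: str = "?") -> np.ndarray:
        try:
            return self._table[drug_id]
        except KeyError:
            raise ChemistryError(f"no precomputed fingerprint for drug {drug_id!r}") from None


def maccs_fingerprint(
    smiles: str | None,
    drug_id: str = "?",
    provider=None,
) -> tuple[np.ndarray, bool]:
    """Return (166-bit vector, missing flag) for a SMILES string.

    A missing SMILES yields the all-zero vector with the missing flag set so
    that downstream imputation can add a missingness indicator.
    """
    if smiles is None or smiles == "":
        return np.zeros(MACCS_LENGTH, dtype=np.int8), True
    provider = provider or RdkitFingerprinter()
    return np.asarray(provider(smiles, drug_id), dtype=np.int8), False


# ---------------------------------------------------------------------------
# Pair encodings
# ---------------------------------------------------------------------------

def pairsum_encode(
    vec_a: np.ndarray,
    vec_b: np.ndarray,
    vocabulary: Sequence[str] | None = None,
    group: str = GROUP_CHEMICAL,
) -> PairEncodedVector:
    """Elementwise sum of two binary vectors; symmetric in its arguments."""
    a = np.asarray(vec_a, dtype=np.int64)
    b = np.asarray(vec_b, dtype=np.int64)
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.size} vs {b.size}")
    vocab = list(vocabulary) if vocabulary is not None else [f"BIT{i + 1}" for i in range(a.size)]
    return PairEncodedVector(values=a + b, vocabulary=vocab, group=group)


def set_features(
    set_a: Iterable[str],
    set_b: Iterable[str],
    vocabulary: Sequence[str],
    group: str = GROUP_TARGETS,
) -> PairEncodedVector:
    """Indicator-then-pairsum encoding of two id sets over a vocabulary.

    Ids outside the vocabulary are dropped with a logged warning — the
    challenge-style annotation lists are known to be incomplete.
    """
    vocab = list(vocabulary)
    if not vocab:
        raise ConfigError("empty vocabulary")
    pos = {v: i for i, v in enumerate(vocab)}
    vecs = []
    for s in (set(set_a), set(set_b)):
        unknown = s - set(pos)
        if unknown:
            logger.warning("ids outside vocabulary dropped: %s", sorted(unknown))
        v = np.zeros(len(vocab), dtype=np.int64)
        for item in s & set(pos):
            v[pos[item]] = 1
        vecs.append(v)
    return PairEncodedVector(values=vecs[0] + vecs[1], vocabulary=vocab, group=group)


def derive_domains_pathways(
    targets: Iterable[str],
    domain_maps: Mapping[str, Mapping[str, Iterable[str]]],
    pathway_map: Mapping[str, Iterable[str]],
) -> tuple[set[str], set[str]]:
    """Union of mapped structural domains (namespaced by source) and pathways.

    A target protein absent from every map contributes nothing; the putative
    target lists are incomplete, so this is logged rather than raised.
    """
    domains: set[str] = set()
    pathways: set[str] = set()
    for protein in targets:
        hit = False
        for source, mapping in domain_maps.items():
            for dom in mapping.get(protein, ()):  # namespaced e.g. pfam:PF00069
                domains.add(dom if dom.startswith(f"{source}:") else f"{source}:{dom}")
                hit = True
        if protein in pathway_map:
            pathways.update(pathway_map[protein])
            hit = True
        if not hit:
            logger.info("target %r absent from all vocabular maps", protein)
    return domains, pathways


def concat_domain_vocabulary(domain_vocabs: Mapping[str, Sequence[str]]) -> list[str]:
    """Concatenate per-source domain vocabularies into one namespaced list."""
    vocab: list[str] = []
    for source in domain_vocabs:
        for dom in domain_vocabs[source]:
            vocab.append(dom if dom.startswith(f"{source}:") else f"{source}:{dom}")
    if len(set(vocab)) != len(vocab):
        raise ConfigError("domain vocabularies collide after namespacing")
    return vocab


# ---------------------------------------------------------------------------
# Monotherapy
# ---------------------------------------------------------------------------

MONOTHERAPY_FIELDS = ["MAX_CONC", "IC50", "IC50_CENSORED", "H", "Einf", "QA"]


def monotherapy_vector(exp: ExperimentRecord) -> tuple[np.ndarray, list[str]]:
    """12 dose-response features (+2 censoring flags) in canonical drug order.

    A censored IC50 (not reached within the tested range) is imputed with the
    drug's maximum tested concentration and flagged, preserving the ordering
    information that the true IC50 lies at or above that concentration.
    """
    values: list[float] = []
    names: list[str] = []
    for side, block in (("A", exp.mono_a), ("B", exp.mono_b)):
        censored = block.ic50 is None
        ic50 = block.max_conc if censored else block.ic50
        values.extend([block.max_conc, ic50, float(censored), block.hill_h,
                       block.einf, float(block.qa)])
        names.extend(f"MONO_{side}_{f}" for f in MONOTHERAPY_FIELDS)
    return np.asarray(values, dtype=float), names


def monotherapy_block(experiments: Sequence[ExperimentRecord]) -> FeatureBlock:
    rows = []
    names: list[str] | None = None
    for e in experiments:
        vec, names = monotherapy_vector(e)
        rows.append(vec)
    values = pd.DataFrame(
        rows,
        columns=names,
        index=pd.MultiIndex.from_tuples([e.key for e in experiments],
                                        names=["COMBINATION_ID", "CELL_LINE"]),
    )
    return FeatureBlock(values=values,
                        groups={n: GROUP_MONOTHERAPY for n in names},
                        key="experiment")


# ---------------------------------------------------------------------------
# Combination-level provider
# ---------------------------------------------------------------------------

def combo_drug_block(
    combos: Sequence[CombinationKey],
    drugs: Mapping[str, DrugRecord],
    target_vocab: Sequence[str],
    domain_vocab: Sequence[str],
    pathway_vocab: Sequence[str],
) -> FeatureBlock:
    """Chemical, target, domain and pathway pair encodings per combination.

    Drugs with no fingerprint contribute zeros; MACCS_MISSING counts how many
    of the two fingerprints were unavailable (0, 1 or 2).
    """
    zero_fp = np.zeros(MACCS_LENGTH, dtype=np.int8)
    rows = []
    index = []
    maccs_names = [f"MACCS_{i + 1}" for i in range(MACCS_LENGTH)]
    columns = (maccs_names + ["MACCS_MISSING"]
               + [f"TARGET_{t}" for t in target_vocab]
               + [f"DOMAIN_{d}" for d in domain_vocab]
               + [f"PATHWAY_{p}" for p in pathway_vocab])
    for combo in combos:
        da, db = drugs[combo.drug_a], drugs[combo.drug_b]
        fa = da.fingerprint if da.fingerprint is not None else zero_fp
        fb = db.fingerprint if db.fingerprint is not None else zero_fp
        n_missing = int(da.fingerprint is None) + int(db.fingerprint is None)
        chem = pairsum_encode(fa, fb, maccs_names, GROUP_CHEMICAL)
        targ = set_features(da.targets, db.targets, target_vocab, GROUP_TARGETS)
        doms = set_features(da.domains, db.domains, domain_vocab, GROUP_DOMAINS)
        path = set_features(da.pathways, db.pathways, pathway_vocab, GROUP_PATHWAYS)
        rows.append(np.concatenate([chem.values, [n_missing], targ.values,
                                    doms.values, path.values]))
        index.append(combo.combo_id)
    values = pd.DataFrame(rows, columns=columns, index=index)
    values = values[~values.index.duplicated()]
    groups = {n: GROUP_CHEMICAL for n in maccs_names}
    groups["MACCS_MISSING"] = GROUP_CHEMICAL
    groups.update({f"TARGET_{t}": GROUP_TARGETS for t in target_vocab})
    groups.update({f"DOMAIN_{d}": GROUP_DOMAINS for d in domain_vocab})
    groups.update({f"PATHWAY_{p}": GROUP_PATHWAYS for p in pathway_vocab})
    return FeatureBlock(values=values, groups=groups, key="combo")
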