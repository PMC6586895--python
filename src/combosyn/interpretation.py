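"""Model interpretation: gain-based feature importance, feature-class
aggregation, and distributional target-association tests.

Gain importance is the fractional contribution of each feature to the total
split-quality improvement of a boosted (or bagged) tree ensemble; summing
the fractions of a feature class gives the class's net importance.  The
target-association test compares the synergy-score distributions of
experiments whose combination carries a given annotation (e.g. either drug
targets a protein) against those that do not, with a two-sample
Kolmogorov-Smirnov statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .data_model import DrugRecord, ExperimentRecord
from .errors import StratificationError
from .modeling import FittedModel

logger = logging.getLogger(__name__)


@dataclass
class ImportanceReport:
    per_feature_gain: pd.Series  # normalized, sums to 1
    per_group_gain: pd.Series  # descending


def gain_importance(model: FittedModel) -> pd.Series:
    """Normalized per-feature gain shares of a tree ensemble.

    Features the ensemble never split on get exactly 0; the shares sum to 1.
    """
    gains = model.raw_gains().astype(float)
    total = gains.sum()
    if total <= 0:
        # a constant-target ensemble makes no splits; spread nothing
        return gains * 0.0
    return gains / total


def group_importance(
    per_feature_gain: pd.Series, groups: Mapping[str, str]
) -> pd.Series:
    """Sum feature gains within each feature class, sorted descending."""
    labels = []
    for feat in per_feature_gain.index:
        if feat not in groups:
            logger.warning("feature %r has no group; counted as 'ungrouped'", feat)
        labels.append(groups.get(feat, "ungrouped"))
    sums = per_feature_gain.groupby(pd.Index(labels, name="group")).sum()
    return sums.sort_values(ascending=False)


def importance_report(model: FittedModel, groups: Mapping[str, str]) -> ImportanceReport:
    per_feature = gain_importance(model)
    return ImportanceReport(per_feature_gain=per_feature,
                            per_group_gain=group_importance(per_feature, groups))


def combos_carrying_target(
    drugs: Mapping[str, DrugRecord],
    target: str,
    kind: str = "targets",
) -> set[str]:
    """Drug ids -> set of drugs carrying an annotation; helper for stratification."""
    return {d.drug_id for d in drugs.values() if target in getattr(d, kind)}


def ks_target_association(
    experiments: Sequence[ExperimentRecord],
    carrier_drugs: set[str],
) -> tuple[float, float, int]:
    """Two-sample KS test of synergy distributions by annotation carriage.

    An experiment is in the carrier stratum when either drug of its
    combination is in ``carrier_drugs`` (pair-encoded entry > 0).  Returns
    (D, two-sided asymptotic p, direction) where direction is the sign of
    the carrier-minus-noncarrier median synergy difference: +1 means the
    annotation favours synergy, -1 antagonism.
    """
    carrier, other = [], []
    for e in experiments:
        if e.combo.drug_a in carrier_drugs or e.combo.drug_b in carrier_drugs:
            carrier.append(e.synergy)
        else:
            other.append(e.synergy)
    if not carrier or not other:
        raise StratificationError(
            "both carrier and non-carrier strata must be non-empty")
    res = ks_2samp(carrier, other, method="asymp")
    direction = int(np.sign(np.median(carrier) - np.median(other)))
    return float(res.statistic), float(res.pvalue), direction
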