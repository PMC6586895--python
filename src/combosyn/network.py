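"""The drug synergy network and its link-prediction proximity features.

Two drugs are connected when the majority of their combination's synergy
scores across cell lines exceeds the synergy threshold (20 on the
Loewe-excess scale).  Three indices borrowed from social-network link
prediction are computed on this graph for any query pair: the number of
common neighbours, the Jaccard coefficient of the neighbourhoods, and the
Adamic-Adar index (common neighbours down-weighted by the natural log of
their degree).
"""

from __future__ import annotations

import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .data_model import GROUP_NETWORK, ExperimentRecord, FeatureBlock
from .errors import LabelingError

SYNERGY_THRESHOLD = 20.0

NETWORK_FEATURES = ["NET_COMMON_NEIGHBORS", "NET_JACCARD", "NET_ADAMIC_ADAR"]


class SynergyNetwork:
    """Undirected graph over drug ids; no self loops, symmetric adjacency."""

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[tuple[str, str]] = ()):
        self._adj: dict[str, set[str]] = {}
        for n in nodes:
            self.add_node(n)
        for a, b in edges:
            self.add_edge(a, b)

    def add_node(self, node: str) -> None:
        self._adj.setdefault(node, set())

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self loop on {a!r}")
        self.add_node(a)
        self.add_node(b)
        self._adj[a].add(b)
        self._adj[b].add(a)

    def remove_edge(self, a: str, b: str) -> None:
        self._adj[a].discard(b)
        self._adj[b].discard(a)

    def has_edge(self, a: str, b: str) -> bool:
        return b in self._adj.get(a, set())

    @property
    def nodes(self) -> set[str]:
        return set(self._adj)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, nbrs in self._adj.items() for b in nbrs}

    def neighbors(self, node: str) -> set[str]:
        """Γ(node); an unknown drug is treated as an isolated node."""
        return set(self._adj.get(node, set()))

    def degree(self, node: str) -> int:
        return len(self._adj.get(node, set()))

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for edge in sorted(tuple(sorted(e)) for e in self.edges):
                fh.write(f"{edge[0]}\t{edge[1]}\n")


def label_combination_synergistic(
    scores: Sequence[float], threshold: float = SYNERGY_THRESHOLD
) -> bool:
    """True iff strictly more than half of the scores strictly exceed threshold.

    A tie (exactly half) is not a majority, and a score equal to the threshold
    does not count as synergistic.
    """
    if len(scores) == 0:
        raise LabelingError("cannot label a combination with no scores")
    return 2 * sum(s > threshold for s in scores) > len(scores)


def build_network(
    experiments: Sequence[ExperimentRecord],
    threshold: float = SYNERGY_THRESHOLD,
) -> SynergyNetwork:
    """Build the synergy network from (typically training) experiments."""
    by_combo: dict[tuple[str, str, str], list[float]] = defaultdict(list)
    net = SynergyNetwork()
    for e in experiments:
        net.add_node(e.combo.drug_a)
        net.add_node(e.combo.drug_b)
        by_combo[(e.combo.combo_id, e.combo.drug_a, e.combo.drug_b)].append(e.synergy)
    for (_, a, b), scores in by_combo.items():
        if label_combination_synergistic(scores, threshold):
            net.add_edge(a, b)
    return net


def common_neighbors(net: SynergyNetwork, x: str, y: str) -> int:
    return len(net.neighbors(x) & net.neighbors(y))


def jaccard(net: SynergyNetwork, x: str, y: str) -> float:
    """|Γ(x)∩Γ(y)| / |Γ(x)∪Γ(y)|; 0 when the union is empty."""
    union = net.neighbors(x) | net.neighbors(y)
    if not union:
        return 0.0
    return len(net.neighbors(x) & net.neighbors(y)) / len(union)


def adamic_adar(net: SynergyNetwork, x: str, y: str) -> float:
    """Σ over common neighbours z of 1/ln|Γ(z)| (natural logarithm).

    For distinct x, y every common neighbour has degree ≥ 2, so each term
    is finite.
    """
    total = 0.0
    for z in net.neighbors(x) & net.neighbors(y):
        total += 1.0 / math.log(net.degree(z))
    return total


def pair_network_features(
    train_experiments: Sequence[ExperimentRecord],
    query_pairs: Sequence[tuple[str, str, str]],
    threshold: float = SYNERGY_THRESHOLD,
    leakage_guard: bool = True,
) -> FeatureBlock:
    """Three proximity features per (combo_id, drug_a, drug_b) query.

    The network is built from the training experiments only.  With the
    leakage guard on (default), a query pair's own edge is removed before its
    features are computed, so a pair never sees its own synergy label.
    Drugs unseen in training are isolated nodes with all features 0.
    """
    net = build_network(train_experiments, threshold)
    rows = []
    index = []
    for combo_id, a, b in query_pairs:
        restore = False
        if leakage_guard and net.has_edge(a, b):
            net.remove_edge(a, b)
            restore = True
        rows.append([common_neighbors(net, a, b), jaccard(net, a, b),
                     adamic_adar(net, a, b)])
        if restore:
            net.add_edge(a, b)
        index.append(combo_id)
    values = pd.DataFrame(rows, columns=NETWORK_FEATURES, index=index)
    values = values[~values.index.duplicated()]
    return FeatureBlock(values=values,
                        groups={n: GROUP_NETWORK for n in NETWORK_FEATURES},
                        key="combo")
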