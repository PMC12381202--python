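"""Node-level network indices and the shared figure layout.

Strength centrality (SC) is the sum of absolute incident edge weights;
expected influence (EI) the signed sum (one-step); bridge expected
influence (BEI) the signed sum of edges crossing community boundaries.
Predictability is the share of a node's variance explained by its selected
neighbors (OLS R^2).  Communities are fixed a priori by scale membership
(depression / anxiety / stress / parental).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ggm import SymptomNetwork

__all__ = [
    "bridge_expected_influence",
    "centrality_table",
    "expected_influence",
    "fr_layout",
    "predictability",
    "strength",
]


def _row(network: SymptomNetwork, node):
    return network.weights[network.index(node)]


def strength(network: SymptomNetwork, node=None):
    """SC: sum of |w| over incident edges (all nodes when node is None)."""
    if node is not None:
        return float(np.abs(_row(network, node)).sum())
    return pd.Series(np.abs(network.weights).sum(axis=1),
                     index=network.labels, name="SC")


def expected_influence(network: SymptomNetwork, node=None):
    """EI: signed sum of incident edge weights (one-step)."""
    if node is not None:
        return float(_row(network, node).sum())
    return pd.Series(network.weights.sum(axis=1), index=network.labels,
                     name="EI")


def bridge_expected_influence(network: SymptomNetwork, communities=None,
                              node=None):
    """BEI: signed sum of edges to nodes in *other* communities."""
    communities = communities or network.communities
    if communities is None:
        raise ValueError("no community assignment available")
    missing = [lab for lab in network.labels if communities.get(lab) is None]
    if missing:
        raise ValueError(f"node(s) without community: {', '.join(missing)}")
    com = np.array([communities[lab] for lab in network.labels])
    cross = com[:, None] != com[None, :]
    bei = (network.weights * cross).sum(axis=1)
    if node is not None:
        return float(bei[network.index(node)])
    return pd.Series(bei, index=network.labels, name="BEI")


def predictability(items: pd.DataFrame, network: SymptomNetwork) -> pd.Series:
    """Per-node R^2 of an OLS regression on the node's nonzero-edge
    neighbors; 0 for isolated nodes.  Index order follows the network."""
    X = items[network.labels].to_numpy(dtype=float)
    n = X.shape[0]
    out = np.zeros(network.p)
    for i in range(network.p):
        nbr = np.nonzero(network.weights[i])[0]
        if len(nbr) == 0:
            continue
        if n <= len(nbr) + 1:
            raise ValueError(
                f"n={n} too small for node {network.labels[i]} with "
                f"{len(nbr)} neighbors")
        y = X[:, i]
        A = np.column_stack([np.ones(n), X[:, nbr]])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        tss = ((y - y.mean()) ** 2).sum()
        out[i] = 0.0 if tss == 0 else 1.0 - (resid ** 2).sum() / tss
    return pd.Series(out, index=network.labels, name="R2")


def centrality_table(network: SymptomNetwork, items=None,
                     communities=None) -> pd.DataFrame:
    """Per-node SC / EI / BEI (and R^2 when items are given) with
    within-network z-standardized variants."""
    tab = pd.DataFrame({"SC": strength(network),
                        "EI": expected_influence(network)})
    communities = communities or network.communities
    if communities:
        tab["BEI"] = bridge_expected_influence(network, communities)
    if items is not None:
        tab["R2"] = predictability(items, network)
    for col in ("SC", "EI", "BEI"):
        if col in tab:
            sd = tab[col].std(ddof=0)
            tab[f"z_{col}"] = 0.0 if sd == 0 else (tab[col] - tab[col].mean()) / sd
    return tab


def fr_layout(networks, seed=0) -> dict:
    """Shared Fruchterman-Reingold layout: per-network force-directed
    coordinates (seeded, deterministic), averaged coordinate-wise across
    networks so paired figures are directly comparable."""
    import networkx as nx
    networks = list(networks)
    if not networks:
        raise ValueError("need at least one network")
    labels = networks[0].labels
    for net in networks[1:]:
        if net.labels != labels:
            raise ValueError("networks must share the same node set")
    coords = []
    for net in networks:
        G = nx.Graph()
        G.add_nodes_from(labels)
        iu = np.triu_indices(net.p, 1)
        for i, j in zip(*iu):
            w = net.weights[i, j]
            if w != 0.0:
                G.add_edge(labels[i], labels[j], weight=abs(w))
        pos = nx.spring_layout(G, seed=seed, weight="weight")
        coords.append(pos)
    return {lab: tuple(np.mean([c[lab] for c in coords], axis=0))
            for lab in labels}
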