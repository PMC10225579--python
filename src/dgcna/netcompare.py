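"""Cross-dataset comparison of differential co-expression networks.

Two networks are compared by treating their DCL calls as binary labelings of
a shared edge universe (the union of pairs tested in any network, restricted
to genes present in every dataset) and computing adjusted mutual information
(AMI).  The chance correction uses the exact expected mutual information
under the permutation model.  An alternative mode compares gene community
labels (connected components of each DCL network) instead of edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import ParameterError
from .diffcoexp import DiffCoexpNetwork


@dataclass
class EdgeLabeling:
    """Binary DCL labels over an ordered universe of gene pairs."""

    universe: list[tuple[str, str]]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.universe) != len(self.labels):
            raise ParameterError("labels must cover the whole universe")


def _canonical_pairs(frame: pd.DataFrame) -> set[tuple[str, str]]:
    return {
        (i, j) if i < j else (j, i)
        for i, j in zip(frame["gene_i"], frame["gene_j"])
    }


def build_edge_labelings(
    networks: list[DiffCoexpNetwork],
) -> list[EdgeLabeling]:
    """Common edge universe + per-network binary DCL labels.

    The universe is the union over networks of their tested pairs, restricted
    to genes present in every dataset; a pair is labeled 1 in a network iff
    it is one of that network's DCLs.
    """
    if len(networks) < 2:
        raise ParameterError("need >= 2 networks to compare")
    shared_genes = set(networks[0].genes)
    for net in networks[1:]:
        shared_genes &= set(net.genes)
    if not shared_genes:
        raise ParameterError("networks share no genes")
    universe: set[tuple[str, str]] = set()
    for net in networks:
        universe |= {
            pair
            for pair in _canonical_pairs(net.pairs)
            if pair[0] in shared_genes and pair[1] in shared_genes
        }
    ordered = sorted(universe)
    out = []
    for net in networks:
        dcls = _canonical_pairs(net.dcls)
        labels = np.fromiter((1 if pair in dcls else 0 for pair in ordered), dtype=int)
        out.append(EdgeLabeling(ordered, labels))
    return out


# ---------------------------------------------------------------------------
# adjusted mutual information (exact permutation-model expectation)

def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def expected_mutual_information(a_counts: np.ndarray, b_counts: np.ndarray, n: int) -> float:
    """E[MI] over contingency tables with fixed margins (permutation model)."""
    emi = 0.0
    log_fact = gammaln(np.arange(0, n + 2) + 1.0)  # log(k!)
    for ai in a_counts:
        for bj in b_counts:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = (nij / n) * np.log(n * nij / (ai * bj))
                log_w = (
                    log_fact[ai]
                    + log_fact[bj]
                    + log_fact[n - ai]
                    + log_fact[n - bj]
                    - log_fact[n]
                    - log_fact[nij]
                    - log_fact[ai - nij]
                    - log_fact[bj - nij]
                    - log_fact[n - ai - bj + nij]
                )
                emi += term * np.exp(log_w)
    return emi


def adjusted_mutual_information(a, b) -> float:
    """AMI between two labelings: (MI − E[MI]) / (mean(H) − E[MI]).

    Invariant to label renaming; 1 for identical non-constant labelings,
    ≈ 0 for independent ones.  Two constant labelings are defined as 0 with
    a warning (there is no information to agree on).
    """
    la = a.labels if isinstance(a, EdgeLabeling) else np.asarray(a)
    lb = b.labels if isinstance(b, EdgeLabeling) else np.asarray(b)
    if isinstance(a, EdgeLabeling) and isinstance(b, EdgeLabeling):
        if a.universe != b.universe:
            raise ParameterError("labelings must share the same universe")
    if len(la) != len(lb):
        raise ParameterError("labelings must have equal length")
    n = len(la)
    _, ca = np.unique(la, return_inverse=True)
    _, cb = np.unique(lb, return_inverse=True)
    ka, kb = ca.max() + 1, cb.max() + 1
    table = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(table, (ca, cb), 1)
    a_counts = table.sum(axis=1)
    b_counts = table.sum(axis=0)
    h_a, h_b = _entropy(a_counts, n), _entropy(b_counts, n)
    if h_a == 0.0 and h_b == 0.0:
        warnings.warn("both labelings constant; AMI defined as 0", stacklevel=2)
        return 0.0
    nz = table > 0
    mi = float(
        (table[nz] / n * np.log(n * table[nz] / np.outer(a_counts, b_counts)[nz])).sum()
    )
    emi = expected_mutual_information(a_counts, b_counts, n)
    denom = 0.5 * (h_a + h_b) - emi
    if abs(denom) < 1e-15:
        return 0.0
    return float((mi - emi) / denom)


# ---------------------------------------------------------------------------
# pairwise comparison

@dataclass
class ComparisonMatrix:
    names: list[str]
    ami: pd.DataFrame  # symmetric, unit diagonal
    shared_dcl_genes: dict[tuple[str, str], list[str]]
    mode: str = "edges"


def _community_labels(net: DiffCoexpNetwork, genes: list[str]) -> np.ndarray:
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    shared = set(genes)
    for i, j in _canonical_pairs(net.dcls):
        if i in shared and j in shared:
            graph.add_edge(i, j)
    label_of: dict[str, int] = {}
    next_label = 1
    for component in nx.connected_components(graph):
        if len(component) > 1:
            for g in component:
                label_of[g] = next_label
            next_label += 1
    return np.array([label_of.get(g, 0) for g in genes])


def pairwise_ami(
    networks: dict[str, DiffCoexpNetwork], mode: str = "edges"
) -> ComparisonMatrix:
    """AMI for every unordered pair of networks plus shared DCL genes.

    ``mode='edges'`` compares binary DCL labels over the shared tested-pair
    universe; ``mode='communities'`` compares gene labels from connected
    components of each DCL network over the shared gene set.
    """
    names = list(networks)
    if len(names) < 2:
        raise ParameterError("need >= 2 networks")
    nets = [networks[name] for name in names]
    if mode == "edges":
        labelings = build_edge_labelings(nets)
    elif mode == "communities":
        shared = sorted(set.intersection(*(set(net.genes) for net in nets)))
        if not shared:
            raise ParameterError("networks share no genes")
        labelings = [_community_labels(net, shared) for net in nets]
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    k = len(names)
    ami = np.eye(k)
    shared_genes: dict[tuple[str, str], list[str]] = {}
    dcl_gene_sets = [
        set(net.dcls["gene_i"]) | set(net.dcls["gene_j"]) for net in nets
    ]
    for i in range(k):
        for j in range(i + 1, k):
            value = adjusted_mutual_information(labelings[i], labelings[j])
            ami[i, j] = ami[j, i] = value
            shared_genes[(names[i], names[j])] = sorted(
                dcl_gene_sets[i] & dcl_gene_sets[j]
            )
    return ComparisonMatrix(
        names=names,
        ami=pd.DataFrame(ami, index=names, columns=names),
        shared_dcl_genes=shared_genes,
        mode=mode,
    )
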