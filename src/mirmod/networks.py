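"""Hub analysis and the two bias-control comparator networks.

A high-degree miRNA in the modulation network could in principle be an
artifact of either (i) sharing unusually many targets with other miRNAs or
(ii) plain expression correlation.  The two comparators isolate those
explanations:

* :func:`shared_target_network` depends **only** on the target table — no
  expression argument exists — and links two miRNAs when their shared-target
  count is hypergeometrically surprising given the target universe;
* :func:`correlation_network` links miRNAs whose (Spearman, by default)
  expression correlation survives Benjamini–Hochberg correction.

:func:`compare_networks` summarizes how much either comparator explains of
the modulation network (edge Jaccard, degree rank correlation, hubs present
in one but not the other).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .inference import MiRNANetwork
from .io import ExpressionMatrix, TargetNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "HubReport",
    "NetworkComparison",
    "hub_report",
    "shared_target_network",
    "correlation_network",
    "compare_networks",
    "read_graphml",
]


@dataclass
class HubReport:
    """Degree summary of a miRNA network."""

    degree: dict[str, int]
    degree_rank: dict[str, int]
    connection_fraction: dict[str, float]
    top: list[tuple[str, int]]
    mean_degree: float
    min_degree: int
    max_degree: int

    @property
    def top_nodes(self) -> list[str]:
        return [n for n, _ in self.top]


def hub_report(net: MiRNANetwork, k: int = 10) -> HubReport:
    """Per-node degree statistics and the top-``k`` hub list.

    The connection fraction is degree/(|nodes|−1), i.e. the share of other
    network miRNAs a node touches.  Ties are broken lexicographically but
    tied nodes at the k-th degree are all reported.
    """
    nodes = net.nodes
    if not nodes:
        raise ValueError("cannot summarize an empty network")
    degree = {n: int(net.graph.degree(n)) for n in nodes}
    by_deg = sorted(nodes, key=lambda n: (-degree[n], n))
    rank = {n: i + 1 for i, n in enumerate(by_deg)}
    denom = max(len(nodes) - 1, 1)
    frac = {n: degree[n] / denom for n in nodes}
    top = [(n, degree[n]) for n in by_deg[:k]]
    cutoff = top[-1][1] if top else 0
    for n in by_deg[k:]:  # report nodes tied with the k-th hub
        if degree[n] != cutoff:
            break
        top.append((n, degree[n]))
    degs = np.array([degree[n] for n in nodes])
    return HubReport(
        degree=degree,
        degree_rank=rank,
        connection_fraction=frac,
        top=top,
        mean_degree=float(degs.mean()),
        min_degree=int(degs.min()),
        max_degree=int(degs.max()),
    )


def shared_target_network(targets: TargetNetwork, alpha: float = 0.05) -> MiRNANetwork:
    """miRNA pairs linked by a surprising number of shared mRNA targets.

    The urn is the set of all mRNAs appearing in the target table (size M);
    for a pair with target-set sizes n1, n2 and overlap k, the edge p-value
    is the hypergeometric upper tail P(X ≥ k).  Edges carry the shared count
    and p so users can threshold the raw count directly instead.
    """
    if targets.n_edges == 0:
        raise ValueError("empty target network")
    target_sets = {a: targets.targets(a) for a in sorted(targets.mirnas)}
    universe = targets.mrnas
    M = len(universe)
    mirnas = sorted(target_sets)
    rows = []
    graph = nx.Graph()
    for i, a in enumerate(mirnas):
        for b in mirnas[i + 1 :]:
            shared = len(target_sets[a] & target_sets[b])
            p = float(
                stats.hypergeom.sf(
                    shared - 1, M, len(target_sets[a]), len(target_sets[b])
                )
            )
            rows.append((a, b, shared, len(target_sets[a]), len(target_sets[b]), p))
            if shared > 0 and p < alpha:
                graph.add_edge(a, b, shared_targets=shared, p=p)
    pairs = pd.DataFrame(
        rows, columns=["mir_a", "mir_b", "shared_targets", "n_a", "n_b", "p"]
    )
    pairs["significant"] = (pairs["shared_targets"] > 0) & (pairs["p"] < alpha)
    return MiRNANetwork(graph=graph, pairs=pairs)


def correlation_network(
    mir: ExpressionMatrix,
    method: str = "spearman",
    alpha: float = 0.05,
    multiple_testing: str = "bh",
) -> MiRNANetwork:
    """miRNA pairs with significant (|r|-based, two-sided) expression correlation.

    Constant rows are dropped with a warning; p-values come from the usual
    t approximation and are Benjamini–Hochberg adjusted before thresholding.
    Anti-correlated pairs qualify: the test is two-sided in r.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if multiple_testing != "bh":
        raise ValueError("only Benjamini-Hochberg ('bh') correction is supported")
    n = mir.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples for the correlation network")
    keep = [i for i, row in enumerate(mir.values) if not np.all(row == row[0])]
    if len(keep) < len(mir.feature_ids):
        dropped = sorted(set(mir.feature_ids) - {mir.feature_ids[i] for i in keep})
        logger.warning("dropping %d constant rows: %s", len(dropped), dropped)
    ids = [mir.feature_ids[i] for i in keep]
    X = mir.values[keep]
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 1, X)
    corr = np.corrcoef(X)
    order = np.argsort(ids, kind="stable")
    rows = []
    for oi in range(len(ids)):
        for oj in range(oi + 1, len(ids)):
            i, j = order[oi], order[oj]
            r = float(np.clip(corr[i, j], -1.0, 1.0))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), n - 2))
            rows.append((ids[i], ids[j], r, p))
    pairs = pd.DataFrame(rows, columns=["mir_a", "mir_b", "correlation", "p"])
    from statsmodels.stats.multitest import multipletests

    if pairs.empty:
        pairs["q"] = pairs["significant"] = []
        return MiRNANetwork(graph=nx.Graph(), pairs=pairs)
    pairs["q"] = multipletests(pairs["p"], method="fdr_bh")[1]
    pairs["significant"] = pairs["q"] < alpha
    graph = nx.Graph()
    for row in pairs[pairs["significant"]].itertuples(index=False):
        graph.add_edge(
            row.mir_a, row.mir_b, correlation=float(row.correlation), q=float(row.q)
        )
    return MiRNANetwork(graph=graph, pairs=pairs)


@dataclass
class NetworkComparison:
    """Edge/degree overlap summary between two miRNA networks."""

    edge_jaccard: float
    shared_edges: int
    edges_a: int
    edges_b: int
    degree_rank_correlation: float
    hubs_only_in_a: list[str]
    hubs_only_in_b: list[str]

    def to_dict(self) -> dict:
        return {
            "edge_jaccard": self.edge_jaccard,
            "shared_edges": self.shared_edges,
            "edges_a": self.edges_a,
            "edges_b": self.edges_b,
            "degree_rank_correlation": self.degree_rank_correlation,
            "hubs_only_in_a": self.hubs_only_in_a,
            "hubs_only_in_b": self.hubs_only_in_b,
        }


def compare_networks(a: MiRNANetwork, b: MiRNANetwork, k: int = 10) -> NetworkComparison:
    """Jaccard of edge sets, Spearman correlation of node degrees (over the
    union of nodes, absent = degree 0), and top-``k`` hubs unique to each."""
    ea, eb = a.edges, b.edges
    union = ea | eb
    jaccard = len(ea & eb) / len(union) if union else 1.0
    nodes = sorted(set(a.nodes) | set(b.nodes))
    deg_a = np.array([a.graph.degree(n) if n in a.graph else 0 for n in nodes], float)
    deg_b = np.array([b.graph.degree(n) if n in b.graph else 0 for n in nodes], float)
    if len(nodes) < 2 or np.all(deg_a == deg_a[0]) or np.all(deg_b == deg_b[0]):
        rank_corr = float("nan")
    else:
        rank_corr = float(stats.spearmanr(deg_a, deg_b).statistic)
    hubs_a = set(hub_report(a, k).top_nodes) if a.nodes else set()
    hubs_b = set(hub_report(b, k).top_nodes) if b.nodes else set()
    return NetworkComparison(
        edge_jaccard=jaccard,
        shared_edges=len(ea & eb),
        edges_a=len(ea),
        edges_b=len(eb),
        degree_rank_correlation=rank_corr,
        hubs_only_in_a=sorted(hubs_a - hubs_b),
        hubs_only_in_b=sorted(hubs_b - hubs_a),
    )


def read_graphml(path) -> MiRNANetwork:
    """Load a network written by :func:`~mirmod.inference.write_network_outputs`."""
    graph = nx.read_graphml(path)
    rows = [
        dict(mir_a=min(a, b), mir_b=max(a, b), **attrs)
        for a, b, attrs in graph.edges(data=True)
    ]
    pairs = pd.DataFrame(rows)
    if not pairs.empty:
        pairs = pairs.sort_values(["mir_a", "mir_b"]).reset_index(drop=True)
    return MiRNANetwork(graph=nx.Graph(graph), pairs=pairs)
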