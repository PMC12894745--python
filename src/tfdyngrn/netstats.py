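"""Feature-annotated topology statistics of the consensus network.

All statistics operate on the simple undirected projection of the
network. Assortativity is Newman's nominal mixing coefficient

    r = (Σ_i e_ii − Σ_i a_i b_i) / (1 − Σ_i a_i b_i),

where e is the label mixing matrix over edge endpoints and a, b its
marginals; its significance is assessed against a topology-preserving
null built by shuffling the node labels. Communities come from an
agglomeration over edges ranked by the edge clustering coefficient

    ECC(u, v) = (#triangles on (u,v) + 1) / min(deg u − 1, deg v − 1),

locking a cluster once its internal edges outnumber its external ones
(a cluster that is already denser inside than outside stops growing),
and reporting clusters of at least ``min_size`` nodes.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import rng_for
from .datamodel import DataError, NetworkEdgeTable


def _as_simple_graph(net: NetworkEdgeTable | nx.Graph) -> nx.Graph:
    if isinstance(net, nx.Graph) and not net.is_directed():
        g = nx.Graph(net)
    elif isinstance(net, nx.Graph):
        g = nx.Graph(net.to_undirected(as_view=False))
    else:
        g = nx.Graph(net.to_graph().to_undirected()) if net.directed else nx.Graph(net.to_graph())
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def betweenness(net: NetworkEdgeTable | nx.Graph) -> pd.Series:
    """Exact unnormalised shortest-path betweenness on the simple projection."""
    g = _as_simple_graph(net)
    if g.number_of_nodes() == 0:
        raise DataError("betweenness of an empty graph is undefined")
    scores = nx.betweenness_centrality(g, normalized=False)
    return pd.Series(scores, name="betweenness").sort_index()


def betweenness_by_class(
    net: NetworkEdgeTable | nx.Graph, labels: Mapping[str, str]
) -> pd.DataFrame:
    """Mean/median betweenness per label class."""
    b = betweenness(net)
    df = pd.DataFrame({"betweenness": b, "label": [labels[n] for n in b.index]})
    return df.groupby("label")["betweenness"].agg(["mean", "median", "count"])


def assortativity_nominal(
    net: NetworkEdgeTable | nx.Graph, labels: Mapping[str, str]
) -> float:
    """Newman's nominal assortativity over the undirected edge set."""
    g = _as_simple_graph(net)
    if g.number_of_edges() == 0:
        raise DataError("assortativity needs at least one edge")
    missing = [n for n in g.nodes if n not in labels]
    if missing:
        raise DataError(f"unlabelled nodes: {sorted(missing)[:10]}")
    classes = sorted({labels[n] for n in g.nodes})
    if len(classes) < 2:
        return float("nan")  # single class: denominator 0, undefined
    index = {c: i for i, c in enumerate(classes)}
    e = np.zeros((len(classes), len(classes)))
    for u, v in g.edges:
        i, j = index[labels[u]], index[labels[v]]
        # each undirected edge contributes both endpoint orderings
        e[i, j] += 1.0
        e[j, i] += 1.0
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    denom = 1.0 - float(a @ b)
    if denom == 0.0:
        return float("nan")
    return (float(np.trace(e)) - float(a @ b)) / denom


@dataclasses.dataclass
class AssortativityResult:
    feature: str
    r: float
    null_mean: float
    null_sd: float
    z: float
    n_shuffles: int


def assortativity_ztest(
    net: NetworkEdgeTable | nx.Graph,
    labels: Mapping[str, str],
    n_shuffles: int = 100,
    seed: int = 0,
    feature: str = "feature",
) -> AssortativityResult:
    """z-score of the observed r against a label-shuffle null on fixed topology."""
    g = _as_simple_graph(net)
    r_obs = assortativity_nominal(g, labels)
    nodes = list(g.nodes)
    values = [labels[n] for n in nodes]
    rng = rng_for(seed, "assortativity", feature)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(nodes))
        shuffled = {nodes[i]: values[perm[i]] for i in range(len(nodes))}
        null[s] = assortativity_nominal(g, shuffled)
    null_mean = float(np.mean(null))
    null_sd = float(np.std(null, ddof=1))
    z = (r_obs - null_mean) / null_sd if null_sd > 0 else float("nan")
    return AssortativityResult(
        feature=feature, r=r_obs, null_mean=null_mean, null_sd=null_sd,
        z=float(z), n_shuffles=n_shuffles,
    )


def edge_clustering_coefficient(g: nx.Graph, u, v) -> float:
    """(triangles on the edge + 1) / min(deg u − 1, deg v − 1); 0 at degree-1 ends."""
    du, dv = g.degree(u), g.degree(v)
    if min(du, dv) <= 1:
        return 0.0
    triangles = len(set(g.neighbors(u)) & set(g.neighbors(v)))
    return (triangles + 1.0) / min(du - 1, dv - 1)


@dataclasses.dataclass
class ModulePartition:
    modules: list[set]
    unassigned: list

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]

    def membership(self) -> dict:
        out = {}
        for i, m in enumerate(self.modules):
            for n in m:
                out[n] = i
        return out


def ecc_communities(net: NetworkEdgeTable | nx.Graph, min_size: int = 5) -> ModulePartition:
    """ECC-ordered agglomerative community detection with module locking.

    Edges are visited in descending ECC (ties broken lexicographically
    on the sorted endpoint pair). The endpoint clusters are merged only
    while the smaller of the two is not yet a module, a cluster being a
    module once its internal edge count exceeds its external edge
    count. Deterministic; clusters below ``min_size`` are reported as
    unassigned.
    """
    g = _as_simple_graph(net)
    if g.number_of_nodes() == 0:
        raise DataError("community detection on an empty graph")
    ecc = {
        tuple(sorted((u, v))): edge_clustering_coefficient(g, u, v) for u, v in g.edges
    }
    order = sorted(ecc, key=lambda e: (-ecc[e], e))
    cluster_of = {n: i for i, n in enumerate(sorted(g.nodes))}
    members: dict[int, set] = {i: {n} for n, i in cluster_of.items()}
    internal = {i: 0 for i in members}
    degree = dict(g.degree)

    def external(c: int) -> int:
        return sum(degree[n] for n in members[c]) - 2 * internal[c]

    def is_module(c: int) -> bool:
        return internal[c] > external(c)

    for u, v in order:
        cu, cv = cluster_of[u], cluster_of[v]
        if cu == cv:
            internal[cu] += 1
            continue
        smaller, larger = (cu, cv) if len(members[cu]) <= len(members[cv]) else (cv, cu)
        if is_module(smaller):
            continue
        for n in members[smaller]:
            cluster_of[n] = larger
        members[larger] |= members[smaller]
        internal[larger] += internal[smaller] + 1
        del members[smaller], internal[smaller]

    modules, unassigned = [], []
    for c in sorted(members, key=lambda c: (-len(members[c]), sorted(members[c]))):
        if len(members[c]) >= min_size:
            modules.append(set(members[c]))
        else:
            unassigned.extend(sorted(members[c]))
    return ModulePartition(modules=modules, unassigned=sorted(unassigned))


def modularity_cross_check(net: NetworkEdgeTable | nx.Graph) -> list[set]:
    """Greedy modularity partition as an independent sanity check."""
    g = _as_simple_graph(net)
    return [set(c) for c in nx.algorithms.community.greedy_modularity_communities(g)]


def module_feature_table(
    partition: ModulePartition, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-module counts of each feature class plus the majority label.

    ``annotations`` is indexed by node with one column per feature.
    """
    rows = []
    for i, module in enumerate(partition.modules):
        nodes = sorted(module)
        rec: dict = {"module": i, "size": len(nodes)}
        for feature in annotations.columns:
            counts = annotations.loc[nodes, feature].value_counts()
            for cls, n in counts.items():
                rec[f"{feature}={cls}"] = int(n)
            rec[f"majority_{feature}"] = counts.idxmax()
        rows.append(rec)
    return pd.DataFrame(rows).fillna(0) if rows else pd.DataFrame()


def collapse_tags(tag_sets: Mapping[str, set], shared_label: str) -> dict[str, str]:
    """Single nominal label per node: the unique tag, or the shared category."""
    out = {}
    for node, tags in tag_sets.items():
        tags = set(tags)
        out[node] = next(iter(tags)) if len(tags) == 1 else shared_label
    return out


def dominant_context_labels(
    diff_table: pd.DataFrame, nodes: Sequence[str], field: str
) -> dict[str, str]:
    """Label each node by the ``field`` value (condition/patient) carrying
    the largest total |differential-activity score|.

    Unlike the collapsed tags of :func:`annotate_da_nodes`, these labels
    stay informative when a TF is active in several contexts, so nominal
    assortativity remains defined on densely activated networks.
    """
    weights = (
        diff_table.assign(_w=diff_table["score"].abs())
        .groupby(["tf", field])["_w"]
        .sum()
    )
    out = {}
    for node in nodes:
        sub = weights.loc[node] if node in weights.index.get_level_values(0) else None
        if sub is None or sub.sum() == 0:
            out[node] = "none"
        else:
            out[node] = str(sub.idxmax())
    return out


def annotate_da_nodes(da_set, nodes: Sequence[str]) -> pd.DataFrame:
    """Condition/patient/interval annotations of consensus nodes from DA tags."""
    cond = collapse_tags({n: da_set.conditions_of(n) for n in nodes}, "both")
    pat = collapse_tags({n: da_set.patients_of(n) for n in nodes}, "shared")
    time = collapse_tags(
        {n: {f"{a}-{b}" for a, b in da_set.intervals_of(n)} for n in nodes}, "multiple"
    )
    return pd.DataFrame({"condition": cond, "patient": pat, "interval": time}).loc[list(nodes)]
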