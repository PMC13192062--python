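"""Boolean implication network construction and clustering.

The Boolean implication network (BIN) has genes as nodes and significant
implication relationships as edges.  To collapse it into a clustered
network (CBIN), genes linked by *equivalence* edges are grouped: a minimum
spanning tree of the equivalence graph is computed (edge weight
1 - Jaccard similarity of the endpoints' neighborhoods), tree edges with
Jaccard < 0.5 — weakly embedded links likely due to noise — are removed,
and the surviving connected components become clusters.  Each cluster is
represented by its genes with the most within-cluster equivalence links;
the dominant relationship among representative pairs of two clusters, when
an overwhelming majority agrees, becomes a typed, color-coded edge of the
CBIN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from . import implication as impl
from .implication import Relationship
from .stepminer import StepMinerDiscretizer, DEFAULT_MARGIN

__all__ = [
    "Cluster",
    "EDGE_COLORS",
    "build_equivalence_graph",
    "edge_jaccard",
    "cluster_by_pruned_mst",
    "cbin",
    "size_distribution_diagnostic",
    "cbin_to_dict",
    "cbin_from_dict",
    "write_cbin_json",
    "read_cbin_json",
    "write_cbin_graphml",
    "BooleanImplicationNetwork",
]

DEFAULT_JACCARD = 0.5
DEFAULT_N_REPS = 3
DEFAULT_MAJORITY = 0.67

EDGE_COLORS = {
    Relationship.LOHI: "orange",
    Relationship.LOLO: "dark blue",
    Relationship.HIHI: "green",
    Relationship.HILO: "red",
    Relationship.EQUIVALENT: "light blue",
    Relationship.OPPOSITE: "black",
}
_SYMMETRIC = {Relationship.EQUIVALENT, Relationship.OPPOSITE}
# converse relationship when an edge is read D -> C instead of C -> D
_CONVERSE = {
    Relationship.EQUIVALENT: Relationship.EQUIVALENT,
    Relationship.OPPOSITE: Relationship.OPPOSITE,
    Relationship.LOLO: Relationship.HIHI,
    Relationship.HIHI: Relationship.LOLO,
    Relationship.LOHI: Relationship.LOHI,
    Relationship.HILO: Relationship.HILO,
}


@dataclass
class Cluster:
    """A connected component of the pruned equivalence forest."""

    id: str
    members: list = field(default_factory=list)
    representatives: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def build_equivalence_graph(edges: pd.DataFrame) -> nx.Graph:
    """Undirected graph of the EQUIVALENT edges of an implication edge list."""
    graph = nx.Graph()
    if len(edges) == 0:
        return graph
    eq = edges[edges["relationship"] == Relationship.EQUIVALENT]
    graph.add_edges_from(zip(eq["gene_a"], eq["gene_b"]))
    return graph


def edge_jaccard(graph: nx.Graph, u, v) -> float:
    """Jaccard similarity of the open neighborhoods of an edge's endpoints."""
    if not graph.has_edge(u, v):
        raise ValueError(f"edge ({u!r}, {v!r}) not in graph")
    nu = set(graph.neighbors(u))
    nv = set(graph.neighbors(v))
    union = nu | nv
    if not union:
        return 0.0
    return len(nu & nv) / len(union)


def _rank_members(graph: nx.Graph, members) -> list:
    """Members ordered by within-cluster equivalence degree, ties by id."""
    member_set = set(members)

    def degree(g):
        if g not in graph:
            return 0
        return sum(1 for nb in graph.neighbors(g) if nb in member_set)

    return sorted(members, key=lambda g: (-degree(g), str(g)))


def cluster_by_pruned_mst(
    graph: nx.Graph,
    jaccard_threshold: float = DEFAULT_JACCARD,
    all_genes=None,
    n_reps: int = DEFAULT_N_REPS,
) -> list[Cluster]:
    """Cluster genes via the Jaccard-pruned minimum spanning forest.

    Edge weight is ``1 - Jaccard`` (computed on the full equivalence
    graph), so the retained tree prefers well-embedded edges.  Tree edges
    with Jaccard strictly below the threshold are removed; components of
    what remains are clusters.  Genes in ``all_genes`` (if given) that
    carry no equivalence edge become singleton clusters.  Clusters are
    ordered by decreasing size, then by smallest member id.
    """
    forest = nx.Graph()
    if all_genes is not None:
        forest.add_nodes_from(all_genes)
    forest.add_nodes_from(graph.nodes)
    if graph.number_of_edges() > 0:
        jacc = {(u, v): edge_jaccard(graph, u, v) for u, v in graph.edges}
        weighted = nx.Graph()
        weighted.add_nodes_from(graph.nodes)
        weighted.add_weighted_edges_from(
            (u, v, 1.0 - j) for (u, v), j in jacc.items()
        )
        mst = nx.minimum_spanning_tree(weighted, weight="weight")
        for u, v in mst.edges:
            j = jacc.get((u, v), jacc.get((v, u)))
            if j >= jaccard_threshold:
                forest.add_edge(u, v)
    components = [sorted(c, key=str) for c in nx.connected_components(forest)]
    components.sort(key=lambda c: (-len(c), str(c[0])))
    clusters = []
    for idx, members in enumerate(components, start=1):
        ranked = _rank_members(graph, members)
        clusters.append(
            Cluster(
                id=f"C{idx}",
                members=members,
                representatives=ranked[:n_reps],
            )
        )
    return clusters


def cbin(
    clusters: list[Cluster],
    states: pd.DataFrame,
    s_thr: float = impl.DEFAULT_S_THR,
    p_thr: float = impl.DEFAULT_P_THR,
    n_reps: int = DEFAULT_N_REPS,
    majority: float = DEFAULT_MAJORITY,
    jaccard_threshold: float = DEFAULT_JACCARD,
) -> nx.DiGraph:
    """Clustered Boolean implication network.

    Nodes are clusters (with ``size``, ``members``, ``representatives``
    attributes); for each cluster pair all ``n_reps x n_reps``
    representative gene pairs are classified, and an edge of the dominant
    type is added when at least half the pairs yield a relationship and at
    least ``majority`` of those agree.  Edges carry the field's color code
    (orange low=>high, dark blue low=>low, green high=>high, red
    high=>low, light blue equivalent, black opposite).  Symmetric
    relationships are marked ``directed=False``.
    """
    if not clusters:
        raise ValueError("no clusters given")
    graph = nx.DiGraph(jaccard_threshold=jaccard_threshold)
    for c in clusters:
        graph.add_node(
            c.id, size=c.size, members=list(c.members),
            representatives=list(c.representatives),
        )
    state_arr = states.to_numpy()
    gene_row = {g: i for i, g in enumerate(states.index)}
    for a_idx, ca in enumerate(clusters):
        reps_a = [g for g in ca.representatives[:n_reps] if g in gene_row]
        for cb_ in clusters[a_idx + 1:]:
            reps_b = [g for g in cb_.representatives[:n_reps] if g in gene_row]
            calls = []
            for ga in reps_a:
                for gb in reps_b:
                    counts = impl.count_quadrants(
                        state_arr[gene_row[ga]], state_arr[gene_row[gb]]
                    )
                    calls.append(impl.classify(counts, s_thr, p_thr))
            n_pairs = len(calls)
            informative = [c for c in calls if c != Relationship.NONE]
            if n_pairs == 0 or len(informative) < 0.5 * n_pairs:
                continue
            kinds, counts_ = np.unique(informative, return_counts=True)
            top = int(np.argmax(counts_))
            if counts_[top] < majority * len(informative):
                continue
            rel = str(kinds[top])
            graph.add_edge(
                ca.id, cb_.id,
                relationship=rel,
                color=EDGE_COLORS[rel],
                directed=rel not in _SYMMETRIC,
            )
    return graph


def size_distribution_diagnostic(
    clusters: list[Cluster], include_singletons: bool = True
):
    """Least-squares fit of log(#clusters of size s) on log(s).

    A scale-free-like cluster size distribution gives an approximately
    linear log-log relationship.  Returns ``(slope, r_squared)``, or
    ``None`` when fewer than 3 distinct sizes exist (fit undefined).
    """
    sizes = [c.size for c in clusters if include_singletons or c.size > 1]
    distinct, counts = np.unique(sizes, return_counts=True)
    if len(distinct) < 3:
        return None
    fit = sps.linregress(np.log(distinct.astype(float)), np.log(counts.astype(float)))
    return float(fit.slope), float(fit.rvalue ** 2)


# ---------------------------------------------------------------------------
# serialization

def cbin_to_dict(graph: nx.DiGraph) -> dict:
    return {
        "jaccard_threshold": graph.graph.get("jaccard_threshold"),
        "nodes": [
            {
                "id": n,
                "size": d["size"],
                "members": list(d["members"]),
                "representatives": list(d["representatives"]),
            }
            for n, d in graph.nodes(data=True)
        ],
        "edges": [
            {
                "source": u,
                "target": v,
                "relationship": d["relationship"],
                "color": d["color"],
                "directed": bool(d["directed"]),
            }
            for u, v, d in graph.edges(data=True)
        ],
    }


def cbin_from_dict(payload: dict) -> nx.DiGraph:
    graph = nx.DiGraph(jaccard_threshold=payload.get("jaccard_threshold"))
    for node in payload["nodes"]:
        graph.add_node(
            node["id"], size=node["size"], members=node["members"],
            representatives=node["representatives"],
        )
    for e in payload["edges"]:
        graph.add_edge(
            e["source"], e["target"], relationship=e["relationship"],
            color=e["color"], directed=e["directed"],
        )
    return graph


def write_cbin_json(graph: nx.DiGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cbin_to_dict(graph), fh, indent=1)


def read_cbin_json(path) -> nx.DiGraph:
    with open(path, encoding="utf-8") as fh:
        return cbin_from_dict(json.load(fh))


def write_cbin_graphml(graph: nx.DiGraph, path) -> None:
    # GraphML attributes must be scalars; lists are comma-joined
    flat = nx.DiGraph(**{k: v for k, v in graph.graph.items() if v is not None})
    for n, d in graph.nodes(data=True):
        flat.add_node(
            n, size=d["size"], members=",".join(map(str, d["members"])),
            representatives=",".join(map(str, d["representatives"])),
        )
    for u, v, d in graph.edges(data=True):
        flat.add_edge(u, v, **d)
    nx.write_graphml(flat, path)


# ---------------------------------------------------------------------------
# estimator

class BooleanImplicationNetwork(BaseEstimator):
    """End-to-end Boolean implication network from an expression matrix.

    scikit-learn style: ``X`` is samples x genes.  ``fit`` discretizes
    every gene with StepMiner, drops genes without dynamic range, scans
    all remaining pairs for Boolean implication relationships, and builds
    the clustered network.

    Parameters
    ----------
    margin : float, default 0.5
        Intermediate-zone half width around each StepMiner threshold.
    s_thr, p_thr : float, defaults 3.0 and 0.1
        Sparsity thresholds of the BooleanNet statistics.
    min_frac : float, default 0.05
        Minimum fraction of samples in each of the LOW and HIGH states.
    jaccard_threshold : float, default 0.5
        Pruning threshold for minimum-spanning-tree edges.
    n_reps : int, default 3
        Representative genes sampled per cluster for inter-cluster calls.
    majority : float, default 0.67
        Fraction of informative representative pairs that must agree.

    Attributes
    ----------
    thresholds_ : pandas.Series of per-gene StepMiner thresholds.
    states_ : pandas.DataFrame, genes x samples ternary states (kept genes).
    kept_genes_ : pandas.Index of genes passing the dynamic-range filter.
    edges_ : pandas.DataFrame of significant pair relationships.
    equivalence_graph_ : networkx.Graph
    clusters_ : list of Cluster (a partition of kept_genes_).
    cbin_ : networkx.DiGraph, the clustered network.
    """

    def __init__(
        self,
        margin: float = DEFAULT_MARGIN,
        s_thr: float = impl.DEFAULT_S_THR,
        p_thr: float = impl.DEFAULT_P_THR,
        min_frac: float = impl.DEFAULT_MIN_FRAC,
        jaccard_threshold: float = DEFAULT_JACCARD,
        n_reps: int = DEFAULT_N_REPS,
        majority: float = DEFAULT_MAJORITY,
    ):
        self.margin = margin
        self.s_thr = s_thr
        self.p_thr = p_thr
        self.min_frac = min_frac
        self.jaccard_threshold = jaccard_threshold
        self.n_reps = n_reps
        self.majority = majority

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            genes = [str(c) for c in X.columns]
            samples = [str(i) for i in X.index]
        else:
            genes = samples = None
        X = check_array(X, dtype=float, ensure_min_samples=4)
        if genes is None:
            genes = [f"g{i}" for i in range(X.shape[1])]
            samples = [f"s{i}" for i in range(X.shape[0])]
        self.n_features_in_ = X.shape[1]
        self.gene_ids_ = list(genes)
        disc = StepMinerDiscretizer(margin=self.margin).fit(X)
        self.discretizer_ = disc
        self.thresholds_ = pd.Series(disc.thresholds_, index=genes, name="threshold")
        states = pd.DataFrame(disc.transform(X).T, index=genes, columns=samples)
        self.kept_genes_ = impl.dynamic_range_filter(states, self.min_frac)
        self.states_ = states.loc[self.kept_genes_]
        self.edges_ = impl.all_pairs(self.states_, self.s_thr, self.p_thr)
        self.equivalence_graph_ = build_equivalence_graph(self.edges_)
        self.clusters_ = cluster_by_pruned_mst(
            self.equivalence_graph_,
            jaccard_threshold=self.jaccard_threshold,
            all_genes=self.kept_genes_,
            n_reps=self.n_reps,
        )
        self.cbin_ = cbin(
            self.clusters_,
            self.states_,
            s_thr=self.s_thr,
            p_thr=self.p_thr,
            n_reps=self.n_reps,
            majority=self.majority,
            jaccard_threshold=self.jaccard_threshold,
        )
        return self

    def cluster_labels_(self) -> pd.Series:
        """Cluster id per kept gene (a partition of kept_genes_)."""
        check_is_fitted(self, "clusters_")
        labels = {}
        for c in self.clusters_:
            for g in c.members:
                labels[g] = c.id
        return pd.Series(labels, name="cluster")
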