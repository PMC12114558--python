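"""Co-occurrence networks, topology, modules, random-graph nulls, keystones.

Networks are built genus-by-genus from relative-abundance tables: after
filtering rare taxa (cumulative relative abundance below 0.5% of the table
total, or detected in fewer than 3 samples), an undirected edge connects two
genera when the magnitude of their Spearman correlation across samples
exceeds 0.6 with p < 0.01 (thresholds configurable; the sign of r is kept as
an edge attribute). Topology is summarised by node/edge counts, the positive
edge fraction, average degree, mean local clustering, average shortest path
length over the largest connected component, and Louvain modularity.

Erdős–Rényi G(n, m) ensembles with the real network's node and edge counts
provide the null for the small-world/modularity assessment. Average degree is
2m/n in both real and null networks by construction and is therefore
reported as non-informative in the comparison. Keystone taxa are ranked by
exact unweighted betweenness centrality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import child_seed
from .community import MODE_RELATIVE, AbundanceTable, parse_lineage


@dataclass(frozen=True)
class CooccurrenceNetwork:
    """Undirected signed co-occurrence graph with provenance."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float
    samples: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "r": d["r"], "p": d["p"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"])


@dataclass(frozen=True)
class NetworkTopology:
    n_nodes: int
    n_edges: int
    positive_edge_fraction: float  # percent
    average_degree: float
    clustering_coefficient: float
    average_path_length: float
    modularity: float
    n_modules: int
    n_major_modules: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class NullEnsemble:
    n_nodes: int
    n_edges: int
    replicates: pd.DataFrame  # one row of topology metrics per replicate
    seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def summary(self) -> pd.DataFrame:
        return self.replicates.agg(["mean", "std"]).T


def filter_taxa(
    table: AbundanceTable,
    min_cumulative_fraction: float = 0.005,
    min_prevalence: int = 3,
) -> AbundanceTable:
    """Drop rare genera before network construction.

    Keeps genera whose summed relative abundance across samples is at least
    ``min_cumulative_fraction`` of the table total AND that are nonzero in at
    least ``min_prevalence`` samples.
    """
    if table.mode != MODE_RELATIVE:
        raise ValueError("filter_taxa expects a relative-abundance table")
    data = table.data
    total = float(data.to_numpy().sum())
    cum_ok = data.sum(axis=1) / total >= min_cumulative_fraction
    prev_ok = (data > 0).sum(axis=1) >= min_prevalence
    keep = cum_ok & prev_ok
    removed_abundance = int((~cum_ok).sum())
    removed_prevalence = int((~prev_ok).sum())
    if not keep.any():
        raise ValueError(
            "no taxa survive filtering "
            f"(abundance rule removed {removed_abundance}, prevalence rule "
            f"removed {removed_prevalence}); review thresholds"
        )
    return AbundanceTable(
        data=data.loc[keep],
        taxonomy=table.taxonomy.loc[keep],
        mode=table.mode,
        subset=True,
    )


def spearman_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman r and two-sided t-approximation p for row variables.

    Mid-rank ties then Pearson on ranks; p from t = r·sqrt((n−2)/(1−r²))
    with n−2 df.
    """
    n = X.shape[1]
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(ranks)
    r = np.clip(r, -1.0, 1.0)
    rr = np.clip(np.abs(r), 0, 1 - 1e-15)
    t = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * stats.t.sf(t, df=n - 2)
    np.fill_diagonal(p, 0.0)
    return r, p


def build_network(
    table: AbundanceTable,
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
    top_n_by_abundance: int | None = None,
) -> CooccurrenceNetwork:
    """Build the co-occurrence graph from a (filtered) abundance table.

    An edge joins two taxa iff |Spearman r| > r_threshold and p < p_threshold
    (both strict). Constant rows cannot be ranked meaningfully and are
    excluded with a warning. ``top_n_by_abundance`` optionally pre-selects the
    most abundant taxa before correlation (disabled by default).
    """
    data = table.data
    if data.shape[1] < 4:
        raise ValueError("need >= 4 samples to build a network")
    if data.shape[0] < 2:
        raise ValueError("need >= 2 taxa")
    if top_n_by_abundance is not None and top_n_by_abundance < data.shape[0]:
        keep = data.mean(axis=1).nlargest(top_n_by_abundance).index
        data = data.loc[keep]
    X = data.to_numpy(dtype=float)
    const = np.ptp(X, axis=1) == 0
    if const.any():
        warnings.warn(
            f"excluding constant taxa from pairing: {list(data.index[const])}",
            stacklevel=2,
        )
        data = data.loc[~const]
        X = X[~const]
    taxa = list(data.index)
    r, p = spearman_matrix(X)
    mean_rel = data.mean(axis=1)

    g = nx.Graph()
    lineages = table.taxonomy.reindex(data.index).fillna("")
    for t in taxa:
        lin = lineages.loc[t]
        g.add_node(
            t,
            lineage=lin,
            genus=parse_lineage(lin)["genus"],
            mean_abundance=float(mean_rel.loc[t]),
        )
    n = len(taxa)
    iu, ju = np.triu_indices(n, k=1)
    hits = (np.abs(r[iu, ju]) > r_threshold) & (p[iu, ju] < p_threshold)
    for i, j in zip(iu[hits], ju[hits]):
        rij = float(r[i, j])
        g.add_edge(
            taxa[i],
            taxa[j],
            r=rij,
            p=float(p[i, j]),
            sign="positive" if rij > 0 else "negative",
        )
    return CooccurrenceNetwork(
        graph=g,
        r_threshold=r_threshold,
        p_threshold=p_threshold,
        samples=tuple(map(str, table.samples)),
    )


def detect_modules(
    graph: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[dict, float]:
    """Louvain modules on the unsigned, unweighted graph.

    Greedy modularity optimisation, best of ``n_restarts`` seeded runs by
    modularity Q = Σ(e_ii/m − (d_i/2m)²). Returns (node → module id, Q).
    """
    if graph.number_of_edges() == 0:
        return {n: 0 for n in graph.nodes}, 0.0
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
             for s in child_seed(seed, "modules").spawn(n_restarts)]
    best_q, best_parts = -np.inf, None
    for s in seeds:
        parts = nx.community.louvain_communities(
            graph, weight=None, resolution=resolution, seed=s
        )
        q = nx.community.modularity(graph, parts, weight=None,
                                    resolution=resolution)
        if q > best_q:
            best_q, best_parts = q, parts
    assignment = {}
    for i, com in enumerate(best_parts):
        for node in com:
            assignment[node] = i
    return assignment, float(best_q)


def network_topology(
    net: CooccurrenceNetwork | nx.Graph,
    seed: int = 0,
    major_module_fraction: float = 0.05,
) -> NetworkTopology:
    """Topology metrics of a co-occurrence (or plain) graph.

    Path length is averaged over the largest connected component; clustering
    is the mean local coefficient (isolated/degree-1 nodes count 0). An
    edgeless graph reports NaN for both.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n < 1:
        raise ValueError("empty graph")
    signs = [d.get("sign", "positive") for _, _, d in g.edges(data=True)]
    pos_frac = 100.0 * sum(s == "positive" for s in signs) / m if m else np.nan
    if m:
        clustering = float(nx.average_clustering(g))
        lcc = g.subgraph(max(nx.connected_components(g), key=len))
        apl = (
            float(nx.average_shortest_path_length(lcc))
            if lcc.number_of_nodes() > 1
            else np.nan
        )
    else:
        clustering, apl = np.nan, np.nan
    assignment, q = detect_modules(g, seed=seed)
    sizes = pd.Series(assignment).value_counts() if assignment else pd.Series(dtype=int)
    n_major = int((sizes >= major_module_fraction * n).sum())
    return NetworkTopology(
        n_nodes=n,
        n_edges=m,
        positive_edge_fraction=float(pos_frac),
        average_degree=2.0 * m / n,
        clustering_coefficient=clustering,
        average_path_length=apl,
        modularity=q,
        n_modules=int(sizes.size),
        n_major_modules=n_major,
    )


def er_null_ensemble(
    n_nodes: int,
    n_edges: int,
    n_replicates: int = 100,
    seed: int = 0,
) -> NullEnsemble:
    """Uniform G(n, m) ensemble at the real network's size.

    Every replicate is a simple graph with exactly ``n_edges`` edges; its
    topology is measured with the same code path as the real network.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"{n_edges} edges infeasible for {n_nodes} nodes (max {max_edges})"
        )
    streams = child_seed(seed, "null").spawn(n_replicates)
    rows = []
    for ss in streams:
        s = int(ss.generate_state(1)[0] % (2**31 - 1))
        g = nx.gnm_random_graph(n_nodes, n_edges, seed=s)
        rows.append(network_topology(g, seed=s).to_dict())
    return NullEnsemble(
        n_nodes=n_nodes,
        n_edges=n_edges,
        replicates=pd.DataFrame(rows),
        seed=seed,
    )


_SW_METRICS = ("modularity", "clustering_coefficient", "average_path_length")


def small_world_assessment(
    real: NetworkTopology,
    null: NullEnsemble,
    modularity_floor: float = 0.4,
) -> dict:
    """Compare a real network against its equal-(n, m) random ensemble.

    Per metric: whether the real value exceeds the null mean, with a z-score.
    Average degree equals 2m/n in both by construction and is reported as
    non-informative. The overall verdict is "small-world + modular" when
    clustering and modularity both exceed the null and Q > ``modularity_floor``.
    """
    if (real.n_nodes, real.n_edges) != (null.n_nodes, null.n_edges):
        raise ValueError("null ensemble was not generated at the real (n, m)")
    metrics = {}
    for name in _SW_METRICS:
        value = getattr(real, name)
        mu = float(null.replicates[name].mean())
        sd = float(null.replicates[name].std(ddof=1))
        z = (value - mu) / sd if sd > 0 else np.nan
        metrics[name] = {
            "real": value,
            "null_mean": mu,
            "null_sd": sd,
            "z": float(z) if np.isfinite(z) else np.nan,
            "exceeds_null": bool(value > mu) if np.isfinite(value) else False,
        }
    metrics["average_degree"] = {
        "real": real.average_degree,
        "note": "identical by construction (2m/n is fixed by the null design)",
    }
    verdict = (
        metrics["clustering_coefficient"]["exceeds_null"]
        and metrics["modularity"]["exceeds_null"]
        and real.modularity > modularity_floor
    )
    return {"metrics": metrics, "small_world_and_modular": bool(verdict)}


def keystone_taxa(
    net: CooccurrenceNetwork,
    top_k: int = 10,
    exclude_unclassified: bool = False,
) -> pd.DataFrame:
    """Rank taxa by exact unweighted betweenness centrality.

    ``exclude_unclassified`` drops taxa with no genus-level assignment from
    the ranking (the usual convention when naming keystone genera).
    """
    g = net.graph
    comps = list(nx.connected_components(g))
    if not comps or max(len(c) for c in comps) < 3:
        raise ValueError("no connected component with >= 3 nodes")
    bc = nx.betweenness_centrality(g, normalized=True)
    rows = [
        {
            "taxon_id": node,
            "genus": g.nodes[node].get("genus", ""),
            "betweenness": val,
            "degree": g.degree(node),
        }
        for node, val in bc.items()
    ]
    df = pd.DataFrame(rows).sort_values(
        ["betweenness", "degree", "taxon_id"], ascending=[False, False, True]
    )
    if exclude_unclassified:
        df = df[df["genus"] != ""]
    if top_k > len(df):
        warnings.warn(
            f"top_k={top_k} exceeds ranked node count {len(df)}; truncating",
            stacklevel=2,
        )
        top_k = len(df)
    return df.head(top_k).reset_index(drop=True)


def export_network(
    net: CooccurrenceNetwork,
    basename,
    modules: dict | None = None,
    betweenness: dict | None = None,
) -> None:
    """Write GraphML + GEXF (Gephi-compatible) and an edge-list CSV."""
    g = net.graph.copy()
    for node in g.nodes:
        if modules is not None:
            g.nodes[node]["module"] = int(modules.get(node, -1))
        if betweenness is not None:
            g.nodes[node]["betweenness"] = float(betweenness.get(node, 0.0))
    basename = str(basename)
    nx.write_graphml(g, basename + ".graphml")
    nx.write_gexf(g, basename + ".gexf")
    net.edge_table().to_csv(basename + "_edges.csv", index=False)


def topology_report(topo: NetworkTopology, path) -> None:
    with open(path, "w") as fh:
        json.dump(topo.to_dict(), fh, indent=2, default=float)
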