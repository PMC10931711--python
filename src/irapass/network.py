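"""APA-events-to-APA-factors (ATF) network and master-factor ranking.

The network mixes two kinds of evidence: signed Spearman correlation edges
between an APA factor's expression and a differential event's PDUI, and
protein-protein interaction edges restricted to the factor / event-gene
universe.  Nodes are ranked by twelve topology measures (the cytoHubba
suite: Betweenness, BottleNeck, Closeness, ClusteringCoefficient, Degree,
DMNC, EcCentricity, EPC, MCC, MNC, Radiality, Stress) and aggregated into
master APA factors by Borda count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from irapass.io import ExpressionTable, InteractionTable, PduiTable, ValidationError
from irapass.diff_apa import bh_fdr

__all__ = [
    "AtfNetwork",
    "CentralityRankings",
    "CENTRALITY_ALGORITHMS",
    "factor_event_correlation",
    "build_atf_network",
    "centrality_suite",
    "master_factors",
    "immune_correlation",
]

logger = logging.getLogger("irapass")

CENTRALITY_ALGORITHMS = (
    "Betweenness", "BottleNeck", "Closeness", "ClusteringCoefficient",
    "Degree", "DMNC", "EcCentricity", "EPC", "MCC", "MNC", "Radiality",
    "Stress",
)

DMNC_EPSILON = 1.7
MCC_NODE_BOUND = 2000


@dataclass
class AtfNetwork:
    """Mixed correlation/PPI graph over factors and event parental genes."""

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def factor_nodes(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d.get("kind") == "factor")


@dataclass
class CentralityRankings:
    """Per-algorithm node scores and 1-based ranks (1 = most central)."""

    scores: pd.DataFrame   # nodes x algorithms
    ranks: pd.DataFrame    # nodes x algorithms


# ---------------------------------------------------------------------------
# Correlation edges
# ---------------------------------------------------------------------------


def factor_event_correlation(expr: ExpressionTable, pdui: PduiTable,
                             factors: list[str],
                             p_threshold: float = 0.05,
                             rho_threshold: float = 0.3,
                             min_samples: int = 5) -> pd.DataFrame:
    """Spearman correlation of each factor's expression with each event's PDUI.

    Pairwise-complete over shared samples; an edge is kept iff
    p < ``p_threshold`` and |rho| >= ``rho_threshold``.  Returns columns
    factor, event_id, rho, p, n.
    """
    shared = [s for s in expr.sample_ids if s in set(pdui.sample_ids)]
    if len(shared) < min_samples:
        raise ValidationError(f"need >= {min_samples} shared samples, got {len(shared)}")
    factors = [f for f in factors if f in expr.data.index]
    fmat = expr.data.loc[factors, shared].to_numpy()
    rows = []
    for ev, prow in pdui.data[shared].iterrows():
        a = prow.to_numpy()
        ok = ~np.isnan(a)
        if ok.sum() < min_samples:
            continue
        a_rank = stats.rankdata(a[ok])
        f_rank = np.apply_along_axis(stats.rankdata, 1, fmat[:, ok])
        a_c = a_rank - a_rank.mean()
        f_c = f_rank - f_rank.mean(axis=1, keepdims=True)
        denom = np.sqrt((f_c**2).sum(axis=1) * (a_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (f_c @ a_c) / denom
        n = int(ok.sum())
        # t-approximation for the Spearman p-value (scipy's default)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        keep = (~np.isnan(rho)) & (p < p_threshold) & (np.abs(rho) >= rho_threshold)
        for fi in np.where(keep)[0]:
            rows.append((factors[fi], str(ev), float(rho[fi]), float(p[fi]), n))
    out = pd.DataFrame(rows, columns=["factor", "event_id", "rho", "p", "n"])
    logger.info("factor_event_correlation: %d edges kept", len(out))
    return out


def build_atf_network(correlation_edges: pd.DataFrame, ppi: InteractionTable,
                      factors: list[str], event_directions: pd.Series) -> AtfNetwork:
    """Union of correlation and PPI evidence.

    ``event_directions`` maps event-id strings to shortened/lengthened.
    Event nodes are keyed by parental gene symbol.  PPI edges are kept only
    when both endpoints are factors or event parental genes; parallel
    correlation + PPI evidence merges into one edge carrying both
    attributes.
    """
    g = nx.Graph()
    factor_set = set(factors)
    event_genes: dict[str, str] = {}
    for ev_str, direction in event_directions.items():
        gene = str(ev_str).split("|")[0]
        event_genes[gene] = str(direction)
    for f in sorted(factor_set):
        g.add_node(f, kind="factor")
    for gene, direction in sorted(event_genes.items()):
        if gene not in g:
            g.add_node(gene, kind="event_gene", direction=direction)
    for _, row in correlation_edges.iterrows():
        gene = str(row["event_id"]).split("|")[0]
        if row["factor"] == gene:
            continue
        g.add_edge(row["factor"], gene, rho=float(row["rho"]), p=float(row["p"]),
                   kinds=_merge_kind(g, row["factor"], gene, "correlation"))
    allowed = factor_set | set(event_genes)
    for a, b, s in ppi.edges.itertuples(index=False):
        if a in allowed and b in allowed and a != b:
            g.add_edge(a, b, combined_score=int(s), kinds=_merge_kind(g, a, b, "ppi"))
    logger.info("ATF network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return AtfNetwork(graph=g)


def _merge_kind(g: nx.Graph, a, b, kind: str) -> tuple[str, ...]:
    if g.has_edge(a, b):
        kinds = set(g.edges[a, b].get("kinds", ())) | {kind}
        return tuple(sorted(kinds))
    return (kind,)


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------


def _bfs_tree_subtree_sizes(g: nx.Graph, root, order: dict) -> dict:
    """Deterministic BFS shortest-path tree; returns subtree size per node."""
    parent = {root: None}
    depth = {root: 0}
    queue = deque([root])
    children: dict = {root: []}
    while queue:
        u = queue.popleft()
        for v in sorted(g.neighbors(u), key=order.get):
            if v not in depth:
                depth[v] = depth[u] + 1
                parent[v] = u
                children[v] = []
                children[u].append(v)
                queue.append(v)
    size = {v: 1 for v in depth}
    for v in sorted(depth, key=depth.get, reverse=True):
        if parent[v] is not None:
            size[parent[v]] += size[v]
    return size


def _stress(g: nx.Graph, nodes: list) -> dict:
    """Stress centrality: number of shortest paths passing through a node."""
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1.0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in g.neighbors(u):
                if v not in d:
                    d[v] = d[u] + 1
                    sig[v] = 0.0
                    queue.append(v)
                if d[v] == d[u] + 1:
                    sig[v] += sig[u]
        dist[s] = d
        sigma[s] = sig
    stress = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            d_st = dist[s].get(t)
            if d_st is None:
                continue
            for v in nodes:
                if v == s or v == t:
                    continue
                d_sv = dist[s].get(v)
                if d_sv is None or d_sv >= d_st:
                    continue
                if d_sv + dist[t].get(v, np.inf) == d_st:
                    stress[v] += sigma[s][v] * sigma[t][v]
    return stress


def centrality_suite(network: AtfNetwork, seed: int = 0,
                     epc_samples: int = 1000, epc_retention: float = 0.5,
                     mcc_node_bound: int = MCC_NODE_BOUND) -> CentralityRankings:
    """All twelve topology scores, computed on the largest component.

    Nodes outside the largest connected component receive score 0 (NaN-safe
    floor) and rank after every analysed node.  EPC is Monte-Carlo
    (seeded); everything else is exact.
    """
    g_full = network.graph
    if g_full.number_of_nodes() == 0:
        raise ValidationError("empty network")
    comps = sorted(nx.connected_components(g_full), key=lambda c: (-len(c), sorted(c)[0]))
    lcc = sorted(comps[0])
    g = g_full.subgraph(lcc).copy()
    if g.number_of_nodes() > mcc_node_bound:
        raise ValidationError(
            f"component has {g.number_of_nodes()} nodes > bound {mcc_node_bound}; "
            "exact clique enumeration (MCC) is infeasible — raise the bound or "
            "exclude MCC"
        )
    nodes = lcc
    order = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    scores = pd.DataFrame(0.0, index=sorted(g_full.nodes), columns=list(CENTRALITY_ALGORITHMS))

    deg = dict(g.degree())
    scores.loc[nodes, "Degree"] = [deg[v] for v in nodes]
    btw = nx.betweenness_centrality(g, normalized=False)
    scores.loc[nodes, "Betweenness"] = [btw[v] for v in nodes]
    harm = nx.harmonic_centrality(g)
    scores.loc[nodes, "Closeness"] = [harm[v] for v in nodes]
    clus = nx.clustering(g)
    scores.loc[nodes, "ClusteringCoefficient"] = [clus[v] for v in nodes]

    stress = _stress(g, nodes)
    scores.loc[nodes, "Stress"] = [stress[v] for v in nodes]

    ecc = nx.eccentricity(g)
    scores.loc[nodes, "EcCentricity"] = [1.0 / ecc[v] if ecc[v] > 0 else 1.0 for v in nodes]

    diam = max(ecc.values())
    spl = dict(nx.all_pairs_shortest_path_length(g))
    if n > 1:
        rad = {v: sum(diam + 1 - d for u, d in spl[v].items() if u != v) / (n - 1)
               for v in nodes}
    else:
        rad = {v: 0.0 for v in nodes}
    scores.loc[nodes, "Radiality"] = [rad[v] for v in nodes]

    # MNC / DMNC on the open neighborhood subgraph
    for v in nodes:
        nbrs = list(g.neighbors(v))
        sub = g.subgraph(nbrs)
        if sub.number_of_nodes() == 0:
            continue
        comp = max(nx.connected_components(sub), key=lambda c: (len(c), -order[sorted(c)[0]]))
        comp_g = sub.subgraph(comp)
        nv, ne = comp_g.number_of_nodes(), comp_g.number_of_edges()
        scores.loc[v, "MNC"] = nv
        if nv >= 2:
            scores.loc[v, "DMNC"] = ne / (nv ** DMNC_EPSILON)

    # MCC: sum over maximal cliques containing v of (|C|-1)!
    mcc = {v: 0.0 for v in nodes}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    scores.loc[nodes, "MCC"] = [mcc[v] for v in nodes]

    # BottleNeck: v scores once per shortest-path tree in which its subtree
    # holds at least a quarter of the nodes
    bn = {v: 0.0 for v in nodes}
    for root in nodes:
        sizes = _bfs_tree_subtree_sizes(g, root, order)
        for v, sz in sizes.items():
            if v != root and sz >= n / 4:
                bn[v] += 1
    scores.loc[nodes, "BottleNeck"] = [bn[v] for v in nodes]

    # EPC: Monte-Carlo edge percolation; score = expected number of nodes
    # still connected to v when each edge survives with prob. epc_retention
    rng = np.random.default_rng(seed)
    edges = list(g.edges())
    epc = np.zeros(n)
    node_pos = {v: i for i, v in enumerate(nodes)}
    for _ in range(epc_samples):
        keep = rng.random(len(edges)) < epc_retention
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(h):
            sz = len(comp)
            for v in comp:
                epc[node_pos[v]] += sz - 1
    epc /= epc_samples
    scores.loc[nodes, "EPC"] = epc

    ranks = scores.rank(ascending=False, method="min").astype(int)
    return CentralityRankings(scores=scores, ranks=ranks)


def master_factors(rankings: CentralityRankings, factor_nodes: list[str],
                   k: int = 10, aggregation: str = "borda") -> pd.DataFrame:
    """Aggregate the twelve rankings into a master-factor list.

    Borda: sum of per-algorithm ranks over factor nodes (smaller = better);
    ``intersection-topN`` counts how many algorithms place the factor in
    their top N=k.  Ties break by Degree, then lexicographically.
    """
    present = [f for f in factor_nodes if f in rankings.ranks.index]
    if not present:
        raise ValidationError("no factor nodes present in rankings")
    sub = rankings.ranks.loc[present]
    if aggregation == "borda":
        agg = sub.sum(axis=1).rename("borda_score")
        ascending = True
    elif aggregation == "intersection-topN":
        agg = (sub <= k).sum(axis=1).rename("top_n_count")
        ascending = False
    else:
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    deg = rankings.scores.loc[present, "Degree"]
    out = pd.DataFrame({agg.name: agg, "degree": deg})
    # stable three-key sort: lexicographic id, then Degree desc, then aggregate
    out = out.reindex(sorted(out.index))
    out = out.sort_values("degree", ascending=False, kind="mergesort")
    out = out.sort_values(agg.name, ascending=ascending, kind="mergesort")
    out = out.join(sub)
    if k > len(out):
        logger.warning("master_factors: k=%d > %d factor nodes; returning all", k, len(out))
        k = len(out)
    out["overall_rank"] = range(1, len(out) + 1)
    return out.head(k)


def immune_correlation(factor_expr: pd.DataFrame, score_vectors: pd.DataFrame,
                       groups: pd.Series, min_samples: int = 5) -> dict[str, pd.DataFrame]:
    """Spearman rho of each factor with each immune score, per group.

    ``score_vectors`` holds externally computed per-sample immune scores
    (ImmuneScore, ESTIMATEscore, TIDEscore, IPScore, ...).  Returns, per
    group, a long table (factor, score, rho, p, fdr_q); BH is applied
    across the whole matrix within each group.
    """
    out = {}
    groups = groups.dropna().astype(str)
    for grp in sorted(groups.unique()):
        samples = [s for s in groups.index[groups == grp]
                   if s in factor_expr.columns and s in score_vectors.index]
        if len(samples) < min_samples:
            logger.warning("immune_correlation: group %s has <%d samples, skipped",
                           grp, min_samples)
            continue
        rows = []
        for f in factor_expr.index:
            for sc in score_vectors.columns:
                rho, p = stats.spearmanr(factor_expr.loc[f, samples],
                                         score_vectors.loc[samples, sc])
                rows.append((f, sc, rho, p))
        df = pd.DataFrame(rows, columns=["factor", "score", "rho", "p"])
        df["fdr_q"] = bh_fdr(df["p"].clip(lower=1e-300)).to_numpy()
        out[grp] = df
    return out
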