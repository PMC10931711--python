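"""Feature-based module extraction from a PPI network.

The parental genes of the scoring-system features seed a personalized
PageRank (damping 0.85, teleport mass spread uniformly over the seeds)
on the largest connected component of the score-filtered PPI network;
the top 200 genes by impact score form the feature-based module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from irapass.io import InteractionTable, ValidationError

__all__ = [
    "PageRankConfig",
    "largest_component",
    "personalized_pagerank",
    "top_module",
    "extract_feature_module",
]

logger = logging.getLogger("irapass")


@dataclass
class PageRankConfig:
    damping: float = 0.85
    tolerance: float = 1e-10
    max_iterations: int = 1000
    top_k: int = 200
    seeds: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0 < self.damping < 1):
            raise ValidationError("damping must be in (0, 1)")
        if self.top_k < 1:
            raise ValidationError("top_k must be >= 1")
        self.seeds = frozenset(str(s) for s in self.seeds)


def largest_component(ppi: InteractionTable | nx.Graph) -> nx.Graph:
    """The connected component with the most nodes.

    Size ties break deterministically in favour of the component holding
    the lexicographically smallest node id.
    """
    g = ppi.to_graph() if isinstance(ppi, InteractionTable) else ppi
    if g.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    return g.subgraph(comps[0]).copy()


def personalized_pagerank(graph: nx.Graph, config: PageRankConfig) -> pd.Series:
    """Impact scores by power iteration with teleport to the seed set.

    x <- d * P x + (1 - d) * s, with P the column-stochastic transition
    matrix of the (undirected) graph and s uniform over the seeds present
    in the graph.  Converged when the L1 change drops below ``tolerance``;
    scores are a probability distribution (sum to 1).
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValidationError("empty graph")
    pos = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    seeds_in = sorted(config.seeds & set(nodes))
    dropped = sorted(config.seeds - set(nodes))
    if dropped:
        logger.warning("personalized_pagerank: %d seed(s) outside the component "
                       "dropped: %s", len(dropped), dropped[:10])
    if not seeds_in:
        raise ValidationError("no seed gene lies in the component")
    s = np.zeros(n)
    s[[pos[v] for v in seeds_in]] = 1.0 / len(seeds_in)

    deg = np.array([graph.degree(v) for v in nodes], dtype=float)
    dangling = deg == 0
    rows, cols, vals = [], [], []
    for a, b in graph.edges():
        ia, ib = pos[a], pos[b]
        rows.append(ia); cols.append(ib); vals.append(1.0 / deg[ib])
        rows.append(ib); cols.append(ia); vals.append(1.0 / deg[ia])
    from scipy.sparse import csr_matrix

    p_mat = csr_matrix((vals, (rows, cols)), shape=(n, n))

    d = config.damping
    x = s.copy()
    for _ in range(config.max_iterations):
        dangling_mass = x[dangling].sum()
        x_new = d * (p_mat @ x + dangling_mass * s) + (1 - d) * s
        if np.abs(x_new - x).sum() < config.tolerance:
            x = x_new
            break
        x = x_new
    else:
        residual = float(np.abs(d * (p_mat @ x + x[dangling].sum() * s)
                                + (1 - d) * s - x).sum())
        raise ValidationError(
            f"PageRank did not converge in {config.max_iterations} iterations "
            f"(L1 residual {residual:.2e})"
        )
    x = x / x.sum()
    return pd.Series(x, index=nodes, name="impact_score")


def top_module(scores: pd.Series, top_k: int = 200) -> pd.DataFrame:
    """Top-k genes by impact score; ties break by node id."""
    if top_k > len(scores):
        logger.warning("top_module: top_k=%d > %d scored nodes; returning all",
                       top_k, len(scores))
        top_k = len(scores)
    ordered = scores.sort_index(kind="mergesort").sort_values(
        ascending=False, kind="mergesort")
    out = ordered.head(top_k).to_frame()
    out["rank"] = range(1, len(out) + 1)
    return out


def extract_feature_module(ppi: InteractionTable, seed_genes,
                           config: PageRankConfig | None = None) -> pd.DataFrame:
    """Full operation: largest component -> personalized PageRank -> top-k."""
    cfg = config or PageRankConfig()
    cfg = PageRankConfig(damping=cfg.damping, tolerance=cfg.tolerance,
                         max_iterations=cfg.max_iterations, top_k=cfg.top_k,
                         seeds=frozenset(seed_genes))
    component = largest_component(ppi)
    scores = personalized_pagerank(component, cfg)
    module = top_module(scores, cfg.top_k)
    module["is_seed"] = [g in cfg.seeds for g in module.index]
    return module
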