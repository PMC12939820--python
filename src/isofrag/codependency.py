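"""Weighted co-dependency gene graphs and betweenness centrality.

Genes whose CRISPR knockout fitness effects correlate across cell lines
are "co-dependent"; an undirected graph over a gene set connects two genes
when either appears in the other's top-k co-dependency list, weighted by
the Pearson correlation r of their effect profiles.  Correlations are
turned into shortest-path penalties 1 - r (non-negative because only
positive-r edges are admitted), all-pairs shortest paths are computed with
Floyd-Warshall while counting path multiplicities under a small length
tolerance, and betweenness centrality identifies hub genes after min-max
normalisation within a connected component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PATH_TOL = 1e-9


@dataclass
class CodepGraph:
    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)  # (u,v) u<v -> r

    def __post_init__(self) -> None:
        for (u, v), r in self.edges.items():
            if u == v:
                raise ValueError(f"self-edge on {u}")
            if 1.0 - r < 0:
                raise ValueError(f"edge ({u}, {v}) has negative penalty (r={r})")

    def penalty(self, u: str, v: str) -> float:
        key = (u, v) if u < v else (v, u)
        return 1.0 - self.edges[key]

    def neighbors(self, u: str) -> list[str]:
        out = []
        for a, b in self.edges:
            if a == u:
                out.append(b)
            elif b == u:
                out.append(a)
        return out

    def degree_zero_nodes(self) -> list[str]:
        touched = {n for e in self.edges for n in e}
        return [n for n in self.nodes if n not in touched]

    def penalty_matrix(self) -> np.ndarray:
        idx = {n: i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        m = np.full((n, n), np.inf)
        np.fill_diagonal(m, 0.0)
        for (u, v), r in self.edges.items():
            m[idx[u], idx[v]] = m[idx[v], idx[u]] = 1.0 - r
        return m

    def components(self) -> list[list[str]]:
        seen: set[str] = set()
        comps: list[list[str]] = []
        adj: dict[str, list[str]] = {n: [] for n in self.nodes}
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        for start in self.nodes:
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                u = stack.pop()
                comp.append(u)
                for w in adj[u]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            comps.append(sorted(comp))
        return comps

    def component_of(self, gene: str) -> list[str]:
        for comp in self.components():
            if gene in comp:
                return comp
        raise KeyError(gene)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"u": u, "v": v, "r": r, "penalty": 1.0 - r}
            for (u, v), r in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["u", "v", "r", "penalty"])


@dataclass
class CentralityResult:
    nodes: list[str]
    raw: dict[str, float]
    normalized: dict[str, float]
    degenerate: bool = False  # component too small or all scores equal

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.normalized.items(), key=lambda kv: (-kv[1], kv[0]))


def pairwise_correlations(
    effect_matrix: pd.DataFrame, min_pairs: int = 10
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between gene rows."""
    return effect_matrix.T.corr(method="pearson", min_periods=min_pairs)


def derive_top_lists(
    corr: pd.DataFrame, genes: Sequence[str], top_k: int = 100
) -> dict[str, list[str]]:
    """Rank each gene's strongest co-dependencies from a correlation matrix."""
    out: dict[str, list[str]] = {}
    for g in genes:
        ranked = corr.loc[g].drop(index=g).dropna().sort_values(ascending=False)
        out[g] = list(ranked.index[:top_k])
    return out


def build_codependency_graph(
    effect_matrix: pd.DataFrame,
    gene_set: Optional[Sequence[str]] = None,
    top_lists: Optional[Mapping[str, Sequence[str]]] = None,
    top_k: int = 100,
    min_pairs: int = 10,
    admit_nonpositive: bool = False,
) -> CodepGraph:
    """Build the co-dependency graph over ``gene_set``.

    An edge (u, v) exists iff u is in v's top-k co-dependency list or vice
    versa, with weight r = Pearson correlation of the two genes' effect
    vectors (pairwise-complete over cell lines).  Edges with r <= 0 are
    dropped unless ``admit_nonpositive`` (then clipped at penalty 1).
    Genes with constant effect vectors have no defined correlation and are
    excluded; isolated genes stay in the vertex set.
    """
    if gene_set is None:
        gene_set = list(effect_matrix.index)
    missing = [g for g in gene_set if g not in effect_matrix.index]
    if missing:
        raise ValueError(f"genes absent from effect matrix: {missing}")
    stds = effect_matrix.loc[list(gene_set)].std(axis=1, ddof=1)
    constant = list(stds.index[(stds == 0) | stds.isna()])
    if constant:
        log.warning("constant effect vectors excluded: %s", constant)
    usable = [g for g in gene_set if g not in constant]
    corr = pairwise_correlations(effect_matrix, min_pairs=min_pairs)
    if top_lists is None:
        top_lists = derive_top_lists(corr, usable, top_k=top_k)
    edges: dict[tuple[str, str], float] = {}
    for i, u in enumerate(usable):
        for v in usable[i + 1:]:
            in_list = v in top_lists.get(u, ()) or u in top_lists.get(v, ())
            if not in_list:
                continue
            r = corr.loc[u, v]
            if pd.isna(r):
                continue  # fewer than min_pairs complete observations
            if r <= 0 and not admit_nonpositive:
                continue
            key = (u, v) if u < v else (v, u)
            edges[key] = float(min(r, 1.0))
    graph = CodepGraph(nodes=sorted(gene_set), edges=edges)
    isolated = graph.degree_zero_nodes()
    if isolated:
        log.info("degree-zero vertices retained: %s", isolated)
    return graph


def shortest_path_census(
    graph: CodepGraph, tol: float = PATH_TOL
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """All-pairs shortest-path distances and path counts by Floyd-Warshall.

    Path multiplicities treat lengths within ``tol`` of the optimum as
    ties; disconnected pairs keep infinite distance and zero count.
    Returns (distance matrix, count matrix, node order).
    """
    dist = graph.penalty_matrix()
    n = dist.shape[0]
    sigma = np.zeros((n, n))
    sigma[np.isfinite(dist)] = 1.0
    np.fill_diagonal(sigma, 1.0)
    for k in range(n):
        for i in range(n):
            if i == k or not np.isfinite(dist[i, k]):
                continue
            for j in range(n):
                if j == k or j == i or not np.isfinite(dist[k, j]):
                    continue
                via = dist[i, k] + dist[k, j]
                if via < dist[i, j] - tol:
                    dist[i, j] = via
                    sigma[i, j] = sigma[i, k] * sigma[k, j]
                elif abs(via - dist[i, j]) <= tol:
                    sigma[i, j] += sigma[i, k] * sigma[k, j]
    sigma[~np.isfinite(dist)] = 0.0
    return dist, sigma, list(graph.nodes)


def betweenness_centrality(
    graph: CodepGraph,
    component_of: Optional[str] = None,
    tol: float = PATH_TOL,
) -> CentralityResult:
    """Betweenness centrality with min-max normalisation.

    g(v) sums, over unordered pairs {s, t} within the component with s, t
    distinct from v, the fraction of shortest s-t paths passing through v.
    Scores are normalised to [0, 1] so the most central vertex is 1 and
    the least central 0.  Components with fewer than 3 vertices (or flat
    scores) return all-zero normalised values flagged degenerate.
    """
    comp = graph.component_of(component_of) if component_of else graph.nodes
    dist, sigma, nodes = shortest_path_census(graph, tol=tol)
    idx = {n: i for i, n in enumerate(nodes)}
    members = [idx[g] for g in comp]
    raw = {g: 0.0 for g in comp}
    for a, s in enumerate(members):
        for t in members[a + 1:]:
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            for g in comp:
                v = idx[g]
                if v == s or v == t:
                    continue
                if abs(dist[s, v] + dist[v, t] - dist[s, t]) <= tol:
                    raw[g] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    values = np.array([raw[g] for g in comp])
    if len(comp) < 3 or np.ptp(values) == 0:
        return CentralityResult(
            nodes=list(comp), raw=raw,
            normalized={g: 0.0 for g in comp}, degenerate=True,
        )
    lo, hi = values.min(), values.max()
    normalized = {g: (raw[g] - lo) / (hi - lo) for g in comp}
    return CentralityResult(nodes=list(comp), raw=raw, normalized=normalized)


def read_effect_matrix(path, sep: str = ",") -> pd.DataFrame:
    """Read a genes x cell-lines effect matrix (first column = gene names)."""
    return pd.read_csv(path, sep=sep, index_col=0)


def read_top_lists(path) -> dict[str, list[str]]:
    """Read top co-dependency lists: TSV of gene \\t comma-joined ranked genes."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, _, rest = line.partition("\t")
            out[gene] = [g for g in rest.split(",") if g]
    return out
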