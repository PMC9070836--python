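"""Gene co-expression networks with a normal-quantile edge threshold.

For a selected gene list within one stratum (genotype x condition), the
pairwise Pearson correlation matrix is computed, all off-diagonal
correlations are Fisher z-transformed and standardized by their own mean
and standard deviation, and a gene pair becomes an edge when its
standardized value exceeds the standard-normal quantile at q (default
q = 0.997, cutoff ~2.748).  Only the upper tail forms edges in this
mode — edges are "co-expression connections".  An alternative empirical
mode thresholds |r| at its empirical q-quantile instead, in which
strongly negative correlations may also form edges.

Modules are detected by greedy modularity maximization; hubs are ranked
by degree, and genes with no connections are reported separately,
mirroring the isolated-gene lists of the published networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .dge import CountMatrix, log2_cpm


@dataclass
class HubReport:
    """Degree-ranked nodes and the isolated (degree-0) set."""

    degrees: pd.Series  # descending
    isolated: list


def pearson_corr_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between gene rows; constant genes yield NaN.

    NaN rows/columns are excluded from edge formation downstream.
    """
    if expr.shape[1] < 3:
        raise ValueError(f"need >=3 samples for correlations, got {expr.shape[1]}")
    mat = expr.values.astype(float)
    sd = mat.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(mat)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def edge_threshold(
    corr: pd.DataFrame,
    q: float = 0.997,
    mode: str = "normal",
    stratum: tuple[str, str] | None = None,
) -> nx.Graph:
    """Threshold a correlation matrix into an undirected co-expression graph.

    mode="normal": Fisher-z all off-diagonal correlations, standardize by
    their mean/sd, keep pairs whose standardized z exceeds norm.ppf(q).
    mode="empirical": keep pairs with |r| at or above the empirical
    q-quantile of off-diagonal |r| values.
    Edges carry the original correlation as ``weight``.
    """
    if not 0.5 < q < 1.0:
        raise ValueError(f"q must lie in (0.5, 1), got {q}")
    if mode not in ("normal", "empirical"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = list(corr.index)
    mat = corr.values
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    r = mat[iu]
    valid = np.isfinite(r)

    keep = np.zeros_like(valid)
    if valid.any():
        if mode == "normal":
            z = np.arctanh(np.clip(r[valid], -1 + 1e-12, 1 - 1e-12))
            sd = z.std()
            if sd > 0:
                zstd = (z - z.mean()) / sd
                keep[valid] = zstd > stats.norm.ppf(q)
        else:
            a = np.abs(r[valid])
            keep[valid] = a >= np.quantile(a, q)

    g = nx.Graph(stratum=stratum, q=q, mode=mode)
    g.add_nodes_from(genes)
    for i, j in zip(iu[0][keep], iu[1][keep]):
        g.add_edge(genes[i], genes[j], weight=float(mat[i, j]))
    return g


def detect_communities(graph: nx.Graph) -> tuple[pd.Series, float]:
    """Greedy modularity-maximizing partition; returns (labels, modularity).

    Modules are numbered by decreasing size; isolated nodes each form
    their own singleton module.
    """
    if graph.number_of_nodes() == 0:
        return pd.Series(dtype=int), 0.0
    if graph.number_of_edges() == 0:
        labels = pd.Series(range(1, graph.number_of_nodes() + 1), index=list(graph))
        return labels, 0.0
    comms = nx.community.greedy_modularity_communities(graph)
    comms = sorted(comms, key=lambda c: (-len(c), sorted(map(str, c))))
    labels = pd.Series(index=list(graph), dtype=int)
    for k, comm in enumerate(comms, start=1):
        for node in comm:
            labels[node] = k
    score = nx.community.modularity(graph, comms)
    return labels, float(score)


def hub_rank(graph: nx.Graph) -> HubReport:
    """Nodes ranked by degree (descending, ties by node id); isolated = degree 0."""
    deg = pd.Series(dict(graph.degree()), dtype=int)
    deg = deg.sort_index().sort_values(ascending=False, kind="stable")
    return HubReport(degrees=deg, isolated=sorted(deg.index[deg == 0]))


def build_stratified_gcns(
    cm: CountMatrix,
    gene_list: list[str],
    q: float = 0.997,
    mode: str = "normal",
) -> dict[tuple[str, str], dict]:
    """Correlate -> threshold -> communities -> hubs, per (genotype, condition).

    Returns a dict keyed by stratum with keys graph, modules, modularity,
    hubs.  Raises if any stratum has fewer than 3 samples.
    """
    missing = [g for g in gene_list if g not in cm.counts.index]
    if missing:
        raise ValueError(f"genes absent from counts: {missing[:5]}")
    lc = log2_cpm(cm).loc[gene_list]
    strata = cm.strata()
    out: dict[tuple[str, str], dict] = {}
    for stratum in sorted(strata.unique()):
        cols = strata.index[strata == stratum]
        if len(cols) < 3:
            raise ValueError(f"stratum {stratum} has <3 samples")
        corr = pearson_corr_matrix(lc[cols])
        graph = edge_threshold(corr, q=q, mode=mode, stratum=stratum)
        modules, score = detect_communities(graph)
        out[stratum] = {
            "graph": graph,
            "modules": modules,
            "modularity": score,
            "hubs": hub_rank(graph),
        }
    return out


def write_graph(graph: nx.Graph, edge_tsv: str, graphml: str | None = None) -> None:
    """Edge list as TSV (gene_a, gene_b, weight) and optionally GraphML."""
    rows = [
        {"gene_a": a, "gene_b": b, "weight": d["weight"]}
        for a, b, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        edge_tsv, sep="\t", index=False
    )
    if graphml:
        g = graph.copy()
        g.graph = {k: str(v) for k, v in g.graph.items()}
        nx.write_graphml(g, graphml)
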