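"""Reduced co-expression graph: top-k partners, correlation floor, no isolates.

The hormone/meristem gene graph is built by a literal three-step rule:
for every gene keep its k (default 5) most highly correlated partners
(signed Pearson r, descending; ties broken by lexicographic partner id),
take the union of those candidate edges across genes, discard edges with
r below the floor (default 0.75), and drop nodes left without edges.

Because the rule is a union over per-gene top-k lists, a hub can exceed
degree k: it only needs to appear in many other genes' top-k lists.
Node degree on the final graph is binned for display as {1}, {2-4},
{5-6}, {7-9}, {>=10}.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

DEGREE_BINS = ((1, 1, "1"), (2, 4, "2-4"), (5, 6, "5-6"), (7, 9, "7-9"))


def pairwise_correlation(expr_subset: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over genes (rows)."""
    if expr_subset.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    if expr_subset.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr_subset.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = expr_subset.index[np.where(sd == 0)[0][0]]
        raise ValueError(f"constant gene {bad!r} has undefined correlations")
    c = np.corrcoef(x)
    return pd.DataFrame(c, index=expr_subset.index, columns=expr_subset.index)


def build_topk_graph(
    corr: pd.DataFrame,
    k: int = 5,
    r_min: float = 0.75,
    use_abs: bool = False,
    node_attrs: pd.DataFrame | None = None,
) -> nx.Graph:
    """Union-of-top-k thresholded correlation graph.

    Parameters
    ----------
    corr
        Symmetric gene x gene Pearson matrix.
    k
        Partners retained per gene before the union.
    r_min
        Correlation floor; edges with r < r_min are discarded (boundary
        inclusive: r == r_min survives).
    use_abs
        Rank partners (and apply the floor) on |r| instead of signed r.
    node_attrs
        Optional per-gene attributes (e.g. module label, functional class)
        copied onto the surviving nodes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = list(corr.index)
    c = corr.to_numpy(dtype=float)
    score = np.abs(c) if use_abs else c

    candidates: set[tuple[str, str]] = set()
    for i, g in enumerate(genes):
        partners = sorted(
            (j for j in range(len(genes)) if j != i),
            key=lambda j: (-score[i, j], genes[j]),
        )[:k]
        for j in partners:
            candidates.add(tuple(sorted((g, genes[j]))))

    graph = nx.Graph()
    for a, b in sorted(candidates):
        i, j = genes.index(a), genes.index(b)
        if score[i, j] >= r_min:
            graph.add_edge(a, b, r=float(c[i, j]))
    graph.remove_nodes_from(list(nx.isolates(graph)))
    if node_attrs is not None:
        for node in graph.nodes:
            if node in node_attrs.index:
                graph.nodes[node].update(node_attrs.loc[node].to_dict())
    _assert_graph_invariants(graph, corr, k, r_min, use_abs)
    return graph


def _assert_graph_invariants(graph, corr, k, r_min, use_abs):
    score = corr.abs() if use_abs else corr
    for a, b, data in graph.edges(data=True):
        s = score.loc[a, b]
        assert s >= r_min, f"edge ({a},{b}) below the correlation floor"
        assert a != b, "self-loop"
        in_top_a = b in _topk_of(score, a, k)
        in_top_b = a in _topk_of(score, b, k)
        assert in_top_a or in_top_b, f"edge ({a},{b}) not in either endpoint's top-{k}"
    assert not list(nx.isolates(graph)), "isolated node in emitted graph"


def _topk_of(score: pd.DataFrame, gene: str, k: int) -> set[str]:
    s = score.loc[gene].drop(gene)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return set(order[:k])


def degree_bins(graph: nx.Graph) -> pd.Series:
    """Display bin per node: {1}, {2-4}, {5-6}, {7-9}, {>=10}.

    Degree-1 nodes get their own bin — they can occur in a union-top-k
    graph but sit below the smallest display bin of the published figure.
    """
    out = {}
    for node, deg in graph.degree():
        label = ">=10"
        for lo, hi, name in DEGREE_BINS:
            if lo <= deg <= hi:
                label = name
                break
        out[node] = label
    return pd.Series(out, name="degree_bin")


def edge_list(graph: nx.Graph) -> pd.DataFrame:
    """Deterministic (sorted) edge list with correlation weights."""
    rows = [(a, b, d["r"]) for a, b, d in graph.edges(data=True)]
    rows = [(min(a, b), max(a, b), r) for a, b, r in rows]
    return pd.DataFrame(sorted(rows), columns=["gene_a", "gene_b", "r"])
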