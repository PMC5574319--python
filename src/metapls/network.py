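"""Thresholded Pearson correlation networks over metabolite tables.

Edges come in two kinds: solid ``correlation`` edges (|r| above a tissue
threshold with two-sided p below alpha, computed within one group's
samples) and dotted ``structural`` edges from a user-supplied similarity
matrix.  Nodes carry an up/down/unchanged direction versus a comparison
group.  Correlation p-values are deliberately NOT multiple-testing
corrected by default (an optional BH switch exists); thresholds are raw.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from metapls.markers import bh_adjust
from metapls.synthgen import MetaboliteTable

logger = logging.getLogger(__name__)

__all__ = [
    "Edge",
    "correlation_edges",
    "node_directions",
    "structural_edges",
    "assemble_network",
    "correlation_p_value",
    "write_graphml",
    "write_edge_tsv",
    "write_node_tsv",
    "read_similarity_matrix",
]


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    kind: str  # "correlation" | "structural"
    r: float | None = None
    p: float | None = None
    similarity: float | None = None


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t-transform, t = r*sqrt(n-2)/sqrt(1-r^2)."""
    if n < 3:
        raise ValueError("need at least 3 samples")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlation_edges(
    table: MetaboliteTable,
    group: str,
    r_threshold: float,
    p_threshold: float = 0.05,
    bh: bool = False,
) -> list[Edge]:
    """All-pairs Pearson edges within one group's samples.

    Keeps pairs with ``|r| > r_threshold`` and ``p < p_threshold``; the edge
    sign is the sign of r.  Constant metabolites within the group are
    excluded with a warning (their correlation is undefined).  With
    ``bh=True`` p-values are BH-adjusted over all pairs before thresholding.
    """
    if not 0 < r_threshold < 1 or not 0 < p_threshold < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    mask = table.group_mask(group)
    n = int(mask.sum())
    if n < 4:
        raise ValueError(f"group {group!r} needs at least 4 samples, has {n}")
    sub = table.values[mask]
    sds = sub.std(axis=0)
    keep = sds > 0
    if not keep.all():
        dropped = [m for m, k in zip(table.metabolite_names, keep) if not k]
        logger.warning("correlation_edges: excluding constant metabolite(s) %s", dropped)
    names = [m for m, k in zip(table.metabolite_names, keep) if k]
    sub = sub[:, keep]
    if sub.shape[1] < 2:
        return []

    corr = np.corrcoef(sub, rowvar=False)
    iu, ju = np.triu_indices(len(names), k=1)
    rs = np.clip(corr[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        ts = rs * np.sqrt(n - 2) / np.sqrt(1.0 - rs * rs)
    ps = np.where(np.abs(rs) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(ts), df=n - 2))
    if bh:
        ps = bh_adjust(np.clip(ps, np.finfo(float).tiny, 1.0))
    edges = [
        Edge(a=names[i], b=names[j], kind="correlation", r=float(r), p=float(p))
        for i, j, r, p in zip(iu, ju, rs, ps)
        if abs(r) > r_threshold and p < p_threshold
    ]
    return edges


def node_directions(
    table: MetaboliteTable,
    group: str,
    reference_group: str,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> dict[str, str]:
    """Up/down/unchanged direction of each metabolite versus a reference group.

    ``up`` if the group mean exceeds the reference mean with raw two-sample
    p < alpha, ``down`` if below, otherwise ``unchanged``.
    """
    mask_g = table.group_mask(group)
    mask_r = table.group_mask(reference_group)
    for name, m in ((group, mask_g), (reference_group, mask_r)):
        if not m.any():
            raise ValueError(f"group {name!r} missing from table")
    a, r = table.values[mask_g], table.values[mask_r]
    res = stats.ttest_ind(a, r, axis=0, equal_var=equal_var)
    pvals = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=0) - r.mean(axis=0)
    out: dict[str, str] = {}
    for met, d, p in zip(table.metabolite_names, diff, pvals):
        if np.isfinite(p) and p < alpha and d != 0:
            out[met] = "up" if d > 0 else "down"
        else:
            out[met] = "unchanged"
    return out


def structural_edges(similarity: pd.DataFrame, threshold: float) -> list[Edge]:
    """Dotted edges between structurally similar metabolites.

    Keeps metabolite pairs whose similarity is >= threshold; the matrix must
    be symmetric with metabolite names as both index and columns.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    mat = similarity.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1] or list(similarity.index) != list(similarity.columns):
        raise ValueError("similarity matrix must be square with matching labels")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    names = list(similarity.index)
    iu, ju = np.triu_indices(len(names), k=1)
    return [
        Edge(a=names[i], b=names[j], kind="structural", similarity=float(mat[i, j]))
        for i, j in zip(iu, ju)
        if mat[i, j] >= threshold
    ]


def assemble_network(
    correlation: Sequence[Edge],
    structural: Sequence[Edge] = (),
    directions: Mapping[str, str] | None = None,
    drop_isolated: bool = True,
) -> nx.MultiGraph:
    """Merge edge lists and node directions into one multigraph.

    Parallel edges of distinct kinds between the same pair are preserved;
    duplicate edges of the same (pair, kind) are rejected.  Metabolites with
    a direction but no edge are dropped when ``drop_isolated`` is true.
    """
    g = nx.MultiGraph()
    seen: set[tuple[frozenset, str]] = set()
    for edge in list(correlation) + list(structural):
        if edge.a == edge.b:
            raise ValueError(f"self-edge on {edge.a!r}")
        key = (frozenset((edge.a, edge.b)), edge.kind)
        if key in seen:
            raise ValueError(f"duplicate {edge.kind} edge {edge.a!r}-{edge.b!r}")
        seen.add(key)
        attrs: dict = {"kind": edge.kind}
        if edge.kind == "correlation":
            attrs["r"] = edge.r
            attrs["p"] = edge.p
            attrs["sign"] = "positive" if (edge.r or 0) >= 0 else "negative"
        else:
            attrs["similarity"] = edge.similarity
        g.add_edge(edge.a, edge.b, key=edge.kind, **attrs)

    if directions:
        for met, direction in directions.items():
            if not drop_isolated or met in g:
                g.add_node(met, direction=direction)
        for node in g.nodes:
            g.nodes[node].setdefault("direction", "unchanged")
    return g


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_graphml(graph: nx.MultiGraph, path) -> None:
    nx.write_graphml(graph, path)


def write_edge_tsv(graph: nx.MultiGraph, path) -> None:
    rows = []
    for a, b, data in sorted(graph.edges(data=True), key=lambda e: (e[0], e[1], e[2]["kind"])):
        rows.append(
            {
                "metabolite_a": a,
                "metabolite_b": b,
                "kind": data["kind"],
                "r": data.get("r", ""),
                "p": data.get("p", ""),
                "similarity": data.get("similarity", ""),
            }
        )
    pd.DataFrame(
        rows, columns=["metabolite_a", "metabolite_b", "kind", "r", "p", "similarity"]
    ).to_csv(path, sep="\t", index=False)


def write_node_tsv(graph: nx.MultiGraph, path) -> None:
    rows = [
        {"metabolite": n, "direction": graph.nodes[n].get("direction", "unchanged")}
        for n in sorted(graph.nodes)
    ]
    pd.DataFrame(rows, columns=["metabolite", "direction"]).to_csv(path, sep="\t", index=False)


def read_similarity_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
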