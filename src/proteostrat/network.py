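"""Protein co-abundance correlation network and modularity modules.

High-variance proteins are connected by edges where the pairwise
Pearson correlation exceeds a threshold (positive correlations only),
pruned to the k-core, and partitioned by Louvain modularity
optimization at a resolution parameter.  A module can then be expanded
into a target feature set by pulling in any protein of the full matrix
correlating above a cutoff with any module member, and summarized as
module x patient-group mean abundances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .io import OmicsMatrix

__all__ = [
    "build_network",
    "kcore",
    "modules",
    "expand_module",
    "module_group_means",
]


def _pairwise_pearson(values: pd.DataFrame) -> np.ndarray:
    """Missing-aware pairwise Pearson correlations between features."""
    X = values.to_numpy(dtype=float)
    if np.isnan(X).any():
        return pd.DataFrame(X.T).corr(min_periods=3).to_numpy()
    return np.corrcoef(X)


def build_network(matrix: OmicsMatrix, n_top_sd: int = 1047,
                  r_edge: float = 0.6) -> nx.Graph:
    """Correlation graph over the ``n_top_sd`` highest-SD features.

    Edges connect feature pairs with Pearson r >= ``r_edge`` (positive
    correlations only); edge weights carry r.
    """
    if not 0.0 < r_edge < 1.0:
        raise ValueError("r_edge must lie in (0, 1)")
    if n_top_sd > matrix.n_features:
        raise ValueError("n_top_sd exceeds the number of features")
    sds = matrix.values.std(axis=1, skipna=True)
    keep = sds.sort_values(ascending=False).index[:n_top_sd]
    sub = matrix.values.loc[keep]
    corr = _pairwise_pearson(sub)
    graph = nx.Graph()
    graph.add_nodes_from(keep)
    feats = keep.to_numpy()
    iu = np.triu_indices(len(feats), k=1)
    rs = corr[iu]
    mask = np.isfinite(rs) & (rs >= r_edge)
    for i, j, r in zip(iu[0][mask], iu[1][mask], rs[mask]):
        graph.add_edge(feats[i], feats[j], r=float(r))
    return graph


def kcore(graph: nx.Graph, k: int = 3) -> nx.Graph:
    """Iteratively remove nodes of degree < k until a fixed point.

    May return an empty graph; the fixed point (every remaining node
    has degree >= k) is asserted.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    core = nx.k_core(graph, k=k).copy()
    assert all(d >= k for _, d in core.degree()), "k-core fixed point violated"
    return core


def modules(graph: nx.Graph, resolution: float = 0.8,
            seed: int = 0) -> pd.Series:
    """Louvain modularity clustering; node -> module label (0-based).

    The graph is rebuilt with sorted node order before clustering so
    labels are invariant to the input node order at a fixed seed;
    community ids are assigned in order of each community's smallest
    node id.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    canonical = nx.Graph()
    canonical.add_nodes_from(sorted(graph.nodes()))
    canonical.add_weighted_edges_from(
        sorted((min(u, v), max(u, v), d.get("r", 1.0))
               for u, v, d in graph.edges(data=True)),
        weight="weight")
    comms = nx.community.louvain_communities(
        canonical, weight="weight", resolution=resolution, seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = {}
    for module_id, members in enumerate(comms):
        for node in members:
            labels[node] = module_id
    return pd.Series(labels, name="module").sort_index()


def expand_module(module_nodes: list[str], full_matrix: OmicsMatrix,
                  r_min: float = 0.7) -> set[str]:
    """Module members plus every feature correlating above ``r_min``
    (strictly) with any member in the full matrix."""
    module_nodes = [f for f in module_nodes if f in full_matrix.values.index]
    if not module_nodes:
        raise ValueError("empty module after matching to the matrix")
    members = full_matrix.values.loc[module_nodes]
    all_vals = full_matrix.values
    # correlation of every feature against every module member
    A = all_vals.to_numpy(dtype=float)
    B = members.to_numpy(dtype=float)
    if np.isnan(A).any():
        corr = np.empty((A.shape[0], B.shape[0]))
        for j in range(B.shape[0]):
            b = B[j]
            for i in range(A.shape[0]):
                a = A[i]
                obs = np.isfinite(a) & np.isfinite(b)
                if obs.sum() < 3 or a[obs].std() == 0 or b[obs].std() == 0:
                    corr[i, j] = np.nan
                else:
                    corr[i, j] = np.corrcoef(a[obs], b[obs])[0, 1]
    else:
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(Ac, axis=1)
        nb = np.linalg.norm(Bc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Ac @ Bc.T) / np.outer(na, nb)
    with np.errstate(invalid="ignore"):
        best = np.nanmax(corr, axis=1)
    pulled = all_vals.index[np.nan_to_num(best, nan=-2.0) > r_min]
    return set(module_nodes) | set(pulled)


def module_group_means(matrix: OmicsMatrix, module_labels: pd.Series,
                       group_labels: pd.Series) -> pd.DataFrame:
    """Module x group table of mean log2 abundance (missing-aware)."""
    groups = group_labels.loc[matrix.sample_ids]
    out = {}
    for module_id in sorted(module_labels.unique()):
        feats = [f for f in module_labels.index[module_labels == module_id]
                 if f in matrix.values.index]
        if not feats:
            raise ValueError(f"module {module_id!r} has no features "
                             "in the matrix")
        sub = matrix.values.loc[feats]
        per_sample = sub.mean(axis=0, skipna=True)
        out[module_id] = per_sample.groupby(groups).mean()
    table = pd.DataFrame(out).T
    table.index.name = "module"
    return table
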