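"""Hierarchical clustering, validation indices, network metrics, hub genes.

The validation indices follow the three families commonly used to compare
distance measures through a clustering method:

internal
    connectivity (lower is better) and the Dunn index (higher is better);
stability
    AD and ADM (lower is better), comparing clusterings of the full data
    with clusterings after deleting one experiment at a time;
biological
    BHI, the within-cluster fraction of annotated gene pairs sharing a
    functional class.

``normalize_scores`` min–max rescales each metric across all compared
(method, k) cells and flips lower-is-better metrics so that, after
normalization, larger is always better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .datamodel import PacDataset, ValidationError
from .similarity import SimilarityMatrix, to_distance, weight_matrix

__all__ = [
    "ClusteringResult",
    "hierarchical_cluster",
    "estimate_k",
    "connectivity",
    "dunn_index",
    "ad_adm",
    "bhi",
    "normalize_scores",
    "network_metrics",
    "module_eigengene_hubs",
]

#: metrics where a smaller raw value means a better clustering
LOWER_IS_BETTER = ("CON", "AD", "ADM")


def _check_distance(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    return dist


@dataclass
class ClusteringResult:
    """Linkage tree plus flat assignments for each requested k."""

    linkage: np.ndarray
    assignments: dict[int, np.ndarray]  # k -> integer labels, one per gene
    method: str


def hierarchical_cluster(
    dist: np.ndarray, k_range: Iterable[int], method: str = "complete"
) -> ClusteringResult:
    """Agglomerative clustering of a distance matrix, cut at each k."""
    dist = _check_distance(dist)
    G = dist.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 1 or k > G for k in ks):
        raise ValidationError(f"cluster counts must lie in [1, {G}]")
    Z = linkage(squareform(dist, checks=False), method=method)
    assignments = {
        k: cut_tree(Z, n_clusters=k)[:, 0].astype(int) for k in ks
    }
    return ClusteringResult(linkage=Z, assignments=assignments, method=method)


def estimate_k(dist: np.ndarray, k_range: Iterable[int], method: str = "complete") -> int:
    """k maximizing the mean silhouette width of the hierarchical cut.

    Ties resolve to the smallest k.
    """
    dist = _check_distance(dist)
    ks = sorted(set(int(k) for k in k_range))
    G = dist.shape[0]
    if any(k < 2 or k > G - 1 for k in ks):
        raise ValidationError(f"silhouette needs k in [2, {G - 1}]")
    res = hierarchical_cluster(dist, ks, method=method)
    best_k, best_s = None, -np.inf
    for k in ks:
        labels = res.assignments[k]
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(dist, labels, metric="precomputed")
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        return ks[0]
    return best_k


def _neighbor_order(dist: np.ndarray, i: int) -> np.ndarray:
    # nearest first; equal distances broken by index
    G = dist.shape[0]
    others = np.array([j for j in range(G) if j != i])
    order = np.lexsort((others, dist[i, others]))
    return others[order]


def connectivity(dist: np.ndarray, assignment: Sequence[int], L: int = 10) -> float:
    """Connectivity index: penalty 1/j when the j-th nearest neighbour of an
    observation sits in a different cluster.  Lower is better; 0 when
    clusters respect the L-nearest-neighbour structure."""
    dist = _check_distance(dist)
    labels = np.asarray(assignment)
    G = dist.shape[0]
    if L >= G:
        raise ValidationError("neighbour count L must be < number of observations")
    total = 0.0
    for i in range(G):
        nn = _neighbor_order(dist, i)[:L]
        for j, v in enumerate(nn, start=1):
            if labels[v] != labels[i]:
                total += 1.0 / j
    return total


def dunn_index(dist: np.ndarray, assignment: Sequence[int]) -> float:
    """Minimum between-cluster distance over maximum cluster diameter."""
    dist = _check_distance(dist)
    labels = np.asarray(assignment)
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValidationError("the Dunn index needs at least two clusters")
    max_diam = 0.0
    for c in clusters:
        idx = np.flatnonzero(labels == c)
        if len(idx) > 1:
            max_diam = max(max_diam, float(dist[np.ix_(idx, idx)].max()))
    if max_diam == 0.0:
        raise ValidationError("degenerate clustering: every cluster has zero diameter")
    min_sep = np.inf
    for a in range(len(clusters)):
        ia = np.flatnonzero(labels == clusters[a])
        for b in range(a + 1, len(clusters)):
            ib = np.flatnonzero(labels == clusters[b])
            min_sep = min(min_sep, float(dist[np.ix_(ia, ib)].min()))
    return min_sep / max_diam


def ad_adm(
    data: PacDataset,
    k: int,
    weight_fn: Callable[[PacDataset], SimilarityMatrix] | None = None,
    method: str = "complete",
) -> tuple[float, float]:
    """Stability indices AD and ADM by leave-one-experiment-out deletion.

    For each experiment deleted in turn (with all its replicates) the weight
    matrix is recomputed and the genes re-clustered at ``k``.  AD averages,
    over deletions and genes, each gene's mean full-data distance to the
    co-members of its *perturbed* cluster (genes isolated in the perturbed
    clustering are skipped).  ADM averages the Euclidean distance between a
    gene's cluster centre (mean gene-level profile on the full data) under
    the full versus the perturbed clustering.  Lower is better for both.
    """
    if data.design.n_experiments < 3:
        raise ValidationError("stability validation needs at least 3 experiments")
    if weight_fn is None:
        weight_fn = weight_matrix
    sim_full = weight_fn(data)
    dist_full = to_distance(sim_full)
    full_labels = hierarchical_cluster(dist_full, [k], method=method).assignments[k]
    _, profiles = data.gene_totals()
    G = len(full_labels)

    def centers(labels: np.ndarray) -> dict[int, np.ndarray]:
        return {
            c: profiles[np.flatnonzero(labels == c)].mean(axis=0)
            for c in set(labels.tolist())
        }

    full_centers = centers(full_labels)
    ad_terms: list[float] = []
    adm_terms: list[float] = []
    for exp in data.design.experiments:
        reduced = data.drop_experiment(exp)
        sim_red = weight_fn(reduced)
        dist_red = to_distance(sim_red)
        red_labels = hierarchical_cluster(dist_red, [k], method=method).assignments[k]
        red_centers = centers(red_labels)
        for i in range(G):
            mates = np.flatnonzero(red_labels == red_labels[i])
            mates = mates[mates != i]
            if len(mates):
                ad_terms.append(float(dist_full[i, mates].mean()))
            adm_terms.append(
                float(np.linalg.norm(full_centers[full_labels[i]] - red_centers[red_labels[i]]))
            )
    ad = float(np.mean(ad_terms)) if ad_terms else 0.0
    adm = float(np.mean(adm_terms))
    return ad, adm


def bhi(assignment: Mapping[str, int], annotation: Mapping[str, Iterable[str]]) -> float:
    """Biological homogeneity index in [0, 1].

    Per cluster, the fraction of ordered pairs of distinct annotated genes
    sharing at least one functional class; averaged over clusters with at
    least two annotated genes.
    """
    ann = {g: set(v) for g, v in annotation.items() if v}
    by_cluster: dict[int, list[str]] = {}
    for gene, c in assignment.items():
        by_cluster.setdefault(c, []).append(gene)
    fractions = []
    for members in by_cluster.values():
        annotated = [g for g in members if g in ann]
        n = len(annotated)
        if n < 2:
            continue
        hits = sum(
            1
            for a in annotated
            for b in annotated
            if a != b and ann[a] & ann[b]
        )
        fractions.append(hits / (n * (n - 1)))
    if not fractions:
        raise ValidationError("no cluster has two or more annotated genes")
    return float(np.mean(fractions))


def normalize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Min–max normalize validation scores to [0, 1], larger = better.

    ``scores`` has one row per compared (method, k) cell and one column per
    metric.  Lower-is-better metrics (CON, AD, ADM) are flipped.  A metric
    constant across cells maps to 0.5 everywhere.
    """
    out = scores.copy().astype(float)
    for col in out.columns:
        v = out[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(v), np.nanmax(v)
        if hi == lo:
            out[col] = 0.5
            continue
        z = (v - lo) / (hi - lo)
        if col in LOWER_IS_BETTER:
            z = 1.0 - z
        out[col] = z
    return out


def network_metrics(
    genes: Sequence[str],
    weights: np.ndarray,
    modules: Mapping[str, int],
    tau: float = 0.5,
) -> tuple[float, float, float]:
    """(mean EC, ACC, MD) of the thresholded weighted gene network.

    The adjacency is binarized at ``w > tau``.  EC is the mean eigenvector
    centrality (principal eigenvector of the binary adjacency, scaled to
    unit maximum); ACC the mean local clustering coefficient over nodes of
    degree >= 2; MD the Newman modularity of the given module partition.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValidationError("weights must lie in [0, 1]")
    A = (weights > tau).astype(float)
    np.fill_diagonal(A, 0.0)
    if A.sum() == 0:
        raise ValidationError("graph is empty after thresholding")
    evals, evecs = np.linalg.eigh(A)
    v = np.abs(evecs[:, np.argmax(evals)])
    ec = float((v / v.max()).mean())

    Gx = nx.from_numpy_array(A)
    cc = nx.clustering(Gx)
    deg = dict(Gx.degree())
    eligible = [n for n in Gx if deg[n] >= 2]
    acc = float(np.mean([cc[n] for n in eligible])) if eligible else 0.0

    parts: dict[int, set[int]] = {}
    for i, gene in enumerate(genes):
        parts.setdefault(modules[gene], set()).add(i)
    md = float(nx.community.modularity(Gx, [p for p in parts.values() if p]))
    return ec, acc, md


def module_eigengene_hubs(
    expression: pd.DataFrame,
    modules: Mapping[str, int],
    threshold: float = 0.7,
) -> dict[int, list[str]]:
    """Hub genes per module via correlation with the module eigengene.

    ``expression`` is a gene x condition profile matrix (rows indexed by
    gene).  Each module's eigengene is the first principal component of its
    row-standardized submatrix, with the sign chosen so the mean gene
    correlation is non-negative.  Genes correlating with the eigengene above
    ``threshold`` are hubs.  Modules of a single gene are skipped with a
    warning.
    """
    out: dict[int, list[str]] = {}
    by_mod: dict[int, list[str]] = {}
    for gene, m in modules.items():
        by_mod.setdefault(m, []).append(gene)
    for m, members in sorted(by_mod.items()):
        if len(members) < 2:
            warnings.warn(f"module {m} has a single gene; skipped")
            continue
        X = expression.loc[members].to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        eig = vt[0]
        cors = np.array([_safe_corr(row, eig) for row in Z])
        if cors.mean() < 0:
            eig = -eig
            cors = -cors
        out[m] = [g for g, c in zip(members, cors) if c > threshold]
    return out


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])
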