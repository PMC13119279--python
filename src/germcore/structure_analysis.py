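"""Distance matrices, ordination, trees, clustering and kinship.

Distances are computed over pairwise non-missing sites.  The NJ
agglomeration is deterministic: Q-criterion ties break on the lowest node
index pair, and negative branch lengths are clamped to zero with the total
deficit logged.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import GenotypeMatrix

log = logging.getLogger(__name__)


def _pairwise_site_mean(dosages: np.ndarray, func) -> np.ndarray:
    """Mean of func(|g_i - g_j|-style per-site values) over complete pairs."""
    n = dosages.shape[0]
    out = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        diff = dosages[i + 1 :] - dosages[i]  # NaN propagates for missing
        vals = func(diff)
        counts = np.sum(~np.isnan(vals), axis=1)
        if (counts == 0).any():
            bad = int(np.flatnonzero(counts == 0)[0]) + i + 1
            raise ValueError(f"accession pair ({i}, {bad}) shares no called sites")
        out[i, i + 1 :] = np.nanmean(vals, axis=1)
        out[i + 1 :, i] = out[i, i + 1 :]
    return out


def ibs_distance(geno: GenotypeMatrix) -> pd.DataFrame:
    """Identity-by-state distance: 1 - mean shared-allele fraction.

    Per site the shared fraction is (2 - |g_i - g_j|)/2, so the distance is
    the mean absolute dosage difference halved.
    """
    if geno.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    d = _pairwise_site_mean(geno.dosages, lambda diff: np.abs(diff) / 2.0)
    return pd.DataFrame(d, index=geno.accession_ids, columns=geno.accession_ids)


def modified_rogers_distance(geno: GenotypeMatrix) -> pd.DataFrame:
    """Modified Rogers distance: sqrt(mean squared dosage difference / 4)."""
    if geno.n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    msq = _pairwise_site_mean(geno.dosages, lambda diff: np.square(diff) / 4.0)
    return pd.DataFrame(
        np.sqrt(msq), index=geno.accession_ids, columns=geno.accession_ids
    )


def gower_distance(table: pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarity for numeric traits: mean range-scaled |x_i - x_j|."""
    x = table.to_numpy(dtype=float)
    ranges = x.max(axis=0) - x.min(axis=0)
    keep = ranges > 0
    if not keep.any():
        raise ValueError("all traits constant: Gower distance undefined")
    xs = x[:, keep] / ranges[keep]
    n = len(table)
    out = np.zeros((n, n))
    for i in range(n - 1):
        out[i, i + 1 :] = np.mean(np.abs(xs[i + 1 :] - xs[i]), axis=1)
        out[i + 1 :, i] = out[i, i + 1 :]
    return pd.DataFrame(out, index=table.index, columns=table.index)


def grm_pca(
    geno: GenotypeMatrix, n_components: int = 10
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of the standardized genotype matrix (GRM eigendecomposition).

    Sites are centered by 2p and scaled by sqrt(2p(1-p)); missing calls are
    mean-imputed (zero after centering).  Returns accession coordinates and
    the percentage of variance explained per component.
    """
    if n_components > geno.n_accessions:
        raise ValueError("more components requested than accessions")
    X = geno.dosages.copy()
    called = ~np.isnan(X)
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * n)
    keep = (n > 0) & (p > 0) & (p < 1)
    X = X[:, keep]
    p = p[keep]
    Z = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    Z[np.isnan(Z)] = 0.0
    G = Z @ Z.T / Z.shape[1]
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    coords = evecs[:, :n_components] * np.sqrt(evals[:n_components])
    cols = [f"PC{i+1}" for i in range(n_components)]
    return pd.DataFrame(coords, index=geno.accession_ids, columns=cols), pct[:n_components]


def pcoa(
    distance: pd.DataFrame, n_components: int = 10
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps the positive
    eigenvalues.  Exact for Euclidean-embeddable input.
    """
    D = np.asarray(distance, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * max(evals.max(), 1.0))
    k = min(n_components, int(pos.sum()))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    idx = distance.index if isinstance(distance, pd.DataFrame) else range(n)
    cols = [f"Axis{i+1}" for i in range(k)]
    return pd.DataFrame(coords, index=idx, columns=cols), evals[:k]


def nj_tree(distance: pd.DataFrame, labels: Optional[Sequence[str]] = None) -> dendropy.Tree:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix.

    Deterministic: Q ties break on the lowest (i, j) node-index pair.
    Negative branch lengths are clamped to zero and the summed deficit is
    logged.  The returned tree is unrooted (seed node of degree 3 for
    n >= 3 leaves).
    """
    D = np.asarray(distance, dtype=float).copy()
    if not np.isfinite(D).all():
        raise ValueError("non-finite distances")
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 leaves")
    if labels is None:
        labels = (
            [str(x) for x in distance.index]
            if isinstance(distance, pd.DataFrame)
            else [f"L{i}" for i in range(n)]
        )

    taxa = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lbl in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lbl))
        nodes.append(nd)

    active = list(range(n))
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(active) > 2:
        r = len(active)
        sub = D[np.ix_(active, active)]
        rowsums = sub.sum(axis=1)
        Q = (r - 2) * sub - rowsums[:, None] - rowsums[None, :]
        np.fill_diagonal(Q, np.inf)
        Q[np.tril_indices(r)] = np.inf
        # argmin on the flattened upper triangle returns the first (row-major)
        # minimum, i.e. the lowest (i, j) pair on exact ties
        flat = int(np.argmin(Q))
        i, j = divmod(flat, r)
        dij = sub[i, j]
        li = dij / 2.0 + (rowsums[i] - rowsums[j]) / (2.0 * (r - 2))
        lj = dij - li
        parent = dendropy.Node()
        ni, nj_ = nodes[active[i]], nodes[active[j]]
        parent.add_child(ni)
        parent.add_child(nj_)
        ni.edge.length = clamp(li)
        nj_.edge.length = clamp(lj)
        # distances from the new node to the remaining active nodes
        new_d = np.zeros(D.shape[0] + 1)
        for k_pos, k in enumerate(active):
            if k_pos in (i, j):
                continue
            new_d[k] = 0.5 * (sub[i, k_pos] + sub[j, k_pos] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d[:-1]
        D[:-1, -1] = new_d[:-1]
        nodes.append(parent)
        new_idx = D.shape[0] - 1
        active = [k for k_pos, k in enumerate(active) if k_pos not in (i, j)] + [new_idx]

    a, b = active
    na, nb = nodes[a], nodes[b]
    final_len = clamp(D[a, b])
    if not na.is_leaf():
        root, child = na, nb
    else:
        root, child = nb, na
    root.add_child(child)
    child.edge.length = final_len
    tree.seed_node = root
    if deficit > 0:
        log.info("NJ clamped negative branch lengths; total deficit %.6g", deficit)
    return tree


def hclust_phenotypes(
    table: pd.DataFrame, k: int = 4, method: str = "ward"
) -> pd.Series:
    """Hierarchical clustering of standardized traits, cut into k clusters.

    Traits are z-scored, distances are Euclidean, linkage defaults to Ward.
    Returns 1-based cluster labels indexed by accession.
    """
    if k > len(table):
        raise ValueError("k exceeds number of accessions")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=0)) / sd
    link = hierarchy.linkage(z, method=method, metric="euclidean")
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=table.index, name="cluster")


def hclust_distance(distance: pd.DataFrame, k: int, method: str = "average") -> pd.Series:
    """Cut a hierarchical clustering of a precomputed distance matrix."""
    condensed = squareform(np.asarray(distance, dtype=float), checks=False)
    link = hierarchy.linkage(condensed, method=method)
    labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
    return pd.Series(labels, index=distance.index, name="group")


def kinship_matrix(geno: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of accession dosage vectors.

    Computed over pairwise non-missing sites; the diagonal is exactly 1.
    Zero-variance accessions yield NaN entries and a warning.
    """
    masked = np.ma.masked_invalid(geno.dosages)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.ma.corrcoef(masked)
    K = np.ma.filled(corr, np.nan)
    np.fill_diagonal(K, 1.0)
    if np.isnan(K).any():
        warnings.warn("zero-variance accession(s): some kinship entries undefined")
    return pd.DataFrame(K, index=geno.accession_ids, columns=geno.accession_ids)


KINSHIP_BIN_LABELS = ("<0.125", "0.125-0.25", "0.25-0.5", ">0.5")


def kinship_bins(
    matrix: pd.DataFrame, cuts: Sequence[float] = (0.125, 0.25, 0.5)
) -> pd.DataFrame:
    """Bin off-diagonal kinship pairs: (<c1), [c1,c2), [c2,c3], (>c3)."""
    c1, c2, c3 = cuts
    K = np.asarray(matrix, dtype=float)
    iu = np.triu_indices(K.shape[0], k=1)
    vals = K[iu]
    counts = np.array(
        [
            np.sum(vals < c1),
            np.sum((vals >= c1) & (vals < c2)),
            np.sum((vals >= c2) & (vals <= c3)),
            np.sum(vals > c3),
        ]
    )
    pct = 100.0 * counts / counts.sum() if counts.sum() else np.zeros(4)
    return pd.DataFrame(
        {"bin": KINSHIP_BIN_LABELS, "n_pairs": counts, "percent": pct}
    )


def group_composition(
    labels_a: pd.Series, labels_b: pd.Series
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate two labelings; returns (counts, row-wise percentages)."""
    joined = pd.concat([labels_a.rename("a"), labels_b.rename("b")], axis=1).dropna()
    counts = pd.crosstab(joined["a"], joined["b"])
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return counts, pct
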