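"""Multivariate source apportionment: correlation, PCA + varimax, clustering.

All analyses operate on the samples × variables table standardised to
z-scores (sd with the n−1 denominator).  PCA is an eigendecomposition of the
Pearson correlation matrix; components with eigenvalue > 1 are retained
(Kaiser criterion) and rotated with varimax under Kaiser normalisation.
Variables are clustered with Ward linkage on Euclidean distances between
their z-score profiles, matching common hydrochemical practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .errors import UndefinedQuantityError, ValidationError


@dataclass(frozen=True)
class CorrMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    sig: pd.DataFrame  # "**" p<0.01, "*" p<0.05, "" otherwise


@dataclass(frozen=True)
class PcaResult:
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    cum_pct: np.ndarray
    loadings: pd.DataFrame  # rotated loadings of the retained components
    n_retained: int
    rotation: str


@dataclass(frozen=True)
class LinkageTree:
    labels: tuple[str, ...]
    linkage: np.ndarray  # scipy linkage matrix
    method: str = "ward"
    metric: str = "euclidean"

    def cut(self, k: int) -> dict[str, int]:
        """Cluster id (1..k) per label at a k-cluster cut."""
        assign = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def to_newick(self) -> str:
        """Dendrogram in Newick format, branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0) if parent_height else node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height - 0.0:.6g}"
            left = walk_child(node.left, node.dist)
            right = walk_child(node.right, node.dist)
            return f"({left},{right})"

        def walk_child(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            inner = f"({walk_child(node.left, node.dist)},{walk_child(node.right, node.dist)})"
            return f"{inner}:{parent_height - node.dist:.6g}"

        return walk(tree, 0.0) + ";"


def zscore_table(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (mean 0, sd 1 with the n−1 denominator)."""
    sd = table.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()].index.tolist()
    if constant:
        raise ValidationError(f"constant column(s): {', '.join(map(str, constant))}")
    return (table - table.mean()) / sd


def pearson_matrix(table: pd.DataFrame) -> CorrMatrix:
    """Pairwise Pearson r with two-tailed t-test significance flags."""
    n = len(table)
    if n < 3:
        raise UndefinedQuantityError(f"need >= 3 samples for significance tests, got {n}")
    z = zscore_table(table)
    cols = tuple(str(c) for c in table.columns)
    r = z.T.dot(z) / (n - 1)
    r = r.clip(-1.0, 1.0)
    np.fill_diagonal(r.values, 1.0)
    rv = r.values
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = rv * np.sqrt((n - 2) / np.maximum(1.0 - rv**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    pf = pd.DataFrame(p, index=r.index, columns=r.columns)
    sig = pf.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    return CorrMatrix(variables=cols, r=r, p=pf, sig=sig)


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation of a loading matrix (variables × components)."""
    lam = np.asarray(loadings, dtype=float).copy()
    p, k = lam.shape
    if k < 2:
        return lam
    if kaiser_normalize:
        comm = np.sqrt((lam**2).sum(axis=1))
        comm[comm == 0] = 1.0
        lam = lam / comm[:, None]
    rot = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        lr = lam @ rot
        tmp = lr**3 - lr @ np.diag((lr**2).sum(axis=0)) / p
        u, s, vt = np.linalg.svd(lam.T @ tmp)
        rot = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    lam = lam @ rot
    if kaiser_normalize:
        lam = lam * comm[:, None]
    return lam


def pca_varimax(table: pd.DataFrame, kaiser_threshold: float = 1.0,
                rotation: str = "varimax") -> PcaResult:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Sign convention: each retained component is flipped so its
    largest-magnitude loading is positive (deterministic output).
    """
    n, m = table.shape
    if n <= 2:
        raise UndefinedQuantityError(f"need more than 2 samples for a PCA, got {n}")
    z = zscore_table(table)
    corr = np.asarray(z.T.dot(z) / (n - 1), dtype=float)
    corr = (corr + corr.T) / 2.0
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    pct = 100.0 * eigval / eigval.sum()
    n_keep = max(int((eigval > kaiser_threshold).sum()), 1)
    load = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    if rotation == "varimax" and n_keep > 1:
        load = varimax(load)
    elif rotation not in ("varimax", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    for j in range(load.shape[1]):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
    # order rotated components by explained variance (column sum of squares)
    col_order = np.argsort(-(load**2).sum(axis=0))
    load = load[:, col_order]
    frame = pd.DataFrame(load, index=table.columns,
                         columns=[f"PC{i + 1}" for i in range(load.shape[1])])
    return PcaResult(eigenvalues=eigval, pct_variance=pct, cum_pct=np.cumsum(pct),
                     loadings=frame, n_retained=n_keep,
                     rotation=rotation if n_keep > 1 else "none")


def hca_ward(table: pd.DataFrame, orientation: str = "variables") -> LinkageTree:
    """Ward/Euclidean hierarchical clustering of variables (or samples).

    ``orientation="variables"`` clusters the columns on their z-score
    profiles across samples; ``"samples"`` clusters rows.
    """
    if orientation not in ("variables", "samples"):
        raise ValueError(f"orientation must be 'variables' or 'samples', got {orientation!r}")
    z = zscore_table(table)
    mat = z.T.values if orientation == "variables" else z.values
    labels = tuple(str(c) for c in (table.columns if orientation == "variables" else table.index))
    if len(labels) < 2:
        return LinkageTree(labels=labels, linkage=np.empty((0, 4)))
    link = hierarchy.linkage(mat, method="ward", metric="euclidean")
    return LinkageTree(labels=labels, linkage=link)
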