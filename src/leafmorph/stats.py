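"""Downstream multivariate analysis of epidermal morphometry.

Per-group median descriptor profiles, a Kendall tau-b correlation matrix
across features, PCA of standardized species medians, and agglomerative
clustering on pairwise distances between those medians.

Because the features mix µm, µm² and dimensionless indices, species
medians are z-scored before PCA and clustering by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import kendalltau

from .morphometrics import DESCRIPTOR_COLUMNS

__all__ = [
    "median_profiles",
    "build_species_profiles",
    "kendall_matrix",
    "run_pca",
    "cluster_species",
    "PCAResult",
    "ClusterResult",
]


def median_profiles(
    table: pd.DataFrame,
    features: list[str] | None = None,
    group: str | list[str] = "species",
) -> pd.DataFrame:
    """Median of each feature per group (one row per group).

    Medians follow the usual convention: middle value for odd counts, mean
    of the two middle values for even counts. A feature with no
    observations at all raises an error naming it.
    """
    if features is None:
        features = [c for c in DESCRIPTOR_COLUMNS if c in table.columns]
    missing = [f for f in features if f not in table.columns or table[f].notna().sum() == 0]
    if missing:
        raise ValueError(f"feature(s) entirely missing: {', '.join(missing)}")
    return table.groupby(group, sort=True)[features].median()


def build_species_profiles(
    cells: pd.DataFrame,
    trichome_summaries: pd.DataFrame | None = None,
    descriptors: list[str] | None = None,
) -> pd.DataFrame:
    """Species x feature matrix of medians with side/class-qualified names.

    From the cell table, every descriptor is split by leaf side and cell
    class: pavement-cell features carry only the side suffix (e.g.
    ``CC_ab``), guard-cell features the ``st_`` prefix (e.g. ``st_C_ad``),
    plus stomatal and pavement densities per side when present. A
    per-species trichome summary (columns ``tr_L``, ``tr_D``, ``gtr_L``,
    ``gtr_D``) may be joined in.

    Missing-value policy: densities of absent structures are imputed as 0;
    absent length/shape features stay NaN (excluded pairwise downstream).
    """
    descriptors = descriptors or [c for c in DESCRIPTOR_COLUMNS if c in cells.columns]
    pieces = []
    for (side, cls), grp in cells.groupby(["side", "cell_class"]):
        prefix = "st_" if cls == "stoma" else ""
        med = grp.groupby("species")[descriptors].median()
        med.columns = [f"{prefix}{c}_{side}" for c in med.columns]
        pieces.append(med)
    density_cols = [c for c in cells.columns if c.endswith("_density_per_mm2")]
    for col in density_cols:
        per_side = cells.pivot_table(
            index="species", columns="side", values=col, aggfunc="median"
        )
        per_side.columns = [f"{col.split('_density')[0]}_D_{s}" for s in per_side.columns]
        pieces.append(per_side)
    profile = pd.concat(pieces, axis=1)
    if trichome_summaries is not None and not trichome_summaries.empty:
        profile = profile.join(trichome_summaries, how="outer")
    density_like = [c for c in profile.columns if "_D" in c or c.endswith("_D")]
    profile[density_like] = profile[density_like].fillna(0.0)
    return profile.sort_index()


def kendall_matrix(
    table: pd.DataFrame,
    features: list[str] | None = None,
    level: str = "image",
) -> pd.DataFrame:
    """Kendall tau-b correlation matrix between features.

    ``level`` controls the unit of observation when the table carries
    per-cell rows: "cell" correlates raw rows, "image" (default)
    aggregates to per-image medians first — avoiding pseudo-replication
    while keeping more rows than species — and "species" aggregates to
    species medians. Tau is tie-corrected (tau-b); a constant column has
    undefined tau and is recorded as NaN, not 0.
    """
    if features is None:
        features = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if level not in ("cell", "image", "species"):
        raise ValueError("level must be 'cell', 'image' or 'species'")
    data = table
    if level == "image" and "image_id" in table.columns:
        data = table.groupby("image_id")[features].median()
    elif level == "species" and "species" in table.columns:
        data = table.groupby("species")[features].median()
    if len(data) < 3:
        raise ValueError("need at least 3 rows to correlate")
    k = len(features)
    out = np.full((k, k), np.nan)
    for i in range(k):
        xi = data[features[i]].to_numpy(dtype=float)
        for j in range(i, k):
            xj = data[features[j]].to_numpy(dtype=float)
            ok = np.isfinite(xi) & np.isfinite(xj)
            if ok.sum() < 2 or np.all(xi[ok] == xi[ok][0]) or np.all(xj[ok] == xj[ok][0]):
                tau = 1.0 if i == j else np.nan
            else:
                tau = kendalltau(xi[ok], xj[ok], variant="b").statistic
            out[i, j] = out[j, i] = tau
    return pd.DataFrame(out, index=features, columns=features)


@dataclass
class PCAResult:
    """Loadings, scores and explained-variance fractions."""

    loadings: pd.DataFrame  # feature x component
    scores: pd.DataFrame  # row (species) x component
    variance_fractions: np.ndarray
    mean: np.ndarray
    std: np.ndarray | None


def run_pca(profile: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of a median-profile matrix via covariance eigen-decomposition.

    Features are z-scored by default (mandatory in practice, since the
    descriptor set mixes units); a zero-variance feature is an error
    naming the feature. Sign convention: the largest-magnitude loading of
    every component is made positive. Columns containing NaN are dropped.
    """
    X = profile.dropna(axis=1)
    if len(X) < 2:
        raise ValueError("need at least 2 rows for PCA")
    features = list(X.columns)
    M = X.to_numpy(dtype=float)
    mean = M.mean(axis=0)
    M = M - mean
    std = None
    if standardize:
        std = X.to_numpy(dtype=float).std(axis=0, ddof=1)
        dead = [f for f, s in zip(features, std) if s == 0]
        if dead:
            raise ValueError(f"zero-variance feature(s) under standardization: {', '.join(dead)}")
        M = M / std
    cov = M.T @ M / (len(M) - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] *= -1
    fractions = eigval / eigval.sum() if eigval.sum() > 0 else eigval
    comp_names = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=features, columns=comp_names),
        scores=pd.DataFrame(M @ eigvec, index=X.index, columns=comp_names),
        variance_fractions=fractions,
        mean=mean,
        std=std,
    )


@dataclass
class ClusterResult:
    """Agglomerative clustering of species median profiles."""

    linkage: np.ndarray  # scipy linkage matrix
    names: list[str]
    metric: str
    method: str

    def flat_labels(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.names, (int(v) for v in labels)))

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (branch lengths from merge heights)."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.names[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


SUPPORTED_METRICS = ("euclidean", "cityblock", "cosine", "correlation", "chebyshev")


def cluster_species(
    profile: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
    standardize: bool = True,
) -> ClusterResult:
    """Hierarchical clustering on pairwise distances between species medians.

    Default Euclidean distance on z-scored medians with average linkage.
    Rows are sorted by species name first, so tie-breaking is
    deterministic and independent of input row order.
    """
    if metric not in SUPPORTED_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; supported: {', '.join(SUPPORTED_METRICS)}"
        )
    X = profile.dropna(axis=1).sort_index()
    if len(X) < 2:
        raise ValueError("need at least 2 species to cluster")
    M = X.to_numpy(dtype=float)
    if standardize:
        std = M.std(axis=0, ddof=1)
        keep = std > 0
        M = (M[:, keep] - M[:, keep].mean(axis=0)) / std[keep]
    Z = hierarchy.linkage(pdist(M, metric=metric), method=method)
    return ClusterResult(linkage=Z, names=list(X.index), metric=metric, method=method)
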