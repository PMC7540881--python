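"""Ecological-space analysis of suitability maps.

The available environment (all valid study-area cells) is summarized by a
PCA on standardized variables (the correlation matrix — the variables mix
degrees Celsius, millimetres, metres and indices).  Each group's modelled
niche is projected into that common space as the cloud of cells whose
suitability exceeds a high-probability threshold (default 0.9), summarized by
an inertia ellipse covering 61% of a Gaussian cloud.

Niche overlap between two suitability surfaces uses Schoener's D and the
Hellinger-based I statistic on the maps normalized to probability
distributions; 1 - overlap feeds complete-linkage hierarchical clustering of
the groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import chi2

from .models import SuitabilityMap
from .raster import EnvStack

PROJECTION_THRESHOLD = 0.9
ELLIPSE_COVERAGE = 0.61


@dataclass
class PCAModel:
    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # (n_vars, n_components), orthonormal columns
    eigenvalues: np.ndarray
    explained_variance_fraction: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.means) / self.sds
        return Z @ self.loadings


@dataclass
class ELNCloud:
    group_id: str
    scores: np.ndarray            # (n_cells, n_components)
    empty: bool = False


@dataclass(frozen=True)
class OverlapScores:
    d: float                      # Schoener's D
    i: float                      # Hellinger-based I


@dataclass
class EllipseSpec:
    center: np.ndarray
    covariance: np.ndarray        # 2x2, already scaled to the coverage quantile
    coverage: float = ELLIPSE_COVERAGE

    def contains(self, points: np.ndarray) -> np.ndarray:
        diff = np.asarray(points, float) - self.center
        inv = np.linalg.pinv(self.covariance)
        return np.einsum("ij,jk,ik->i", diff, inv, diff) <= 1.0


def fit_pca(stack: EnvStack, variables: list[str] | None = None) -> PCAModel:
    """PCA of the standardized environment over all valid study-area cells.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so results are reproducible across linear-algebra backends.
    """
    X, _ = stack.to_matrix(variables)
    variables = list(variables) if variables is not None else stack.names
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 valid cells")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    sds = np.where(sds > 0, sds, 1.0)     # constant variables carry no signal
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return PCAModel(
        variables=variables,
        means=means,
        sds=sds,
        loadings=eigvec,
        eigenvalues=eigval,
        explained_variance_fraction=eigval / eigval.sum(),
    )


def project_eln(pca: PCAModel, eln: SuitabilityMap, stack: EnvStack,
                threshold: float = PROJECTION_THRESHOLD) -> ELNCloud:
    """Scores of exactly the cells with suitability strictly above threshold."""
    valid = ~stack.shared_mask
    sel = valid & (eln.values > threshold)
    if not sel.any():
        return ELNCloud(eln.group_id, np.empty((0, len(pca.variables))), empty=True)
    X = np.column_stack([stack[v].values[sel] for v in pca.variables])
    return ELNCloud(eln.group_id, pca.transform(X))


def inertia_ellipse(cloud_scores: np.ndarray, coverage: float = ELLIPSE_COVERAGE,
                    components: tuple[int, int] = (0, 1)) -> EllipseSpec:
    """Inertia ellipse of a 2-D score cloud.

    The sample covariance is scaled by the chi-square(2) quantile at
    ``coverage``, so for Gaussian clouds the ellipse contains about that
    fraction of the points.  ``coverage`` 0 degenerates to the mean point.
    """
    pts = np.asarray(cloud_scores, float)[:, list(components)]
    center = pts.mean(axis=0)
    if coverage <= 0:
        return EllipseSpec(center, np.zeros((2, 2)), coverage)
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in [0, 1)")
    cov = np.cov(pts, rowvar=False, ddof=1)
    scale = chi2.ppf(coverage, df=2)
    return EllipseSpec(center, cov * scale, coverage)


# ---------------------------------------------------------------------------
# Overlap statistics

def _normalized_pair(map1: SuitabilityMap, map2: SuitabilityMap):
    if map1.grid != map2.grid:
        raise ValueError("overlap requires maps on the same grid")
    valid = map1.valid & map2.valid
    p1 = map1.values[valid]
    p2 = map2.values[valid]
    s1, s2 = p1.sum(), p2.sum()
    if s1 <= 0 or s2 <= 0:
        raise ValueError("cannot normalize an all-zero suitability map")
    return p1 / s1, p2 / s2


def schoener_d(map1: SuitabilityMap, map2: SuitabilityMap) -> float:
    """Schoener's D = 1 - 0.5 * sum |p1 - p2| over normalized maps."""
    p1, p2 = _normalized_pair(map1, map2)
    return float(1.0 - 0.5 * np.abs(p1 - p2).sum())


def hellinger_i(map1: SuitabilityMap, map2: SuitabilityMap) -> float:
    """I = 1 - 0.5 * sum (sqrt(p1) - sqrt(p2))^2 over normalized maps."""
    p1, p2 = _normalized_pair(map1, map2)
    return float(1.0 - 0.5 * ((np.sqrt(p1) - np.sqrt(p2)) ** 2).sum())


def overlap_matrix(elns: list[SuitabilityMap]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise (D, I) overlap matrices, symmetric with unit diagonal."""
    ids = [m.group_id for m in elns]
    n = len(elns)
    D = np.eye(n)
    I = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            D[a, b] = D[b, a] = schoener_d(elns[a], elns[b])
            I[a, b] = I[b, a] = hellinger_i(elns[a], elns[b])
    return (pd.DataFrame(D, index=ids, columns=ids),
            pd.DataFrame(I, index=ids, columns=ids))


def dissimilarity(overlap: pd.DataFrame) -> pd.DataFrame:
    """1 - overlap, the distance-like matrix fed to clustering."""
    return 1.0 - overlap


def cluster_niches(dissim: pd.DataFrame) -> np.ndarray:
    """Complete-linkage agglomeration on Euclidean distances between the rows
    of the dissimilarity matrix.  Returns a scipy linkage matrix."""
    rows = np.asarray(dissim, float)
    if rows.shape[0] < 2:
        raise ValueError("clustering needs at least 2 niches")
    with warnings.catch_warnings():
        # the rows of the dissimilarity matrix ARE the feature vectors here;
        # scipy's heuristic warning about uncondensed matrices is expected
        warnings.simplefilter("ignore")
        return linkage(rows, method="complete", metric="euclidean")


def dendrogram_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string (heights as branch
    lengths from parent merge height)."""
    tree = to_tree(link)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"
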