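"""PCA model: scores, loadings, explained variance, plane distances.

The model is fitted by singular value decomposition of the (already
centered) scaled matrix, X = U S P^T. Scores are T = U S (per-strain
coordinates), loadings P have orthonormal columns (per-feature weights),
and component k explains S_k^2/(n-1) of the variance. Only the numerical
rank is retained: after column centering the rank is at most n-1, so a
collection of n strains yields at most n-1 informative components.

Features shared identically by all strains are zeroed by Pareto scaling
and therefore receive loading 0 on every component: common background
ions cannot contribute to variance, which is exactly what makes the
loading distance a triage statistic for strain-unique chemistry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PCAModel",
    "Plane",
    "fit_pca",
    "loading_distance",
    "top_distance_features",
]

_RANK_RTOL = 1e-10  # singular values below this fraction of S1 are noise


@dataclass(frozen=True)
class Plane:
    """A pair of principal components, 1-based as in 'PC13 vs. PC15'."""

    pc_i: int
    pc_j: int

    def __post_init__(self) -> None:
        if self.pc_i == self.pc_j:
            raise ValueError("plane needs two distinct components")
        if self.pc_i < 1 or self.pc_j < 1:
            raise ValueError("component indices are 1-based")

    def as_tuple(self) -> tuple[int, int]:
        return (self.pc_i, self.pc_j)


@dataclass
class PCAModel:
    """Fitted PCA: scores T (n x K), loadings P (p x K), explained variance."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_var: np.ndarray
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    def check_plane(self, plane: Plane) -> None:
        if max(plane.pc_i, plane.pc_j) > self.n_components:
            raise ValueError(
                f"plane {plane.as_tuple()} exceeds the {self.n_components} "
                "retained components"
            )


def fit_pca(X: np.ndarray) -> PCAModel:
    """Fit PCA by SVD of a centered matrix.

    Components are truncated at the numerical rank (singular values above
    1e-10 of the largest). Sign convention: each component is flipped so
    its largest-magnitude loading is positive, making scores and loadings
    reproducible across runs and LAPACK builds.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a matrix with at least 2 rows")
    n = X.shape[0]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S[0] == 0:
        K = 0
        return PCAModel(
            scores=np.zeros((n, 0)),
            loadings=np.zeros((X.shape[1], 0)),
            explained_var=np.zeros(0),
            singular_values=np.zeros(0),
        )
    K = int(np.sum(S > _RANK_RTOL * S[0]))
    U, S, Vt = U[:, :K], S[:K], Vt[:K]
    P = Vt.T
    # deterministic sign: largest |loading| of each component positive
    flip = np.sign(P[np.argmax(np.abs(P), axis=0), np.arange(K)])
    flip[flip == 0] = 1.0
    P = P * flip
    T = (U * S) * flip
    return PCAModel(
        scores=T,
        loadings=P,
        explained_var=S**2 / (n - 1),
        singular_values=S.copy(),
    )


def loading_distance(model: PCAModel, plane: Plane) -> np.ndarray:
    """Euclidean distance of every feature from the origin of a loadings plane.

    Features near 0 sit in the center of the loadings plot and are common
    across strains; large distances mark the features that drive the
    separation visible in that plane's scores plot.
    """
    model.check_plane(plane)
    return np.hypot(
        model.loadings[:, plane.pc_i - 1], model.loadings[:, plane.pc_j - 1]
    )


def top_distance_features(distances: np.ndarray, top_n: int) -> np.ndarray:
    """Indices (0-based) of the ``top_n`` largest distances, descending.

    Ties break toward the lower feature index. If ``top_n`` exceeds the
    number of features, all are returned with a warning.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    d = np.asarray(distances)
    if top_n > d.size:
        warnings.warn(
            f"top_n={top_n} exceeds the {d.size} available features; returning all"
        )
        top_n = d.size
    order = np.lexsort((np.arange(d.size), -d))
    return order[:top_n]
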