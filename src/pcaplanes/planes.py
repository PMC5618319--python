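"""Automated per-strain search for the most separating PC plane.

A strain is discoverable in the plane of two components on which its
score is far from every other strain's score. For each component the
*gap* measures how far the strain stands from the rest; the best plane
pairs the two components with the largest gaps. Scanning all strains at
once yields a gap matrix — a textual equivalent of the per-strain
"scores overview" plot vendors offer, with the selection automated.

Gap metrics
-----------
``nearest_neighbor`` (default)
    min over other strains r of ``|T[s, k] - T[r, k]|``. A strain stands
    out only if it is separated from *all* others; a second outlier on
    the same component collapses the gap, as it should.
``abs_deviation_from_median``
    ``|T[s, k] - median(T[:, k])|``. Cheaper notion of extremeness;
    retained because which of the two a vendor's overview plot reports
    is not documented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pca import PCAModel, Plane

__all__ = [
    "PlaneSelection",
    "component_gap",
    "scores_overview",
    "best_plane",
    "exhaustive_best_plane",
]

GAP_METRICS = ("nearest_neighbor", "abs_deviation_from_median")


@dataclass
class PlaneSelection:
    """The chosen plane for one strain, with its separation gaps."""

    strain_id: str
    plane: Plane
    gap_i: float
    gap_j: float
    all_gaps: np.ndarray

    def __post_init__(self) -> None:
        if self.gap_i < self.gap_j - 1e-15:
            raise ValueError("gap_i must be the larger gap")


def _gap_matrix(scores: np.ndarray, metric: str) -> np.ndarray:
    n = scores.shape[0]
    if n < 2:
        raise ValueError("gap computation needs at least 2 strains")
    if metric == "nearest_neighbor":
        # pairwise |t_s - t_r| per component, min over r != s
        diff = np.abs(scores[:, None, :] - scores[None, :, :])
        diff[np.arange(n), np.arange(n), :] = np.inf
        return diff.min(axis=1)
    if metric == "abs_deviation_from_median":
        return np.abs(scores - np.median(scores, axis=0))
    raise ValueError(f"unknown gap metric {metric!r}; choose from {GAP_METRICS}")


def component_gap(
    model: PCAModel, strain: int, pc: int, metric: str = "nearest_neighbor"
) -> float:
    """Separation gap of one strain on one component (``pc`` is 1-based)."""
    if not 1 <= pc <= model.n_components:
        raise ValueError(f"component {pc} out of range 1..{model.n_components}")
    if not 0 <= strain < model.n_samples:
        raise ValueError(f"strain index {strain} out of range")
    return float(_gap_matrix(model.scores, metric)[strain, pc - 1])


def scores_overview(model: PCAModel, metric: str = "nearest_neighbor") -> np.ndarray:
    """Full gap matrix (n_strains x K): row s holds strain s's gap on every PC."""
    return _gap_matrix(model.scores, metric)


def best_plane(
    model: PCAModel,
    strain: int,
    strain_id: str | None = None,
    metric: str = "nearest_neighbor",
) -> PlaneSelection:
    """Plane of the two components with the largest gaps for this strain.

    Ties break toward the lower component index, favouring the
    higher-variance component. Deterministic.
    """
    if model.n_components < 2:
        raise ValueError("plane search needs at least 2 retained components")
    gaps = _gap_matrix(model.scores, metric)[strain]
    order = np.lexsort((np.arange(gaps.size), -gaps))
    i, j = int(order[0]), int(order[1])
    return PlaneSelection(
        strain_id=strain_id if strain_id is not None else str(strain),
        plane=Plane(pc_i=i + 1, pc_j=j + 1),
        gap_i=float(gaps[i]),
        gap_j=float(gaps[j]),
        all_gaps=gaps,
    )


def exhaustive_best_plane(
    model: PCAModel,
    strain: int,
    strain_id: str | None = None,
    metric: str = "nearest_neighbor",
) -> PlaneSelection:
    """Brute-force search over all K(K-1)/2 planes.

    Ranks a plane by the smaller of its two component gaps (a strain is
    only as separated as its weaker axis), then by the larger gap, then
    by lower component indices. Provided as an alternative mode and as
    the oracle the fast top-2 selection is verified against: the two
    agree by construction whenever gaps are distinct.
    """
    if model.n_components < 2:
        raise ValueError("plane search needs at least 2 retained components")
    gaps = _gap_matrix(model.scores, metric)[strain]
    K = gaps.size
    best_key = None
    best_pair = None
    for a in range(K):
        for b in range(a + 1, K):
            hi, lo = (a, b) if gaps[a] >= gaps[b] else (b, a)
            key = (-min(gaps[a], gaps[b]), -max(gaps[a], gaps[b]), hi, lo)
            if best_key is None or key < best_key:
                best_key, best_pair = key, (hi, lo)
    i, j = best_pair
    return PlaneSelection(
        strain_id=strain_id if strain_id is not None else str(strain),
        plane=Plane(pc_i=i + 1, pc_j=j + 1),
        gap_i=float(gaps[i]),
        gap_j=float(gaps[j]),
        all_gaps=gaps,
    )
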