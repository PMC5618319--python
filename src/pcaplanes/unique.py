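"""Strain-unique feature detection, ranking, and the end-to-end workflow.

Uniqueness is a statement about the bucket table, not about the PCA
model: a feature belongs to a strain when that strain has signal and
every other strain has (at most a tolerated fraction of) none. PCA then
supplies the *ranking* — the loading distance in the strain's best
plane orders unique features by how strongly they drive that strain's
separation — and the plane labels tell the analyst where to look in a
scores/loadings plot.

The full workflow shrinks a table of (potentially hundreds of thousands
of) buckets to a short ranked list per strain:

    replicate averaging -> range filter -> sum normalization ->
    Pareto scaling -> PCA -> per strain: best plane -> unique masses ->
    rank by loading distance -> optional database dereplication
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bucketing import average_replicates
from .derep import AdductRule, CompoundDB, DEFAULT_ADDUCTS, annotate_report
from .pca import PCAModel, fit_pca, loading_distance
from .planes import PlaneSelection, best_plane
from .preprocess import PreprocessParams, preprocess
from .tables import BucketTable, StrainReport, UniqueFeatureRecord

__all__ = [
    "UniquenessParams",
    "WorkflowResult",
    "find_unique",
    "rank_unique",
    "shared_features",
    "run_workflow",
]

logger = logging.getLogger("pcaplanes")


@dataclass(frozen=True)
class UniquenessParams:
    """Uniqueness tolerance and report length.

    alpha : in [0, 1); maximum intensity any *other* strain may carry,
        as a fraction of the owner's intensity. 0 (the default) demands
        strictly exclusive presence; a small alpha tolerates near-zero
        noise buckets.
    top_n : report length per strain (default 60).
    """

    alpha: float = 0.0
    top_n: int = 60

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


def find_unique(
    table: BucketTable, strain: str, params: UniquenessParams | None = None
) -> np.ndarray:
    """0-based indices of features unique to ``strain`` in the raw table.

    Feature f qualifies iff ``table[strain, f] > 0`` and, for every other
    strain r, ``table[r, f] <= alpha * table[strain, f]``. Evaluated on
    the raw (range-filtered, unscaled) table: presence/absence is an
    instrument-level fact that normalization and scaling must not touch.
    """
    if params is None:
        params = UniquenessParams()
    s = table.strain_index(strain)
    own = table.values[s]
    others = np.delete(table.values, s, axis=0)
    if others.shape[0] == 0:
        raise ValueError("uniqueness needs at least 2 strains")
    mask = (own > 0) & (others.max(axis=0) <= params.alpha * own)
    return np.flatnonzero(mask)


def rank_unique(
    model: PCAModel,
    selection: PlaneSelection,
    unique_idx: np.ndarray,
    params: UniquenessParams,
    table: BucketTable,
) -> list[UniqueFeatureRecord]:
    """Order a strain's unique features by loading distance in its plane.

    Descending distance, ties toward the lower feature index, truncated
    to ``top_n``; ranks are 1-based. ``table`` must be the same
    (range-filtered) table the model was fitted to — it supplies the
    (rt, m/z) keys and the owner's raw intensity for the report.
    """
    unique_idx = np.asarray(unique_idx, dtype=int)
    if unique_idx.size == 0:
        return []
    d = loading_distance(model, selection.plane)[unique_idx]
    order = np.lexsort((unique_idx, -d))[: params.top_n]
    s = table.strain_index(selection.strain_id)
    records = []
    for rank, pos in enumerate(order, start=1):
        f = int(unique_idx[pos])
        records.append(
            UniqueFeatureRecord(
                feature=table.features[f],
                strain_id=selection.strain_id,
                plane=selection.plane.as_tuple(),
                distance=float(d[pos]),
                intensity=float(table.values[s, f]),
                rank=rank,
            )
        )
    return records


def shared_features(
    table: BucketTable, min_strains: int = 2, max_strains: int = 3
) -> dict[int, list[str]]:
    """Features present in a small group of strains (2-3 by default).

    Complements the per-strain reports: chemistry shared by a few
    related strains is excluded from every individual report by the
    uniqueness definition, yet can flag an interesting sub-group.
    Returns {feature index: owner strain ids}.
    """
    present = table.values > 0
    counts = present.sum(axis=0)
    out: dict[int, list[str]] = {}
    for f in np.flatnonzero((counts >= min_strains) & (counts <= max_strains)):
        out[int(f)] = [s for i, s in enumerate(table.strain_ids) if present[i, f]]
    return out


@dataclass
class WorkflowResult:
    """Everything the end-to-end run produces.

    reports : one ranked StrainReport per strain (the primary output)
    model : the fitted PCA model
    selections : per-strain plane selections with their gap vectors
    filtered : the range-filtered raw table uniqueness was judged on
    counts : per-stage feature counts (input -> filtered -> unique/strain)
    """

    reports: list[StrainReport]
    model: PCAModel
    selections: list[PlaneSelection]
    filtered: BucketTable
    counts: dict = field(default_factory=dict)


def run_workflow(
    table: BucketTable,
    preprocess_params: PreprocessParams | None = None,
    uniq: UniquenessParams | None = None,
    db: CompoundDB | None = None,
    adducts: list[AdductRule] | None = None,
    tol_ppm: float = 5.0,
    replicate_map: dict[str, str] | None = None,
    gap_metric: str = "nearest_neighbor",
) -> WorkflowResult:
    """Run the whole strain-prioritization workflow on one bucket table.

    Parameters
    ----------
    table : BucketTable
        Raw bucket table (replicate rows allowed with ``replicate_map``).
    preprocess_params, uniq : parameter blocks (defaults as documented).
    db, adducts, tol_ppm : optional compound database for dereplication;
        matched records carry the best hit, unmatched ones are flagged
        as putatively novel.
    replicate_map : replicate row id -> strain id; triggers averaging.
    gap_metric : plane-search gap metric.

    Returns a :class:`WorkflowResult`; ``reports`` holds one ranked
    unique-feature list per strain (empty for strains without unique
    chemistry).
    """
    if preprocess_params is None:
        preprocess_params = PreprocessParams()
    if uniq is None:
        uniq = UniquenessParams()
    counts = {"input_features": table.n_features, "input_rows": table.n_strains}

    if replicate_map is not None:
        table = average_replicates(table, replicate_map)
        counts["strains"] = table.n_strains
    if table.n_strains < 3:
        raise ValueError(
            f"workflow needs at least 3 strains for a meaningful plane search, "
            f"got {table.n_strains}"
        )

    prep = preprocess(table, preprocess_params)
    counts["after_range_filter"] = prep.filtered.n_features
    logger.info(
        "features: %d in, %d after RT %g-%g min / m/z %g-%g filter",
        counts["input_features"], counts["after_range_filter"],
        preprocess_params.rt_min, preprocess_params.rt_max,
        preprocess_params.mz_min, preprocess_params.mz_max,
    )

    model = fit_pca(prep.scaled)
    counts["components"] = model.n_components
    logger.info("PCA: %d strains, %d retained components", table.n_strains, model.n_components)

    if model.n_components < 2:
        # no variance structure to search (e.g. all strains identical):
        # every report is empty by construction
        logger.warning(
            "model has %d component(s); no plane to search, reports are empty",
            model.n_components,
        )
        counts["unique_per_strain"] = {sid: 0 for sid in prep.filtered.strain_ids}
        return WorkflowResult(
            reports=[
                StrainReport(strain_id=sid, plane=(1, 2), records=[])
                for sid in prep.filtered.strain_ids
            ],
            model=model,
            selections=[],
            filtered=prep.filtered,
            counts=counts,
        )

    reports: list[StrainReport] = []
    selections: list[PlaneSelection] = []
    counts["unique_per_strain"] = {}
    for s, sid in enumerate(prep.filtered.strain_ids):
        try:
            sel = best_plane(model, s, strain_id=sid, metric=gap_metric)
            uniq_idx = find_unique(prep.filtered, sid, uniq)
            records = rank_unique(model, sel, uniq_idx, uniq, prep.filtered)
        except Exception as exc:
            raise RuntimeError(f"workflow failed for strain {sid!r}: {exc}") from exc
        counts["unique_per_strain"][sid] = int(uniq_idx.size)
        logger.info(
            "%s: plane PC%d vs PC%d, %d unique features (%d reported)",
            sid, sel.plane.pc_i, sel.plane.pc_j, uniq_idx.size, len(records),
        )
        report = StrainReport(strain_id=sid, plane=sel.plane.as_tuple(), records=records)
        if db is not None:
            report = annotate_report(
                report, db, adducts or list(DEFAULT_ADDUCTS), tol_ppm
            )
        selections.append(sel)
        reports.append(report)
    return WorkflowResult(
        reports=reports, model=model, selections=selections,
        filtered=prep.filtered, counts=counts,
    )
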