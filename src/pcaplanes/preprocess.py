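"""Range filtering, sum normalization and Pareto scaling before PCA.

The preprocessing chain mirrors standard untargeted-metabolomics practice
for strain-collection profiling:

1. keep buckets inside the chromatographically and mass-spectrometrically
   trustworthy window (defaults: RT 2-14 min, m/z 150-1500);
2. divide every analysis row by its own total signal, so strains with
   systematically weaker ionisation (a real phenomenon between strains)
   are comparable;
3. Pareto-scale each bucket column, (x - mean)/sqrt(sd), which centers
   the data and damps the dominance of intense buckets less aggressively
   than unit-variance scaling — appropriate when intensity carries
   information but should not monopolise the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import BucketTable

__all__ = [
    "PreprocessParams",
    "PreprocessResult",
    "filter_ranges",
    "normalize_sum",
    "pareto_scale",
    "preprocess",
]


@dataclass(frozen=True)
class PreprocessParams:
    """Filtering and scaling settings.

    rt window in minutes (default 2-14), m/z window in Th (default
    150-1500); ``normalize`` toggles row-sum normalization; ``scale`` is
    ``"pareto"`` or ``"none"``.
    """

    rt_min: float = 2.0
    rt_max: float = 14.0
    mz_min: float = 150.0
    mz_max: float = 1500.0
    normalize: bool = True
    scale: str = "pareto"

    def __post_init__(self) -> None:
        if not self.rt_min < self.rt_max:
            raise ValueError("rt_min must be < rt_max")
        if not self.mz_min < self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.scale not in ("pareto", "none"):
            raise ValueError(f"unknown scale {self.scale!r}")


def filter_ranges(table: BucketTable, params: PreprocessParams | None = None) -> BucketTable:
    """Keep features with rt and m/z inside the closed parameter windows."""
    if params is None:
        params = PreprocessParams()
    rt, mz = table.rt, table.mz
    mask = (
        (rt >= params.rt_min)
        & (rt <= params.rt_max)
        & (mz >= params.mz_min)
        & (mz <= params.mz_max)
    )
    return table.select_features(mask, note="range_filtered")


def normalize_sum(table: BucketTable) -> BucketTable:
    """Divide each strain row by its own total intensity.

    Every output row sums to 1, removing per-strain differences in
    overall ion yield. Raises if any strain has zero total signal.
    """
    totals = table.values.sum(axis=1)
    zero = [s for s, t in zip(table.strain_ids, totals) if t <= 0]
    if zero:
        raise ValueError(f"cannot sum-normalize all-zero strain row(s): {zero}")
    return BucketTable(
        strain_ids=list(table.strain_ids),
        features=list(table.features),
        values=table.values / totals[:, None],
        meta={**table.meta, "history": table.meta.get("history", []) + ["sum_normalized"]},
    )


def pareto_scale(matrix: np.ndarray) -> np.ndarray:
    """Pareto scaling: per column, (x - mean) / sqrt(sd).

    sd uses the n-1 (sample) denominator. Constant columns are set to
    all-zero rather than dropped, keeping feature indices aligned with
    the source table; such columns carry no variance and are invisible
    to PCA. Output columns have mean 0 and variance equal to the
    pre-scale standard deviation.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("Pareto scaling needs a matrix with at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = np.zeros_like(X)
    nz = sd > 0
    out[:, nz] = (X[:, nz] - mean[nz]) / np.sqrt(sd[nz])
    return out


@dataclass
class PreprocessResult:
    """Output of the full preprocessing chain.

    filtered : range-filtered raw table (uniqueness is judged on this)
    normalized : sum-normalized table (same shape as filtered)
    scaled : Pareto-scaled matrix fed to PCA (same feature order)
    """

    filtered: BucketTable
    normalized: BucketTable
    scaled: np.ndarray


def preprocess(table: BucketTable, params: PreprocessParams | None = None) -> PreprocessResult:
    """Run range filter -> sum normalization -> Pareto scaling."""
    if params is None:
        params = PreprocessParams()
    filtered = filter_ranges(table, params)
    normalized = normalize_sum(filtered) if params.normalize else filtered
    if params.scale == "pareto":
        scaled = pareto_scale(normalized.values)
    else:
        scaled = normalized.values - normalized.values.mean(axis=0)
    return PreprocessResult(filtered=filtered, normalized=normalized, scaled=scaled)
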