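"""Merge per-sample LC-MS feature lists into one bucket table.

Features detected in different runs are the same compound when they agree
in retention time within ``delta_rt`` minutes and in mass within
``delta_ppm`` parts per million. Bucketing sweeps all features from all
samples in ascending m/z order and assigns each to the nearest open bucket
centroid that satisfies both gates, or opens a new bucket. Centroids are
intensity-weighted, so an intense well-measured peak anchors its bucket.

The sweep is deterministic and invariant to the order in which samples or
features are supplied: the input is canonically sorted before processing
and buckets are emitted in (rt, m/z) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import BucketTable, FeatureKey

__all__ = [
    "SampleFeatureList",
    "BucketingParams",
    "bucket_features",
    "average_replicates",
    "read_feature_lists",
]


@dataclass
class SampleFeatureList:
    """Detected features of one analysis: (rt minutes, m/z, intensity)."""

    sample_id: str
    features: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rt, mz, inten in self.features:
            if inten < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: negative intensity at "
                    f"(rt={rt}, mz={mz})"
                )


@dataclass(frozen=True)
class BucketingParams:
    """Tolerances of the bucketing sweep.

    delta_rt : minutes, default 0.33
    delta_ppm : parts per million of m/z, default 4
    """

    delta_rt: float = 0.33
    delta_ppm: float = 4.0

    def __post_init__(self) -> None:
        if not (self.delta_rt > 0 and self.delta_ppm > 0):
            raise ValueError("bucketing tolerances must be positive")


class _Bucket:
    __slots__ = ("mz", "rt", "weight", "count", "cells")

    def __init__(self) -> None:
        self.mz = 0.0  # weighted centroid m/z
        self.rt = 0.0  # weighted centroid rt
        self.weight = 0.0
        self.count = 0
        self.cells: dict[int, float] = {}  # sample index -> summed intensity

    def add(self, rt: float, mz: float, intensity: float, sample: int) -> None:
        # intensity-weighted running centroid; unweighted mean if all
        # member intensities are zero
        w = intensity
        if self.weight + w > 0:
            total = self.weight + w
            self.mz = (self.mz * self.weight + mz * w) / total
            self.rt = (self.rt * self.weight + rt * w) / total
            self.weight = total
        else:
            self.mz = (self.mz * self.count + mz) / (self.count + 1)
            self.rt = (self.rt * self.count + rt) / (self.count + 1)
        self.count += 1
        self.cells[sample] = self.cells.get(sample, 0.0) + intensity


def _ppm(mz_a: float, mz_b: float) -> float:
    return abs(mz_a - mz_b) / ((mz_a + mz_b) / 2.0) * 1e6


def bucket_features(
    samples: list[SampleFeatureList], params: BucketingParams | None = None
) -> BucketTable:
    """Cluster features from all samples into (rt, m/z) buckets.

    Every input feature lands in exactly one bucket; same-sample hits in
    one bucket are summed, so total intensity is conserved. A feature
    joins an existing bucket only if it is within ``delta_ppm`` of the
    bucket's m/z centroid and within ``delta_rt`` of its RT centroid;
    among several admissible buckets it takes the nearest in ppm, ties
    toward the lower-m/z centroid.
    """
    if params is None:
        params = BucketingParams()
    if not samples:
        raise ValueError("need at least one sample")
    sample_ids = sorted({s.sample_id for s in samples})
    if len(sample_ids) != len(samples):
        raise ValueError("duplicate sample ids")
    sample_pos = {sid: i for i, sid in enumerate(sample_ids)}

    # canonical order makes the sweep independent of input order
    rows = sorted(
        (mz, rt, sample_pos[s.sample_id], inten)
        for s in samples
        for (rt, mz, inten) in s.features
    )
    for mz, rt, _samp, inten in rows:
        if inten < 0:
            raise ValueError(f"negative intensity at (rt={rt}, mz={mz})")

    closed: list[_Bucket] = []
    active: list[_Bucket] = []  # ascending centroid m/z
    for mz, rt, samp, inten in rows:
        # retire buckets that no future (sorted) feature can join
        still = []
        for b in active:
            if mz > b.mz and _ppm(mz, b.mz) > params.delta_ppm:
                closed.append(b)
            else:
                still.append(b)
        active = still

        best = None
        best_key = None
        for b in active:
            dppm = _ppm(mz, b.mz)
            if dppm <= params.delta_ppm and abs(rt - b.rt) <= params.delta_rt:
                key = (dppm, b.mz)
                if best is None or key < best_key:
                    best, best_key = b, key
        if best is None:
            best = _Bucket()
            active.append(best)
        best.add(rt, mz, inten, samp)
        active.sort(key=lambda b: b.mz)

    closed.extend(active)
    closed.sort(key=lambda b: (b.rt, b.mz))

    features = [FeatureKey(rt=b.rt, mz=b.mz) for b in closed]
    values = np.zeros((len(sample_ids), len(closed)))
    for j, b in enumerate(closed):
        for i, v in b.cells.items():
            values[i, j] = v
    return BucketTable(
        strain_ids=sample_ids,
        features=features,
        values=values,
        meta={"history": [f"bucketed({params.delta_rt} min, {params.delta_ppm} ppm)"]},
    )


def average_replicates(table: BucketTable, groups: dict[str, str]) -> BucketTable:
    """Collapse replicate rows to one arithmetic-mean row per strain.

    ``groups`` maps every replicate row id to its strain id. Averaging
    happens on the raw bucket table, before normalization and scaling.
    """
    unmapped = [s for s in table.strain_ids if s not in groups]
    if unmapped:
        raise ValueError(f"replicate rows without a group mapping: {unmapped}")
    order: list[str] = list(dict.fromkeys(groups[s] for s in table.strain_ids))
    values = np.vstack(
        [
            table.values[[i for i, s in enumerate(table.strain_ids) if groups[s] == g]].mean(
                axis=0
            )
            for g in order
        ]
    )
    return BucketTable(
        strain_ids=order,
        features=list(table.features),
        values=values,
        meta={**table.meta, "history": table.meta.get("history", []) + ["averaged_replicates"]},
    )


def read_feature_lists(path) -> list[SampleFeatureList]:
    """Read per-sample feature lists from a long CSV.

    Expects columns ``sample, rt, mz, intensity`` (the common MZmine/XCMS
    export shape); one row per detected feature, duplicates allowed.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"sample", "rt", "mz", "intensity"}
    if required - set(df.columns):
        missing = ", ".join(sorted(required - set(df.columns)))
        raise ValueError(f"feature-list csv {path} is missing column(s): {missing}")
    out: dict[str, SampleFeatureList] = {}
    for samp, rt, mz, inten in zip(df["sample"], df["rt"], df["mz"], df["intensity"]):
        sid = str(samp)
        out.setdefault(sid, SampleFeatureList(sample_id=sid, features=[]))
        out[sid].features.append((float(rt), float(mz), float(inten)))
    return list(out.values())
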