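"""Synthetic LC-MS bucket tables and feature lists with known ground truth.

Emulates the structure of a strain-collection profiling experiment:

* a large block of *background* features shared across strains — the
  minor, noise-threshold features that a permissive S/N cutoff lets
  through in their hundreds of thousands on real instruments;
* a handful of *unique* metabolite features per strain — genuine
  chromatographic peaks, orders of magnitude above the noise-level
  background, present in exactly one strain;
* a per-strain global intensity factor (strains genuinely differ in
  overall ion yield, which is what sum normalization corrects);
* optional dropout of background features and optional replicate rows
  with multiplicative measurement noise.

Everything is reproducible from the seed, and the planted truth is
returned alongside the table so recovery can be scored exactly.

What this generator does *not* emulate: chromatographic peak shapes,
isotope envelopes, adduct multiplicity of one compound, RT drift between
runs (beyond the small jitter of :func:`generate_feature_lists`), and
features shared by subsets of strains. Passing tests therefore show the
algorithmic chain is correct, not that any real collection will separate
this cleanly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .bucketing import SampleFeatureList
from .tables import BucketTable, FeatureKey

__all__ = [
    "SynthSpec",
    "SyntheticDataset",
    "generate",
    "generate_feature_lists",
    "write_ground_truth",
]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic strain collection.

    Intensity scales are log-normal (mu, sigma) in log-intensity units:
    background features default to exp(8.5) ~ 5e3 counts with a wide
    spread (noise-threshold features), unique metabolites to
    exp(13.1) ~ 5e5 counts (real peaks, ~100x the noise floor).
    ``strain_intensity_range`` is the uniform range of per-strain global
    ion-yield multipliers. ``noise_cv`` is the coefficient of variation
    of the multiplicative measurement noise applied to every replicate.
    """

    n_strains: int = 20
    n_background: int = 2000
    n_unique_per_strain: int = 5
    background_intensity_lognorm: tuple[float, float] = (math.log(5e3), 1.0)
    unique_intensity_lognorm: tuple[float, float] = (math.log(5e5), 0.5)
    strain_intensity_range: tuple[float, float] = (0.5, 2.0)
    dropout_rate: float = 0.1
    n_replicates: int = 1
    noise_cv: float = 0.05
    rt_range: tuple[float, float] = (2.0, 14.0)
    mz_range: tuple[float, float] = (150.0, 1500.0)
    min_separation_ppm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1 or self.n_background < 0 or self.n_unique_per_strain < 0:
            raise ValueError("counts must be non-negative (n_strains >= 1)")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


@dataclass
class SyntheticDataset:
    """Generated table plus the planted truth.

    table : BucketTable with one row per replicate (per strain when
        ``n_replicates == 1``)
    truth : strain id -> set of planted unique FeatureKeys
    replicate_map : replicate row id -> strain id (None when there is
        one replicate, i.e. rows are strains already)
    """

    table: BucketTable
    truth: dict[str, set[FeatureKey]]
    replicate_map: dict[str, str] | None = None
    background_keys: list[FeatureKey] = field(default_factory=list)


def _draw_keys(rng: np.random.Generator, n: int, spec: SynthSpec) -> list[FeatureKey]:
    """Draw n (rt, mz) keys whose m/z values are mutually >= min_separation_ppm apart."""
    lo, hi = spec.mz_range
    mz = rng.uniform(lo, hi, n)
    for _attempt in range(100):
        order = np.argsort(mz)
        sep = np.diff(mz[order]) / mz[order][:-1] * 1e6
        bad = order[1:][sep < spec.min_separation_ppm]
        if bad.size == 0:
            break
        mz[bad] = rng.uniform(lo, hi, bad.size)
    else:
        raise RuntimeError(
            f"could not draw {n} m/z keys separated by {spec.min_separation_ppm} ppm "
            f"in range {spec.mz_range} after 100 redraws"
        )
    rt = rng.uniform(*spec.rt_range, n)
    return [FeatureKey(rt=float(r), mz=float(m)) for r, m in zip(rt, mz)]


def _noise_sigma(cv: float) -> float:
    # lognormal sigma giving multiplicative noise with the requested CV
    return math.sqrt(math.log(1 + cv**2))


def generate(spec: SynthSpec) -> SyntheticDataset:
    """Generate a bucket table with planted strain-unique features.

    Background intensities are ``base_f x factor_s`` (shared profile
    modulated by strain ion yield), thinned by dropout; unique features
    are nonzero in exactly one strain. Each replicate row multiplies
    every cell by unit-mean log-normal noise with CV ``noise_cv``.
    """
    rng = np.random.default_rng(spec.seed)
    n, B, U = spec.n_strains, spec.n_background, spec.n_unique_per_strain
    strain_ids = [f"S{i+1:02d}" for i in range(n)]
    keys = _draw_keys(rng, B + n * U, spec)
    bg_keys = keys[:B]
    uniq_keys = keys[B:]

    factors = rng.uniform(*spec.strain_intensity_range, n)
    mu_b, sig_b = spec.background_intensity_lognorm
    base = rng.lognormal(mu_b, sig_b, B)
    X = np.outer(factors, base)
    if spec.dropout_rate > 0:
        X[rng.random((n, B)) < spec.dropout_rate] = 0.0

    mu_u, sig_u = spec.unique_intensity_lognorm
    Ublock = np.zeros((n, n * U))
    truth: dict[str, set[FeatureKey]] = {}
    for s, sid in enumerate(strain_ids):
        vals = rng.lognormal(mu_u, sig_u, U) * factors[s]
        Ublock[s, s * U : (s + 1) * U] = vals
        truth[sid] = set(uniq_keys[s * U : (s + 1) * U])
    X = np.hstack([X, Ublock])
    features = bg_keys + uniq_keys

    sig = _noise_sigma(spec.noise_cv)
    if spec.n_replicates == 1:
        rows = X * rng.lognormal(-sig**2 / 2, sig, X.shape) if sig > 0 else X
        row_ids = strain_ids
        rep_map = None
    else:
        blocks, row_ids, rep_map = [], [], {}
        for r in range(spec.n_replicates):
            noise = rng.lognormal(-sig**2 / 2, sig, X.shape) if sig > 0 else 1.0
            blocks.append(X * noise)
        # interleave so rows group by strain: S01_r1, S01_r2, ...
        stacked = np.stack(blocks, axis=1).reshape(n * spec.n_replicates, -1)
        for s, sid in enumerate(strain_ids):
            for r in range(spec.n_replicates):
                rid = f"{sid}_r{r+1}"
                row_ids.append(rid)
                rep_map[rid] = sid
        rows = stacked

    table = BucketTable(
        strain_ids=row_ids,
        features=features,
        values=rows,
        meta={"history": [f"synthetic(seed={spec.seed})"]},
    )
    return SyntheticDataset(
        table=table, truth=truth, replicate_map=rep_map, background_keys=bg_keys
    )


def generate_feature_lists(
    spec: SynthSpec, jitter_ppm: float = 1.0, jitter_rt: float = 0.05
) -> tuple[list[SampleFeatureList], SyntheticDataset]:
    """Per-sample feature lists with small (rt, m/z) measurement jitter.

    Each nonzero bucket of the generated table is emitted in each
    sample's list with uniform jitter of at most ``jitter_rt`` minutes
    and ``jitter_ppm`` ppm. With jitter below half the bucketing
    tolerances and keys drawn ``min_separation_ppm`` apart, bucketing at
    default tolerances reconstructs exactly the true buckets.
    """
    ds = generate(spec)
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x1157)))
    samples = []
    for i, sid in enumerate(ds.table.strain_ids):
        feats = []
        for j, key in enumerate(ds.table.features):
            v = ds.table.values[i, j]
            if v <= 0:
                continue
            rt = key.rt + rng.uniform(-jitter_rt, jitter_rt)
            mz = key.mz * (1 + rng.uniform(-jitter_ppm, jitter_ppm) * 1e-6)
            feats.append((float(rt), float(mz), float(v)))
        samples.append(SampleFeatureList(sample_id=sid, features=feats))
    return samples, ds


def write_ground_truth(ds: SyntheticDataset, path: str | Path) -> Path:
    """Sidecar CSV of the planted truth (strain, rt, mz)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["strain", "rt", "mz"])
        for sid in sorted(ds.truth):
            for key in sorted(ds.truth[sid]):
                w.writerow([sid, repr(key.rt), repr(key.mz)])
    return path
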