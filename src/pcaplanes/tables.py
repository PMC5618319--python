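"""Bucket-table containers and I/O.

A *bucket table* is the wide matrix produced by LC-MS feature bucketing:
rows are strains (or replicate analyses), columns are (retention time, m/z)
buckets, and cells hold summed ion intensities (0 = feature absent). It is
the unit of multivariate analysis for strain prioritization.

Supported on-disk dialects:

``vendor_txt``
    Tab-delimited wide export in the style of vendor profiling software.
    The first column holds analysis names; every other column header
    encodes the bucket's RT (minutes) and m/z, e.g.
    ``Bucket_9.65min_1185.7445mz``. Header decoration varies between
    vendor versions, so the parser extracts the two floats permissively
    (a ``<float>min ... <float>mz`` pair, falling back to the first two
    floats in the header).
``wide_csv``
    Same layout, comma-separated.
``long_csv``
    Tidy table with columns ``sample, rt, mz, intensity`` — the common
    MZmine/XCMS export shape.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKey",
    "BucketTable",
    "UniqueFeatureRecord",
    "StrainReport",
    "clean_labels",
    "read_bucket_table",
    "write_bucket_table",
    "write_report",
    "read_report_csv",
    "TableFormatError",
]

#: Columns of the per-strain report, in output order.
REPORT_COLUMNS = (
    "rank",
    "rt",
    "mz",
    "distance",
    "pc_i",
    "pc_j",
    "intensity",
    "match_name",
    "match_adduct",
    "match_ppm",
    "novel_flag",
)


class TableFormatError(ValueError):
    """Raised when an input file cannot be parsed as a bucket table."""


@dataclass(frozen=True, order=True)
class FeatureKey:
    """Identity of one bucket: retention time (minutes) and m/z (Th)."""

    rt: float
    mz: float

    def __post_init__(self) -> None:
        if not (self.rt > 0 and self.mz > 0):
            raise ValueError(f"FeatureKey requires rt > 0 and mz > 0, got {self}")


@dataclass
class BucketTable:
    """Strains x features intensity matrix with (rt, m/z) feature keys.

    Parameters
    ----------
    strain_ids : list of str
        Row labels; must be unique.
    features : list of FeatureKey
        Column keys; must be unique.
    values : ndarray of shape (n_strains, n_features)
        Non-negative intensities; 0 encodes absence.
    meta : dict
        Provenance: source path, dialect, processing history.
    """

    strain_ids: list[str]
    features: list[FeatureKey]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.strain_ids) or p != len(self.features):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.features)} features"
            )
        if len(set(self.strain_ids)) != n:
            dupes = sorted({s for s in self.strain_ids if self.strain_ids.count(s) > 1})
            raise ValueError(f"duplicate strain ids: {dupes}")
        if len(set(self.features)) != p:
            raise ValueError("duplicate feature keys")
        if self.values.size and self.values.min() < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def rt(self) -> np.ndarray:
        """Retention times of all features, in table order."""
        return np.array([f.rt for f in self.features])

    @property
    def mz(self) -> np.ndarray:
        """m/z values of all features, in table order."""
        return np.array([f.mz for f in self.features])

    def row(self, strain_id: str) -> np.ndarray:
        return self.values[self.strain_index(strain_id)]

    def strain_index(self, strain_id: str) -> int:
        try:
            return self.strain_ids.index(strain_id)
        except ValueError:
            raise KeyError(f"strain {strain_id!r} not in table") from None

    def select_strains(self, strain_ids: Sequence[str]) -> "BucketTable":
        """Sub-table with the given strains, preserving all feature columns."""
        idx = [self.strain_index(s) for s in strain_ids]
        return BucketTable(
            strain_ids=list(strain_ids),
            features=list(self.features),
            values=self.values[idx],
            meta={**self.meta, "history": self.meta.get("history", []) + ["select_strains"]},
        )

    def select_features(self, mask: np.ndarray, note: str = "select_features") -> "BucketTable":
        mask = np.asarray(mask)
        feats = [f for f, keep in zip(self.features, mask) if keep]
        return BucketTable(
            strain_ids=list(self.strain_ids),
            features=feats,
            values=self.values[:, mask],
            meta={**self.meta, "history": self.meta.get("history", []) + [note]},
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame view (index = strains, columns = MultiIndex (rt, mz))."""
        cols = pd.MultiIndex.from_tuples(
            [(f.rt, f.mz) for f in self.features], names=["rt", "mz"]
        )
        return pd.DataFrame(self.values, index=self.strain_ids, columns=cols)


@dataclass
class UniqueFeatureRecord:
    """One ranked strain-unique mass feature."""

    feature: FeatureKey
    strain_id: str
    plane: tuple[int, int]  # 1-based PC indices (pc_i, pc_j)
    distance: float  # Euclidean loading distance in the plane
    intensity: float  # owner's raw bucket intensity
    rank: int  # 1-based
    match_name: str | None = None
    match_adduct: str | None = None
    match_ppm: float | None = None
    novel: bool | None = None


@dataclass
class StrainReport:
    """Ranked unique-feature list for one strain in its best PC plane."""

    strain_id: str
    plane: tuple[int, int]
    records: list[UniqueFeatureRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = [r.distance for r in self.records]
        if any(a < b for a, b in zip(d, d[1:])):
            raise ValueError("report records must be sorted by non-increasing distance")


# ---------------------------------------------------------------------------
# label cleaning

_EXT_RE = re.compile(r"\.[A-Za-z][A-Za-z0-9]{0,9}$")
_NON_ALNUM_RE = re.compile(r"[^A-Za-z0-9]+")


def clean_labels(raw: Iterable[str]) -> list[str]:
    """Clean raw analysis names into readable, unique identifiers.

    Strips directory paths, a trailing file extension and whitespace,
    replaces runs of non-alphanumerics with ``_``, and deduplicates
    repeated names with a numeric suffix (``a``, ``a_2``, ...). Order is
    preserved and the function is total and idempotent.
    """
    out: list[str] = []
    used: set[str] = set()
    seen: dict[str, int] = {}
    for name in raw:
        s = str(name).strip()
        s = s.replace("\\", "/").rsplit("/", 1)[-1]
        s = _EXT_RE.sub("", s)
        s = _NON_ALNUM_RE.sub("_", s).strip("_")
        if not s:
            s = "unnamed"
        count = seen.get(s, 0) + 1
        label = s if count == 1 else f"{s}_{count}"
        while label in used:  # suffixed name may itself collide with a raw name
            count += 1
            label = f"{s}_{count}"
        seen[s] = count
        used.add(label)
        out.append(label)
    return out


# ---------------------------------------------------------------------------
# bucket-table reading

_FLOAT_RE = re.compile(r"[0-9]+(?:\.[0-9]+)?")
_RT_TAG_RE = re.compile(r"([0-9]+(?:\.[0-9]+)?)\s*min", re.IGNORECASE)
_MZ_TAG_RE = re.compile(r"([0-9]+(?:\.[0-9]+)?)\s*(?:mz|m/z|da)", re.IGNORECASE)


def parse_bucket_header(header: str) -> FeatureKey:
    """Extract (rt, mz) from one bucket column header.

    Prefers explicitly unit-tagged values (``...min`` / ``...mz``); falls
    back to the first two floats in the header interpreted as (rt, mz).
    """
    rt_m = _RT_TAG_RE.search(header)
    mz_m = _MZ_TAG_RE.search(header)
    if rt_m and mz_m:
        rt, mz = float(rt_m.group(1)), float(mz_m.group(1))
    else:
        floats = _FLOAT_RE.findall(header)
        if len(floats) < 2:
            raise TableFormatError(
                f"cannot parse bucket header {header!r}: need an RT and an m/z value"
            )
        rt, mz = float(floats[0]), float(floats[1])
    try:
        return FeatureKey(rt=rt, mz=mz)
    except ValueError as exc:
        raise TableFormatError(f"invalid bucket header {header!r}: {exc}") from exc


def _read_wide(path: Path, sep: str, dialect: str) -> BucketTable:
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    features = [parse_bucket_header(str(c)) for c in df.columns]
    if len(set(features)) != len(features):
        raise TableFormatError(f"duplicate bucket keys in header of {path}")
    raw_ids = [str(i) for i in df.index]
    ids = clean_labels(raw_ids)
    if len(set(raw_ids)) != len(raw_ids):
        dupes = sorted({i for i in raw_ids if raw_ids.count(i) > 1})
        raise TableFormatError(f"duplicate strain labels in {path}: {dupes}")
    values = df.to_numpy(dtype=float)
    values = np.nan_to_num(values, nan=0.0)
    meta = {"source": str(path), "dialect": dialect, "history": ["read"]}
    if len(ids) == 0:
        meta["empty"] = True
    return BucketTable(strain_ids=ids, features=features, values=values, meta=meta)


def _read_long(path: Path) -> BucketTable:
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"sample", "rt", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise TableFormatError(
            f"long_csv {path} is missing column(s): {', '.join(sorted(missing))}"
        )
    raw_ids = list(dict.fromkeys(df["sample"].astype(str)))
    ids = clean_labels(raw_ids)
    id_map = dict(zip(raw_ids, ids))
    keys = list(dict.fromkeys(FeatureKey(rt=r, mz=m) for r, m in zip(df["rt"], df["mz"])))
    keys.sort()
    key_pos = {k: j for j, k in enumerate(keys)}
    values = np.zeros((len(ids), len(keys)))
    row_pos = {s: i for i, s in enumerate(ids)}
    for samp, rt, mz, inten in zip(df["sample"], df["rt"], df["mz"], df["intensity"]):
        i = row_pos[id_map[str(samp)]]
        j = key_pos[FeatureKey(rt=rt, mz=mz)]
        values[i, j] += 0.0 if math.isnan(inten) else float(inten)
    meta = {"source": str(path), "dialect": "long_csv", "history": ["read"]}
    if not ids:
        meta["empty"] = True
    return BucketTable(strain_ids=ids, features=keys, values=values, meta=meta)


def read_bucket_table(path: str | Path, dialect: str = "vendor_txt") -> BucketTable:
    """Read a bucket table from disk.

    Parameters
    ----------
    path : path
        Input file.
    dialect : {"vendor_txt", "wide_csv", "long_csv"}
        File layout; see module docstring.

    Missing/NA cells become intensity 0 (the table is dense: a bucket
    absent from an analysis simply means no signal there). Feature order
    is preserved from the file for wide dialects and canonicalised to
    (rt, mz) order for the long dialect.
    """
    path = Path(path)
    if dialect == "vendor_txt":
        return _read_wide(path, sep="\t", dialect=dialect)
    if dialect == "wide_csv":
        return _read_wide(path, sep=",", dialect=dialect)
    if dialect == "long_csv":
        return _read_long(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _format_float(x: float) -> str:
    # repr round-trips exactly through float(); required so 4-ppm mass
    # distinctions survive write/read cycles
    return repr(float(x))


def write_bucket_table(table: BucketTable, path: str | Path, dialect: str = "wide_csv") -> Path:
    """Write a bucket table; the inverse of :func:`read_bucket_table`.

    Values and feature keys are written at full precision so that
    read(write(t)) reproduces the matrix exactly for csv dialects.
    """
    path = Path(path)
    sep = {"vendor_txt": "\t", "wide_csv": ",", "long_csv": None}.get(dialect, "?")
    if sep == "?":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", newline="") as fh:
        if dialect == "long_csv":
            w = csv.writer(fh)
            w.writerow(["sample", "rt", "mz", "intensity"])
            for i, sid in enumerate(table.strain_ids):
                for j, f in enumerate(table.features):
                    w.writerow(
                        [sid, _format_float(f.rt), _format_float(f.mz),
                         _format_float(table.values[i, j])]
                    )
        else:
            w = csv.writer(fh, delimiter=sep)
            headers = [f"Bucket_{_format_float(f.rt)}min_{_format_float(f.mz)}mz"
                       for f in table.features]
            w.writerow(["strain", *headers])
            for i, sid in enumerate(table.strain_ids):
                w.writerow([sid, *(_format_float(v) for v in table.values[i])])
    return path


# ---------------------------------------------------------------------------
# report writing

def _record_row(rec: UniqueFeatureRecord) -> list:
    return [
        rec.rank,
        rec.feature.rt,
        rec.feature.mz,
        rec.distance,
        rec.plane[0],
        rec.plane[1],
        rec.intensity,
        rec.match_name if rec.match_name is not None else "",
        rec.match_adduct if rec.match_adduct is not None else "",
        rec.match_ppm if rec.match_ppm is not None else "",
        "" if rec.novel is None else bool(rec.novel),
    ]


def _sheet_names(strain_ids: Sequence[str]) -> list[str]:
    """Excel sheet names: 31-char truncation with numeric dedup."""
    out: list[str] = []
    seen: dict[str, int] = {}
    for sid in strain_ids:
        name = sid[:31]
        count = seen.get(name, 0) + 1
        seen[name] = count
        if count > 1:
            suffix = f"_{count}"
            name = name[: 31 - len(suffix)] + suffix
            warnings.warn(f"sheet name collision for {sid!r}; using {name!r}")
        out.append(name)
    return out


def write_report(
    reports: Sequence[StrainReport], path: str | Path, format: str = "xlsx"
) -> Path:
    """Write per-strain ranked unique-feature reports.

    ``xlsx``: one workbook, one sheet per strain (sheet names truncated to
    Excel's 31-character limit and deduplicated). ``csv``: one long file
    with a leading ``strain`` column. Floats are written at full precision.
    """
    if not reports:
        raise ValueError("need at least one report")
    path = Path(path)
    if format == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for rep, sheet in zip(reports, _sheet_names([r.strain_id for r in reports])):
                df = pd.DataFrame(
                    [_record_row(r) for r in rep.records], columns=list(REPORT_COLUMNS)
                )
                df.to_excel(writer, sheet_name=sheet, index=False)
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["strain", *REPORT_COLUMNS])
            for rep in reports:
                for rec in rep.records:
                    row = _record_row(rec)
                    row[1:4] = [_format_float(v) for v in row[1:4]]
                    row[6] = _format_float(row[6])
                    if row[9] != "":
                        row[9] = _format_float(row[9])
                    w.writerow([rep.strain_id, *row])
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report_csv(path: str | Path) -> list[StrainReport]:
    """Read back a csv report written by :func:`write_report`."""
    df = pd.read_csv(path, keep_default_na=False)
    reports: list[StrainReport] = []
    for sid in dict.fromkeys(df["strain"].astype(str)):
        sub = df[df["strain"].astype(str) == sid]
        records = []
        for _, r in sub.iterrows():
            records.append(
                UniqueFeatureRecord(
                    feature=FeatureKey(rt=float(r["rt"]), mz=float(r["mz"])),
                    strain_id=sid,
                    plane=(int(r["pc_i"]), int(r["pc_j"])),
                    distance=float(r["distance"]),
                    intensity=float(r["intensity"]),
                    rank=int(r["rank"]),
                    match_name=str(r["match_name"]) or None,
                    match_adduct=str(r["match_adduct"]) or None,
                    match_ppm=float(r["match_ppm"]) if str(r["match_ppm"]) else None,
                    novel=None if str(r["novel_flag"]) == "" else str(r["novel_flag"]) == "True",
                )
            )
        plane = records[0].plane if records else (1, 2)
        reports.append(StrainReport(strain_id=sid, plane=plane, records=records))
    return reports
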