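"""Exact-mass dereplication against a compound database.

Observed ions are converted to neutral monoisotopic masses under a set
of adduct rules (``M = m/z x charge - mass_shift``) and matched against
a mass-sorted database within a ppm tolerance via binary search. A mass
with no hit under any adduct is flagged as putatively novel — the cue
to prioritise that strain for isolation work. The database is a plain
CSV (``name, monoisotopic_mass[, formula]``), so any licensed or public
compound collection can be mounted.

ppm errors are computed relative to the database (theoretical) mass,
the mass-spectrometry convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import StrainReport

__all__ = [
    "PROTON_MASS",
    "AdductRule",
    "DEFAULT_ADDUCTS",
    "KNOWN_ADDUCTS",
    "CompoundDB",
    "MatchResult",
    "neutral_mass",
    "ion_mz",
    "match_mass",
    "annotate_report",
]

#: Mass of a proton in Da.
PROTON_MASS = 1.007276


@dataclass(frozen=True)
class AdductRule:
    """Ion-formation rule: observed m/z = (M + mass_shift) / charge."""

    label: str
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


#: Positive-ESI adducts available by name.
KNOWN_ADDUCTS: dict[str, AdductRule] = {
    "[M+H]+": AdductRule("[M+H]+", PROTON_MASS, 1),
    "[M+Na]+": AdductRule("[M+Na]+", 22.989218, 1),
    "[M+NH4]+": AdductRule("[M+NH4]+", 18.033823, 1),
    "[M+2H]2+": AdductRule("[M+2H]2+", 2 * PROTON_MASS, 2),
}

#: Default adduct set: protonation only (positive ESI).
DEFAULT_ADDUCTS: tuple[AdductRule, ...] = (KNOWN_ADDUCTS["[M+H]+"],)


def neutral_mass(mz: float, adduct: AdductRule) -> float:
    """Neutral monoisotopic mass of the ion ``mz`` under an adduct rule."""
    M = mz * adduct.charge - adduct.mass_shift
    if M <= 0:
        raise ValueError(
            f"m/z {mz} under {adduct.label} gives non-positive neutral mass {M}"
        )
    return M


def ion_mz(neutral: float, adduct: AdductRule) -> float:
    """Observed m/z of a neutral mass under an adduct rule (inverse of neutral_mass)."""
    return (neutral + adduct.mass_shift) / adduct.charge


@dataclass
class CompoundDB:
    """Mass-sorted compound database for exact-mass lookup."""

    names: list[str]
    masses: np.ndarray  # ascending neutral monoisotopic masses, Da
    formulas: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.names) != self.masses.size:
            raise ValueError("names and masses differ in length")
        if not self.formulas:
            self.formulas = [None] * len(self.names)
        if self.masses.size and self.masses.min() <= 0:
            raise ValueError("compound masses must be positive")
        order = np.argsort(self.masses, kind="stable")
        self.masses = self.masses[order]
        self.names = [self.names[i] for i in order]
        self.formulas = [self.formulas[i] for i in order]

    def __len__(self) -> int:
        return self.masses.size

    @classmethod
    def from_csv(cls, path: str | Path) -> "CompoundDB":
        """Load from CSV with columns ``name``, ``monoisotopic_mass`` (or
        ``mass``) and optional ``formula``."""
        df = pd.read_csv(path)
        df.columns = [str(c).strip().lower() for c in df.columns]
        mass_col = next(
            (c for c in ("monoisotopic_mass", "mass", "neutral_mass") if c in df.columns),
            None,
        )
        if "name" not in df.columns or mass_col is None:
            raise ValueError(
                f"compound db {path} needs 'name' and 'monoisotopic_mass' (or 'mass') columns"
            )
        formulas = (
            [None if pd.isna(f) else str(f) for f in df["formula"]]
            if "formula" in df.columns
            else []
        )
        return cls(
            names=[str(n) for n in df["name"]],
            masses=df[mass_col].to_numpy(dtype=float),
            formulas=formulas,
        )


@dataclass
class MatchResult:
    """Database hits for one query ion."""

    query_mz: float
    matches: list[tuple[str, str, float]]  # (compound name, adduct label, ppm error)
    novel: bool

    def best(self) -> tuple[str, str, float] | None:
        return self.matches[0] if self.matches else None


def match_mass(
    mz: float,
    db: CompoundDB,
    adducts: list[AdductRule] | tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
    tol_ppm: float = 5.0,
) -> MatchResult:
    """Match one observed m/z against the database under each adduct.

    Returns all entries whose theoretical mass lies within ``tol_ppm``
    of the query's neutral mass under some adduct, sorted by |ppm error|
    ascending. ``novel`` is True iff nothing matched under any adduct.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if len(db) == 0:
        warnings.warn("empty compound database: every query will be flagged novel")
        return MatchResult(query_mz=mz, matches=[], novel=True)
    hits: list[tuple[float, int, str, str]] = []
    for ai, adduct in enumerate(adducts):
        try:
            M = neutral_mass(mz, adduct)
        except ValueError:
            continue
        # |M_db - M| / M_db <= tol  <=>  M_db in [M/(1+tol), M/(1-tol)]
        tol = tol_ppm * 1e-6
        lo = np.searchsorted(db.masses, M / (1 + tol), side="left")
        hi = np.searchsorted(db.masses, M / (1 - tol), side="right")
        for k in range(lo, hi):
            ppm = (M - db.masses[k]) / db.masses[k] * 1e6
            if abs(ppm) <= tol_ppm:
                hits.append((abs(ppm), ai, db.names[k], adducts[ai].label, ppm))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    matches = [(name, label, ppm) for _, _, name, label, ppm in hits]
    return MatchResult(query_mz=mz, matches=matches, novel=not matches)


def annotate_report(
    report: StrainReport,
    db: CompoundDB,
    adducts: list[AdductRule] | tuple[AdductRule, ...] = DEFAULT_ADDUCTS,
    tol_ppm: float = 5.0,
) -> StrainReport:
    """Attach the best database hit (or a novelty flag) to every record.

    Record order and ranking are unchanged; dereplication annotates, it
    never reorders.
    """
    records = []
    for rec in report.records:
        res = match_mass(rec.feature.mz, db, adducts, tol_ppm)
        best = res.best()
        records.append(
            replace(
                rec,
                match_name=best[0] if best else None,
                match_adduct=best[1] if best else None,
                match_ppm=best[2] if best else None,
                novel=res.novel,
            )
        )
    return StrainReport(strain_id=report.strain_id, plane=report.plane, records=records)
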