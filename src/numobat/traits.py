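"""Morphometric trait tables: reading, validation, derived size indices.

The canonical trait vocabulary covers the linear distances routinely
recorded in myrmecological morphometrics (cephalic length CL, head widths
CW/CWb, eye diameters ELmax/ELmin, scape length SL, spine measurements
SPST/SPWI/SPTI/SPBA, petiole/postpetiole dimensions, hair lengths, ...).
All values are stored internally in micrometres; readers convert
millimetre files on the way in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical trait abbreviations (measured linear distances, μm).
TRAITS: tuple[str, ...] = (
    "CL", "CW", "CWb", "ELmax", "ELmin", "FRS", "ML", "MW", "PEH", "PEW",
    "PHL", "PnHL", "POC", "PPH", "PPW", "SL", "SPBA", "SPH", "SPML",
    "SPST", "SPTI", "SPWI",
)

#: Synonyms seen in print: FR is the frontal-carina distance FRS; HPL is
#: the petiole hair length PHL.
ALIASES: dict[str, str] = {"FR": "FRS", "HPL": "PHL"}

#: Derived columns that are conventions, not measured traits. CS is the
#: arithmetic mean of CL and CWb; EYE the mean of the two eye diameters.
DERIVED: tuple[str, ...] = ("CS", "EYE")

META_COLUMNS: tuple[str, ...] = ("specimen_id", "nest_id", "caste", "species", "locality")

CASTES = ("worker", "gyne")

#: Sanity ceiling for any linear trait of these ants, in μm.
MAX_TRAIT_UM = 5000.0


class TraitTableError(ValueError):
    """Malformed trait table input (missing header, bad caste, ...)."""


class UnitError(TraitTableError):
    """Measurement units could not be established."""


def canonical_trait(name: str) -> str | None:
    """Map a column label to its canonical trait abbreviation, or None."""
    for t in TRAITS + DERIVED:
        if name.strip().lower() == t.lower():
            return t
    for alias, target in ALIASES.items():
        if name.strip().lower() == alias.lower():
            return target
    return None


def compute_cs(cl, cwb):
    """Cephalic size: arithmetic mean of cephalic length and postocular
    head width, in μm.  Inputs must be strictly positive."""
    cl = np.asarray(cl, dtype=float)
    cwb = np.asarray(cwb, dtype=float)
    if np.any(cl[~np.isnan(cl)] <= 0) or np.any(cwb[~np.isnan(cwb)] <= 0):
        raise ValueError("CL and CWb must be strictly positive")
    out = (cl + cwb) / 2.0
    return float(out) if out.ndim == 0 else out


def compute_eye(elmax, elmin):
    """Mean eye diameter (ELmax + ELmin)/2 — a derived convention."""
    elmax = np.asarray(elmax, dtype=float)
    elmin = np.asarray(elmin, dtype=float)
    out = (elmax + elmin) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class TraitTable:
    """Specimens × traits with nest/caste/species metadata, canonical μm.

    ``data`` holds one row per specimen: the metadata columns of
    :data:`META_COLUMNS` (``species``/``locality`` may be absent) followed
    by trait columns. Trait cells may be NaN (missing measurement).
    """

    data: pd.DataFrame
    caste: str
    unknown_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.caste not in CASTES:
            raise TraitTableError(f"caste must be one of {CASTES}, got {self.caste!r}")
        if "specimen_id" not in self.data.columns or "nest_id" not in self.data.columns:
            raise TraitTableError("table needs specimen_id and nest_id columns")
        ids = self.data["specimen_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise TraitTableError(f"duplicate specimen ids: {dupes[:5]}")
        if (self.data["nest_id"].astype(str).str.len() == 0).any():
            raise TraitTableError("empty nest_id")

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c in TRAITS or c in DERIVED]

    @property
    def n(self) -> int:
        return len(self.data)

    def trait_frame(self, traits: Sequence[str] | None = None) -> pd.DataFrame:
        """Numeric trait columns (optionally a subset), μm."""
        cols = list(traits) if traits is not None else self.traits
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise KeyError(f"traits not in table: {missing}")
        return self.data[cols].astype(float)

    def with_derived(self) -> "TraitTable":
        """Return a copy with CS (and EYE where possible) appended."""
        df = self.data.copy()
        if "CS" not in df.columns and {"CL", "CWb"} <= set(df.columns):
            df["CS"] = compute_cs(df["CL"], df["CWb"])
        if "EYE" not in df.columns and {"ELmax", "ELmin"} <= set(df.columns):
            df["EYE"] = compute_eye(df["ELmax"], df["ELmin"])
        return TraitTable(df, self.caste, self.unknown_columns)


def _detect_unit(cl: pd.Series, unit_hint: str) -> float:
    """Return the multiplier to μm (1 or 1000)."""
    if unit_hint == "um":
        return 1.0
    if unit_hint == "mm":
        return 1000.0
    if unit_hint != "auto":
        raise UnitError(f"unknown unit hint {unit_hint!r}")
    med = float(cl.dropna().median()) if cl.notna().any() else np.nan
    if 0.3 <= med <= 3.0:
        return 1000.0
    if 300.0 <= med <= 3000.0:
        return 1.0
    raise UnitError(
        f"cannot infer units: median CL = {med!r} lies in neither the mm "
        "band [0.3, 3] nor the μm band [300, 3000]"
    )


def read_trait_table(
    path: str | Path,
    caste: str | None = None,
    unit_hint: str = "auto",
) -> TraitTable:
    """Read a delimited (or .xlsx) morphometric table into canonical μm.

    The header must name traits by their standard abbreviations
    (case-insensitive; FR→FRS and HPL→PHL aliases accepted) alongside
    ``specimen_id``/``nest_id``/``caste``/optional ``species`` columns.
    Unknown columns are preserved and reported on
    ``TraitTable.unknown_columns``, never silently dropped. Millimetre
    files (detected from median CL, or forced with ``unit_hint``) are
    multiplied by 1000.
    """
    path = Path(path)
    if not path.exists():
        raise TraitTableError(f"no such file: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        try:
            raw = pd.read_csv(path, sep=None, engine="python")
        except Exception as exc:  # noqa: BLE001 - surfaced as format error
            raise TraitTableError(f"cannot parse {path}: {exc}") from exc
    if raw.empty or len(raw.columns) < 2:
        raise TraitTableError(f"{path}: empty table or missing header row")

    meta_map: dict[str, str] = {}
    trait_map: dict[str, str] = {}
    unknown: list[str] = []
    for col in raw.columns:
        low = str(col).strip().lower()
        if low in ("specimen_id", "id", "specimen"):
            meta_map[col] = "specimen_id"
        elif low in ("nest_id", "nest", "sample", "nest_sample"):
            meta_map[col] = "nest_id"
        elif low in META_COLUMNS:
            meta_map[col] = low
        else:
            canon = canonical_trait(str(col))
            if canon is not None:
                trait_map[col] = canon
            else:
                unknown.append(str(col))
    if "specimen_id" not in meta_map.values() or "nest_id" not in meta_map.values():
        raise TraitTableError(f"{path}: header lacks specimen_id/nest_id columns")
    if not trait_map:
        raise TraitTableError(f"{path}: no recognized trait columns in header")

    df = raw.rename(columns={**meta_map, **trait_map})
    for col in trait_map.values():
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TraitTableError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row + 1}"
            )
        df[col] = coerced

    if caste is None:
        if "caste" not in df.columns:
            raise TraitTableError(f"{path}: caste neither in file nor given")
        castes = set(df["caste"].astype(str).str.lower())
        if len(castes) != 1:
            raise TraitTableError(f"{path}: mixed castes {sorted(castes)}")
        caste = castes.pop()
    df["caste"] = caste

    order = TRAITS + DERIVED
    trait_cols = sorted(set(trait_map.values()), key=order.index)
    scale = _detect_unit(df["CL"] if "CL" in df.columns else df[trait_cols[0]], unit_hint)
    df[trait_cols] = df[trait_cols] * scale

    keep = [c for c in META_COLUMNS if c in df.columns] + trait_cols
    out = df[keep].copy()
    out["specimen_id"] = out["specimen_id"].astype(str)
    out["nest_id"] = out["nest_id"].astype(str)
    return TraitTable(out.reset_index(drop=True), caste, tuple(unknown))


def write_trait_table(table: TraitTable, path: str | Path, sep: str = ",") -> Path:
    """Write canonical-μm values; round-trips through read_trait_table."""
    path = Path(path)
    df = table.data.copy()
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    return path


@dataclass
class ValidationReport:
    """Per-record invariant violations; purely observational."""

    violations: list[dict] = field(default_factory=list)
    n_checked: int = 0

    @property
    def ok(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps(
            {"ok": self.ok, "n_checked": self.n_checked, "violations": self.violations},
            indent=2,
        )


def validate_traits(table: TraitTable, max_um: float = MAX_TRAIT_UM) -> ValidationReport:
    """Check trait-vector invariants: positivity, the sanity ceiling,
    ELmin ≤ ELmax and CWb ≤ CW (CW spans the eyes, CWb sits behind them).
    Missing values are ignored; the table is never mutated."""
    report = ValidationReport(n_checked=table.n)
    df = table.data
    for i, row in df.iterrows():
        sid = row["specimen_id"]
        for t in table.traits:
            v = row.get(t)
            if pd.isna(v):
                continue
            if v <= 0:
                report.violations.append(
                    {"specimen_id": sid, "trait": t, "kind": "non_positive", "value": float(v)}
                )
            elif v >= max_um:
                report.violations.append(
                    {"specimen_id": sid, "trait": t, "kind": "above_sanity_bound", "value": float(v)}
                )
        if {"ELmin", "ELmax"} <= set(df.columns):
            lo, hi = row.get("ELmin"), row.get("ELmax")
            if pd.notna(lo) and pd.notna(hi) and lo > hi:
                report.violations.append(
                    {"specimen_id": sid, "trait": "ELmin", "kind": "elmin_gt_elmax",
                     "value": float(lo)}
                )
        if {"CWb", "CW"} <= set(df.columns):
            cwb, cw = row.get("CWb"), row.get("CW")
            if pd.notna(cwb) and pd.notna(cw) and cwb > cw:
                report.violations.append(
                    {"specimen_id": sid, "trait": "CWb", "kind": "cwb_gt_cw", "value": float(cwb)}
                )
    return report


def complete_cases(
    df: pd.DataFrame, traits: Iterable[str]
) -> tuple[pd.DataFrame, int]:
    """Rows complete for ``traits``; returns (subset, n_excluded)."""
    cols = list(traits)
    mask = df[cols].notna().all(axis=1)
    return df.loc[mask], int((~mask).sum())
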