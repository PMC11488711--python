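"""Nest-centroid aggregation, standardization, allometry removal and
species-level ratio summaries.

Nest samples — all specimens from one colony — are the unit of the
exploratory clustering: averaging individuals to their nest centroid
suppresses within-colony measurement and developmental noise. Allometric
size variance is removed by regressing every trait on cephalic length
(CL) pooled over all rows and keeping the residuals. Ratio summaries
report each trait relative to cephalic size CS = (CL+CWb)/2, the
denominator used throughout this literature, with CL/CWb and POC/CL as
their own ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitTable, compute_cs, compute_eye

__all__ = [
    "NestCentroidMatrix",
    "nest_centroids",
    "standardize",
    "remove_allometry",
    "ratio_summary",
    "RATIO_ROWS",
]


@dataclass
class NestCentroidMatrix:
    """Per-nest arithmetic mean trait vectors (μm).

    ``values`` is indexed by nest id; ``n_per_nest`` counts the
    individuals contributing to each nest; ``exclusions`` lists
    (nest, trait) cells with zero usable individuals.
    """

    values: pd.DataFrame
    n_per_nest: pd.Series
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nest_ids(self) -> list[str]:
        return list(self.values.index)


def nest_centroids(table: TraitTable, traits: list[str] | None = None) -> NestCentroidMatrix:
    """Aggregate individuals to nest centroids.

    The centroid of a nest for a trait is the mean over that nest's
    non-missing values; nests with no usable individual for a trait are
    recorded in the exclusion report and left NaN.
    """
    traits = list(traits) if traits is not None else table.traits
    df = table.data
    grouped = df.groupby("nest_id", sort=True)
    values = grouped[traits].mean()
    n_per_nest = grouped.size().rename("n")
    exclusions = [
        (str(nest), str(t))
        for nest, row in values.iterrows()
        for t in traits
        if pd.isna(row[t])
    ]
    if values.empty:
        raise ValueError("no nests to aggregate")
    return NestCentroidMatrix(values, n_per_nest, exclusions)


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """z-score columns (sample SD); returns (z, means, sds) so the same
    transform can be replayed on supplementary rows."""
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    zero = sds[sds == 0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    z = (matrix - means) / sds
    return z, means, sds


@dataclass
class AllometryResult:
    """Residual matrix plus the per-trait OLS fits (trait ~ a + b·CL)."""

    residuals: pd.DataFrame
    fits: pd.DataFrame  # index: trait; columns: intercept, slope, r
    n_excluded: int = 0


def remove_allometry(
    matrix: pd.DataFrame, reference_trait: str = "CL", groups: pd.Series | None = None
) -> AllometryResult:
    """Remove size allometry: OLS-fit every trait on the reference trait
    (CL) pooled over all rows, keep residuals, drop the reference column.

    Rows missing the reference trait are excluded and counted. With
    ``groups`` given, fits are per group instead of pooled (off the
    default path).
    """
    if reference_trait not in matrix.columns:
        raise ValueError(f"reference trait {reference_trait!r} not in matrix")
    usable = matrix[matrix[reference_trait].notna()]
    n_excluded = len(matrix) - len(usable)
    if len(usable) < 3:
        raise ValueError("need at least 3 rows with the reference trait")
    x = usable[reference_trait].to_numpy(dtype=float)
    out = {}
    fits = {}
    for trait in matrix.columns:
        if trait == reference_trait:
            continue
        y = usable[trait].to_numpy(dtype=float)
        if groups is not None:
            resid = np.full_like(y, np.nan)
            g = groups.loc[usable.index]
            for label in g.unique():
                m = (g == label).to_numpy()
                fit = stats.linregress(x[m], y[m])
                resid[m] = y[m] - (fit.intercept + fit.slope * x[m])
            fits[trait] = {"intercept": np.nan, "slope": np.nan, "r": np.nan}
            out[trait] = resid
        else:
            fit = stats.linregress(x, y)
            out[trait] = y - (fit.intercept + fit.slope * x)
            fits[trait] = {"intercept": fit.intercept, "slope": fit.slope, "r": fit.rvalue}
    residuals = pd.DataFrame(out, index=usable.index)
    return AllometryResult(residuals, pd.DataFrame(fits).T, n_excluded)


#: Summary rows in table order: absolute CS first, the two length ratios
#: by their own denominators, then every other trait over CS.
RATIO_ROWS: tuple[str, ...] = (
    "CS", "CL/CWb", "POC/CL", "SL/CL", "FR/CS", "MW/CS", "SPBA/CS",
    "SPWI/CS", "SPTI/CS", "PEW/CS", "PPW/CS", "ML/CS", "SPST/CS",
    "PLST/CS", "PEH/CS", "SPH/CS", "PPH/CS", "EYE/CS",
)

_NUMERATOR = {
    "CL/CWb": ("CL", "CWb"),
    "POC/CL": ("POC", "CL"),
    "SL/CL": ("SL", "CL"),
}


def _ratio_values(df: pd.DataFrame, row: str) -> pd.Series | None:
    """Per-individual value of one summary row, or None if traits absent."""
    if row == "CS":
        if {"CL", "CWb"} <= set(df.columns):
            return pd.Series(compute_cs(df["CL"], df["CWb"]), index=df.index)
        return None
    if row in _NUMERATOR:
        num, den = _NUMERATOR[row]
        if {num, den} <= set(df.columns):
            return df[num] / df[den]
        return None
    trait = row.split("/")[0]
    trait = {"FR": "FRS"}.get(trait, trait)
    if trait == "EYE":
        if {"ELmax", "ELmin", "CL", "CWb"} <= set(df.columns):
            eye = pd.Series(compute_eye(df["ELmax"], df["ELmin"]), index=df.index)
            return eye / compute_cs(df["CL"], df["CWb"])
        if {"EYE", "CL", "CWb"} <= set(df.columns):
            return df["EYE"] / compute_cs(df["CL"], df["CWb"])
        return None
    if {trait, "CL", "CWb"} <= set(df.columns):
        return df[trait] / compute_cs(df["CL"], df["CWb"])
    return None


def shape_ratios(table: TraitTable) -> pd.DataFrame:
    """Per-specimen shape variables: every summary-row ratio that the
    table's traits allow (trait/CS, plus CL/CWb, POC/CL, SL/CL), with
    the nest id carried along.

    Dividing by cephalic size removes the shared size axis exactly, so
    clustering on these variables (via nest means) targets shape
    differences rather than body size.
    """
    df = table.data
    out = {}
    for row in RATIO_ROWS:
        if row == "CS":
            continue
        vals = _ratio_values(df, row)
        if vals is not None:
            out[row] = vals
    ratios = pd.DataFrame(out, index=df.index)
    ratios.insert(0, "nest_id", df["nest_id"])
    return ratios


def nest_shape_centroids(table: TraitTable) -> pd.DataFrame:
    """Nest means of the per-specimen shape ratios."""
    return shape_ratios(table).groupby("nest_id").mean()


def ratio_summary(table: TraitTable) -> pd.DataFrame:
    """Species-level summary in the conventional layout: CS in absolute
    μm, other traits as trait/CS (CL/CWb and POC/CL, SL/CL by their own
    denominators); mean, sample SD, min, max and n per species.

    Denominators are computed per individual. Returns a tidy frame with
    columns species, row, mean, sd, min, max, n.
    """
    df = table.data
    if "species" not in df.columns or df["species"].isna().all():
        raise ValueError("ratio_summary needs species labels")
    records = []
    for species, sub in df.groupby("species", sort=True):
        if sub.empty:
            continue
        for row in RATIO_ROWS:
            vals = _ratio_values(sub, row)
            if vals is None:
                continue
            vals = vals.dropna()
            if vals.empty:
                continue
            records.append(
                {
                    "species": species,
                    "row": row,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame.from_records(records)
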