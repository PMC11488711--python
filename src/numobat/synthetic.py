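"""Synthetic morphometric trait tables with the hierarchical structure
the analysis assumes: species-level clusters, nest-level correlation,
shared-size allometry and individual measurement noise.

Each species is an envelope of a cephalic-size (CS) mean/SD plus
per-trait ratio mean/SDs (trait/CS; CL/CWb, POC/CL and SL/CL by their
own denominators), transcribed from the published worker and gyne
summary tables. For a nest, every ratio gets a nest effect drawn with SD
τ·SD_ratio; an individual draws CS ~ N(CS_mean, CS_SD) and each ratio
adds individual noise with SD σ·SD_ratio, so τ² + σ² = 1 reproduces the
printed total ratio SD. Trait values are ratio × denominator, which
induces size-driven trait correlation without inventing covariances the
tables do not publish. Negative draws are resampled (not truncated) to
keep means unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .traits import TraitTable

__all__ = ["SpeciesEnvelope", "SyntheticSpec", "generate", "preset_corsicus_group"]

#: Default variance split of the printed ratio SD between the nest level
#: (τ) and the individual level (σ); τ² + σ² = 1.
DEFAULT_TAU = 0.5

#: Eye-ellipse convention: ELmax/ELmin emitted as EYE·(1 ± this).
EYE_ELLIPTICITY = 0.15


@dataclass
class SpeciesEnvelope:
    """Per-species generator parameters.

    ``ratios`` maps summary-row names ("CL/CWb", "FR/CS", ...) to
    (mean, sd) in dimensionless units; ``cs_mean``/``cs_sd`` are μm.
    ``slope_dev`` (per ratio) adds departure from isometry: the ratio
    shifts by slope_dev·(CS − CS_mean)/CS_mean.
    """

    name: str
    cs_mean: float
    cs_sd: float
    ratios: dict[str, tuple[float, float]]
    n_nests: int = 10
    individuals_per_nest: int = 3
    slope_dev: dict[str, float] = field(default_factory=dict)
    hair_range_um: tuple[float, float] | None = None


@dataclass
class SyntheticSpec:
    """Full design of one synthetic dataset."""

    caste: str
    species: list[SpeciesEnvelope]
    tau: float = DEFAULT_TAU
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.caste not in ("worker", "gyne"):
            raise ValueError("caste must be 'worker' or 'gyne'")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        for sp in self.species:
            if sp.cs_sd < 0 or any(sd < 0 for _, sd in sp.ratios.values()):
                raise ValueError(f"negative SD in envelope for {sp.name}")
            if sp.n_nests * sp.individuals_per_nest < 1:
                raise ValueError(f"{sp.name}: needs at least one individual")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(1.0 - self.tau**2))

    def to_json(self) -> str:
        import json
        from dataclasses import asdict

        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        import json

        payload = json.loads(text)
        species = [
            SpeciesEnvelope(
                **{**sp, "ratios": {k: tuple(v) for k, v in sp["ratios"].items()},
                   "hair_range_um": tuple(sp["hair_range_um"]) if sp.get("hair_range_um")
                   else None}
            )
            for sp in payload.pop("species")
        ]
        return cls(species=species, **payload)


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> tuple[float, int]:
    """Normal draw resampled until positive; returns (value, resamples)."""
    if sd == 0:
        return mean, 0
    resamples = 0
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return v, resamples
        resamples += 1
        if resamples > 1000:
            raise RuntimeError(f"cannot draw positive value from N({mean}, {sd})")


def generate(spec: SyntheticSpec) -> tuple[TraitTable, pd.DataFrame]:
    """Draw a trait table and its ground truth from a design.

    Returns ``(table, truth)`` where ``truth`` has one row per specimen
    (true species, nest, drawn CS) consistent row-for-row with the
    table. Fixed seed → byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    truth: list[dict] = []
    resample_count = 0
    for sp in spec.species:
        ratio_names = list(sp.ratios)
        for nest_i in range(sp.n_nests):
            nest_id = f"{sp.name}_N{nest_i:02d}"
            nest_effect = {
                r: rng.normal(0.0, spec.tau * sp.ratios[r][1]) for r in ratio_names
            }
            for ind_i in range(sp.individuals_per_nest):
                cs, k = _positive_normal(rng, sp.cs_mean, sp.cs_sd)
                resample_count += k
                ratios = {}
                for r in ratio_names:
                    mean, sd = sp.ratios[r]
                    dev = sp.slope_dev.get(r, 0.0) * (cs - sp.cs_mean) / sp.cs_mean
                    while True:
                        v = mean + nest_effect[r] + rng.normal(0.0, spec.sigma * sd) + dev
                        if v > 0 or (mean == 0 and sd == 0):
                            break
                        resample_count += 1
                    ratios[r] = v
                record = _ratios_to_traits(cs, ratios, rng)
                if sp.hair_range_um is not None:
                    record["PHL"] = rng.uniform(*sp.hair_range_um)
                record.update(
                    specimen_id=f"{nest_id}_I{ind_i}",
                    nest_id=nest_id,
                    caste=spec.caste,
                    species=sp.name,
                )
                rows.append(record)
                truth.append(
                    {
                        "specimen_id": record["specimen_id"],
                        "nest_id": nest_id,
                        "species": sp.name,
                        "cs": cs,
                    }
                )
    df = pd.DataFrame(rows)
    meta = ["specimen_id", "nest_id", "caste", "species"]
    df = df[meta + [c for c in df.columns if c not in meta]]
    table = TraitTable(df, spec.caste)
    truth_df = pd.DataFrame(truth)
    truth_df.attrs["resamples"] = resample_count
    return table, truth_df


def _ratios_to_traits(
    cs: float, ratios: dict[str, float], rng: np.random.Generator
) -> dict[str, float]:
    """Convert one individual's drawn CS + summary-row ratios to μm traits.

    CL and CWb come from CS and the CL/CWb ratio (CS is their mean);
    POC and SL scale on CL; every other row scales on CS. The EYE row is
    split into ELmax/ELmin with an individually jittered ellipticity
    (exact collinearity between the two diameters would be an artifact
    no measured dataset shows), and CW spans the eyes so it sits above
    CWb by a jittered fraction of the eye bulge.
    """
    out: dict[str, float] = {}
    r_head = ratios.get("CL/CWb", 1.2)
    cl = 2.0 * cs * r_head / (1.0 + r_head)
    cwb = 2.0 * cs / (1.0 + r_head)
    out["CL"], out["CWb"] = cl, cwb
    for row, value in ratios.items():
        if row in ("CL/CWb",):
            continue
        if row == "POC/CL":
            out["POC"] = value * cl
        elif row == "SL/CL":
            out["SL"] = value * cl
        elif row == "EYE/CS":
            eye = value * cs
            ell = EYE_ELLIPTICITY + rng.normal(0.0, 0.02)
            out["ELmax"] = eye * (1.0 + ell)
            out["ELmin"] = eye * (1.0 - ell)
        else:
            trait = row.split("/")[0]
            trait = {"FR": "FRS"}.get(trait, trait)
            out[trait] = value * cs
    # CW must not undercut CWb (it spans the eyes): widen by the eye bulge.
    if "ELmax" in out:
        out["CW"] = cwb + (0.3 + abs(rng.normal(0.0, 0.04))) * out["ELmax"]
    return out


def _load_envelopes(caste: str) -> pd.DataFrame:
    fname = f"ratio_envelopes_{caste}.csv"
    with resources.files("numobat.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


#: Published petiole-hair ranges usable as optional generator envelopes.
_HAIR_RANGES = {
    ("worker", "kraussei"): (125.0, 147.0),
    ("worker", "algerianus"): (85.0, 130.0),
    ("worker", "ravouxi"): (88.0, 124.0),
    ("gyne", "kraussei"): (140.0, 175.0),
    ("gyne", "algerianus"): (125.0, 145.0),
}


def preset_corsicus_group(
    caste: str,
    n_nests: int = 10,
    individuals_per_nest: int = 3,
    tau: float = DEFAULT_TAU,
    seed: int | None = None,
    include_singletons: bool = False,
    with_hair: bool = False,
) -> SyntheticSpec:
    """Envelopes transcribed from the published ratio tables.

    Gynes: 9 species; workers: 6 multi-sample species (the single
    holotype-only vector joins as an optional singleton with zero SDs).
    """
    env = _load_envelopes(caste)
    species: list[SpeciesEnvelope] = []
    for name, sub in env.groupby("species", sort=True):
        sub = sub.set_index("row")
        singleton = int(sub["n"].iloc[0]) == 1
        if singleton and not include_singletons:
            continue
        cs_mean = float(sub.loc["CS", "mean"])
        cs_sd = float(sub.loc["CS", "sd"]) if not singleton else 0.0
        ratios = {
            row: (float(r["mean"]), float(r["sd"]) if not singleton else 0.0)
            for row, r in sub.iterrows()
            if row != "CS"
        }
        species.append(
            SpeciesEnvelope(
                name=str(name),
                cs_mean=cs_mean,
                cs_sd=cs_sd,
                ratios=ratios,
                n_nests=1 if singleton else n_nests,
                individuals_per_nest=1 if singleton else individuals_per_nest,
                hair_range_um=_HAIR_RANGES.get((caste, str(name))) if with_hair else None,
            )
        )
    return SyntheticSpec(caste=caste, species=species, tau=tau, seed=seed)
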