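"""Species identification for the *Temnothorax corsicus* group: the
published discriminant scorers and the dichotomous keys.

Three published linear discriminant functions separate the look-alike
pairs on raw μm trait values; their coefficients are shipped verbatim
and never re-fit (re-fitting belongs to :mod:`numobat.discriminant`):

* D5a (gynes):  +0.047·CW −0.073·FR −0.035·SPWI −0.018·ML +0.057·SPST
  +2.974; positive → *T. adlerzi*, negative → *T. ravouxi*.
* D3 (gynes):   +0.117·ELmax −0.046·SL +0.038·SPH −9.973; negative →
  *T. algerianus*, positive → *T. ravouxi*.
* D5b (workers): +0.029·SL +0.080·SPBA −0.070·PPW −0.045·SPH
  −0.056·ELmax +5.703; positive → *T. algerianus*, negative →
  *T. ravouxi*.

The dichotomous keys for gynes and workers are encoded couplet by
couplet, including the strict petiole-hair splits (>140 μm in gynes,
>125 μm in workers → *T. kraussei*) and the coarse geographic couplets.
Missing characters yield a multi-species call listing every reachable
leaf rather than a guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Scorer",
    "D5A", "D3", "D5B",
    "score_D5a", "score_D3", "score_D5b",
    "KeyObservation", "Identification", "run_key",
    "HAIR_ENVELOPES_UM",
]


class Region(str, Enum):
    CANARY_ISLANDS = "canary_islands"
    NORTH_AFRICA_SOUTH_SPAIN = "north_africa_south_spain"
    NORTH_SPAIN_TO_TURKIYE = "north_spain_to_turkiye"
    PONTIC_MEDITERRANEAN = "pontic_mediterranean"
    KAZAKHSTAN = "kazakhstan"


class FronsSculpture(str, Enum):
    SHINY_SMOOTH = "shiny_smooth"
    SHINY_FEEBLY_COSTULATE = "shiny_feebly_costulate"
    DULL_AREOLATE = "dull_areolate"


class ClypeusMargin(str, Enum):
    FLAT = "flat"
    CONVEX = "convex"


class PropodeumContour(str, Enum):
    STRAIGHT = "straight"
    CONVEX = "convex"


@dataclass(frozen=True)
class Scorer:
    """A published linear discriminant: score = Σ coef·trait + intercept.

    Group statistics (score mean, [min, max] range and n over the
    original reference material) are shipped as printed so an evaluated
    score can be annotated in-range or out-of-range.
    """

    name: str
    caste: str
    coefficients: dict[str, float]
    intercept: float
    positive_species: str
    negative_species: str
    group_stats: dict[str, dict]

    def score(self, traits_um: dict[str, float]) -> float:
        missing = [t for t in self.coefficients if traits_um.get(t) is None
                   or (isinstance(traits_um.get(t), float) and np.isnan(traits_um[t]))]
        if missing:
            raise ValueError(f"{self.name}: missing trait(s) {missing}")
        values = {t: float(traits_um[t]) for t in self.coefficients}
        if all(0 < v < 5 for v in values.values()):
            raise ValueError(
                f"{self.name}: inputs look like millimetres (all < 5); supply μm"
            )
        return float(sum(c * values[t] for t, c in self.coefficients.items())
                     + self.intercept)

    def call(self, traits_um: dict[str, float]) -> tuple[float, str, str]:
        """Return (score, species call, range note)."""
        s = self.score(traits_um)
        species = self.positive_species if s > 0 else self.negative_species
        lo, hi = self.group_stats[species]["range"]
        note = "in-range" if lo <= s <= hi else (
            f"out-of-range: {s:+.3f} outside printed [{lo:+.3f}, {hi:+.3f}] for {species}"
        )
        return s, species, note


D5A = Scorer(
    name="D5a",
    caste="gyne",
    coefficients={"CW": 0.047, "FR": -0.073, "SPWI": -0.035, "ML": -0.018, "SPST": 0.057},
    intercept=2.974,
    positive_species="adlerzi",
    negative_species="ravouxi",
    group_stats={
        "adlerzi": {"mean": 1.699, "range": (-0.160, 3.894), "n": 17},
        "ravouxi": {"mean": -1.699, "range": (-4.064, 1.113), "n": 110},
    },
)

D3 = Scorer(
    name="D3",
    caste="gyne",
    coefficients={"ELmax": 0.117, "SL": -0.046, "SPH": 0.038},
    intercept=-9.973,
    positive_species="ravouxi",
    negative_species="algerianus",
    group_stats={
        "algerianus": {"mean": -1.882, "range": (-3.857, 1.046), "n": 34},
        "ravouxi": {"mean": 1.882, "range": (-1.082, 5.154), "n": 113},
    },
)

D5B = Scorer(
    name="D5b",
    caste="worker",
    coefficients={"SL": 0.029, "SPBA": 0.080, "PPW": -0.070, "SPH": -0.045, "ELmax": -0.056},
    intercept=5.703,
    positive_species="algerianus",
    negative_species="ravouxi",
    group_stats={
        "algerianus": {"mean": 1.673, "range": (-0.747, 3.250), "n": 45},
        "ravouxi": {"mean": -1.673, "range": (-4.500, 0.595), "n": 173},
    },
)

SCORERS = {"D5a": D5A, "D3": D3, "D5b": D5B}


def score_D5a(CW: float, FR: float, SPWI: float, ML: float, SPST: float):
    """Gyne separator *T. adlerzi* (positive) vs *T. ravouxi* (negative)."""
    return D5A.call({"CW": CW, "FR": FR, "SPWI": SPWI, "ML": ML, "SPST": SPST})


def score_D3(ELmax: float, SL: float, SPH: float):
    """Gyne separator *T. algerianus* (negative) vs *T. ravouxi* (positive)."""
    return D3.call({"ELmax": ELmax, "SL": SL, "SPH": SPH})


def score_D5b(SL: float, SPBA: float, PPW: float, SPH: float, ELmax: float):
    """Worker separator *T. algerianus* (positive) vs *T. ravouxi* (negative)."""
    return D5B.call({"SL": SL, "SPBA": SPBA, "PPW": PPW, "SPH": SPH, "ELmax": ELmax})


#: Published petiole-hair length envelopes, μm (typical + [min, max]).
HAIR_ENVELOPES_UM = {
    ("worker", "kraussei"): {"typical_exceeds": 130.0, "range": (125.0, 147.0)},
    ("worker", "algerianus"): {"range": (85.0, 130.0)},
    ("worker", "ravouxi"): {"range": (88.0, 124.0)},
    ("gyne", "kraussei"): {"range": (140.0, 175.0)},
    ("gyne", "algerianus"): {"range": (125.0, 145.0)},
}

#: Strict key thresholds for the longest erect petiole hair, μm.
HAIR_THRESHOLD_UM = {"gyne": 140.0, "worker": 125.0}


@dataclass
class KeyObservation:
    """Characters a user can read off a specimen for the keys.

    Qualitative states and the region token are optional — absent
    characters make the traversal branch into every reachable leaf.
    ``traits`` (μm) are only consulted when a leaf refers to one of the
    published discriminant functions.
    """

    caste: str
    funiculus_segments: int | None = None
    clypeus_margin: str | None = None
    frons_sculpture: str | None = None
    propodeum_dorsal_contour: str | None = None
    petiole_hair_max: float | None = None
    region: str | None = None
    traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.caste not in ("worker", "gyne"):
            raise ValueError("caste must be 'worker' or 'gyne'")
        if self.funiculus_segments is not None and self.funiculus_segments not in (10, 11):
            raise ValueError("funiculus_segments must be 10 or 11")
        if self.petiole_hair_max is not None and self.petiole_hair_max <= 0:
            raise ValueError("petiole_hair_max must be > 0 μm")


@dataclass
class Identification:
    """Outcome of a key traversal: candidate species, the couplet path
    taken, any discriminant scores computed, and confidence notes."""

    species: list[str]
    path: list[str] = field(default_factory=list)
    scores: dict[str, dict] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    @property
    def unambiguous(self) -> bool:
        return len(self.species) == 1

    def to_json_dict(self) -> dict:
        return {
            "species": self.species,
            "unambiguous": self.unambiguous,
            "path": self.path,
            "scores": self.scores,
            "notes": self.notes,
        }


def _hair_note(caste: str, species: str, hair: float | None) -> str | None:
    env = HAIR_ENVELOPES_UM.get((caste, species))
    if env is None or hair is None:
        return None
    lo, hi = env["range"]
    if not lo <= hair <= hi:
        return (
            f"petiole hair {hair:g} μm out of the published {species} "
            f"{caste} envelope [{lo:g}, {hi:g}] μm"
        )
    return None

def _hair_note(caste: str, species: str, hair: float | None) -> str | None:
    env = HAIR_ENVELOPES_UM.get((caste, species))
    if env is None or hair is None:
        return None
    lo, hi = env["range"]
    if not lo <= hair <= hi:
        return (
            f"petiole hair {hair:g} μm out of the published {species} "
            f"{caste} envelope [{lo:g}, {hi:g}] μm"
        )
    return None


class _Traversal:
    """Mutable state while walking the couplets of one key."""

    def __init__(self, obs: KeyObservation) -> None:
        self.obs = obs
        self.ident = Identification(species=[])
        self.reached: list[str] = []

    def leaf(self, name: str, path_note: str) -> None:
        if name not in self.reached:
            self.reached.append(name)
        self.ident.path.append(path_note)

    def step(self, path_note: str) -> None:
        self.ident.path.append(path_note)

    def note(self, text: str) -> None:
        if text and text not in self.ident.notes:
            self.ident.notes.append(text)

    def try_scorer(self, scorer: Scorer, pair: tuple[str, str]) -> None:
        """Run a discriminant scorer on the observation's traits; on
        success replace the ambiguous pair by the scored call."""
        traits = dict(self.obs.traits)
        if "FR" in scorer.coefficients and "FR" not in traits and "FRS" in traits:
            traits["FR"] = traits["FRS"]
        try:
            s, species, range_note = scorer.call(traits)
        except ValueError as exc:
            self.note(f"{scorer.name} not computed: {exc}")
            return
        self.ident.scores[scorer.name] = {
            "score": s, "call": species, "note": range_note,
        }
        if range_note != "in-range":
            self.note(f"{scorer.name} {range_note}")
        for name in pair:
            if name != species and name in self.reached:
                self.reached.remove(name)
        self.step(f"{scorer.name} = {s:+.3f} → {species}")


def run_key(obs: KeyObservation) -> Identification:
    """Traverse the printed dichotomous key for the observation's caste.

    The traversal follows the couplets exactly. A couplet whose
    character is missing explores both branches, so the final call lists
    every reachable species. The hair-length couplets are strict
    (>140 μm gynes, >125 μm workers → *T. kraussei*); exact equality
    routes to the "else" branch with a borderline warning, since the
    printed couplets use strict inequalities in both directions.
    Contradictory observations produce an ambiguity note, not a crash.
    """
    t = _Traversal(obs)
    if obs.caste == "gyne":
        _gyne_key(t)
    else:
        _worker_key(t)
    t.ident.species = t.reached
    if len(t.reached) != 1:
        t.note(f"ambiguous: {len(t.reached)} species reachable with the characters given")
    return t.ident


def _gyne_key(t: _Traversal) -> None:
    obs = t.obs
    if obs.region == Region.CANARY_ISLANDS.value:
        t.leaf("birgitae", "1a endemic to the Canary Islands → birgitae")
        if obs.funiculus_segments == 11:
            t.note(
                "contradiction: funiculus 11-segmented conflicts with the Canary "
                "endemic branch (couplet 1a); both readings reported"
            )
            t.step("2a funiculus 11 → 3 (contradictory branch)")
            t.leaf("microcellatus", "3 pontic-mediterranean → microcellatus")
        return
    if obs.region is None:
        t.leaf("birgitae", "1a? region unknown → birgitae reachable")
    t.step("1b out of the Canary Islands, West Palearctic → 2")
    if obs.funiculus_segments in (11, None):
        t.step("2a funiculus 11-segmented → 3")
        if obs.region in (Region.PONTIC_MEDITERRANEAN.value, None):
            t.leaf("microcellatus", "3 pontic-mediterranean → microcellatus")
        if obs.region in (Region.KAZAKHSTAN.value, None):
            t.leaf("gordiagini", "3 Kazakhstan (type locality) → gordiagini")
            t.note("gordiagini: gyne unknown; recorded from the type locality only")
    if obs.funiculus_segments in (10, None):
        t.step("2b funiculus 10-segmented → 4")
        if obs.clypeus_margin in (ClypeusMargin.FLAT.value, None):
            t.leaf("stumperi", "4a anterior clypeus margin flat → stumperi")
        if obs.clypeus_margin in (ClypeusMargin.CONVEX.value, None):
            t.step("4b anterior clypeus margin evenly convex → 5")
            if obs.frons_sculpture in (FronsSculpture.SHINY_SMOOTH.value, None):
                t.leaf("bernardi", "6a frons extensively smooth, shiny → bernardi")
            if obs.frons_sculpture in (FronsSculpture.SHINY_FEEBLY_COSTULATE.value, None):
                t.leaf("corsicus", "6b frons medially shiny, feebly costulate → corsicus")
            if obs.frons_sculpture in (FronsSculpture.DULL_AREOLATE.value, None):
                t.step("5b frons dull, ground sculpture areolate → 7")
                _hair_couplet(t, threshold=HAIR_THRESHOLD_UM["gyne"], couplet="7",
                              else_branch=_gyne_couplet8)


def _gyne_couplet8(t: _Traversal) -> None:
    obs = t.obs
    if obs.region in (Region.NORTH_AFRICA_SOUTH_SPAIN.value, None):
        t.leaf("algerianus", "8a North Africa, South Spain → algerianus")
        t.note(_hair_note("gyne", "algerianus", obs.petiole_hair_max) or "")
    if obs.region in (Region.NORTH_SPAIN_TO_TURKIYE.value, None):
        t.leaf("adlerzi", "8b North Spain to Türkiye → adlerzi, ravouxi "
                          "(safe separation: differential diagnosis, D5a)")
        t.leaf("ravouxi", "8b North Spain to Türkiye → adlerzi, ravouxi")
        if obs.traits:
            t.try_scorer(D5A, ("adlerzi", "ravouxi"))


def _worker_key(t: _Traversal) -> None:
    obs = t.obs
    if obs.funiculus_segments in (11, None):
        t.step("1a funiculus 11-segmented → 2")
        if obs.propodeum_dorsal_contour in (PropodeumContour.STRAIGHT.value, None):
            t.leaf("gordiagini", "2a propodeum dorsal contour straight in profile → gordiagini")
        if obs.propodeum_dorsal_contour in (PropodeumContour.CONVEX.value, None):
            t.leaf("microcellatus", "2b propodeum dorsal contour convex in profile → microcellatus")
    if obs.funiculus_segments in (10, None):
        t.step("1b funiculus 10-segmented → 3")
        if obs.clypeus_margin in (ClypeusMargin.FLAT.value, None):
            t.leaf("stumperi", "3a anterior clypeus margin straight → stumperi")
        if obs.clypeus_margin in (ClypeusMargin.CONVEX.value, None):
            t.step("3b anterior clypeus margin convex → 4")
            if obs.frons_sculpture in (
                FronsSculpture.SHINY_SMOOTH.value,
                FronsSculpture.SHINY_FEEBLY_COSTULATE.value,
                None,
            ):
                t.leaf("bernardi", "4a frons shiny, sculpture absent or feebly areolate → bernardi")
            if obs.frons_sculpture in (FronsSculpture.DULL_AREOLATE.value, None):
                t.step("4b frons dull, ground sculpture areolate → 5")
                _hair_couplet(t, threshold=HAIR_THRESHOLD_UM["worker"], couplet="5",
                              else_branch=_worker_couplet6)


def _worker_couplet6(t: _Traversal) -> None:
    obs = t.obs
    if obs.region in (Region.NORTH_AFRICA_SOUTH_SPAIN.value, None):
        t.leaf("algerianus", "6a North Africa, South Spain → algerianus")
        t.note(_hair_note("worker", "algerianus", obs.petiole_hair_max) or "")
    if obs.region in (Region.NORTH_SPAIN_TO_TURKIYE.value, None):
        t.leaf("ravouxi", "6b North Spain to Türkiye → ravouxi")
        t.note(_hair_note("worker", "ravouxi", obs.petiole_hair_max) or "")
        if obs.region is not None and obs.traits:
            t.try_scorer(D5B, ("algerianus", "ravouxi"))


def _hair_couplet(t: _Traversal, threshold: float, couplet: str, else_branch) -> None:
    """The strict petiole-hair split to *T. kraussei*."""
    obs = t.obs
    hair = obs.petiole_hair_max
    caste = obs.caste
    if hair is None:
        t.leaf("kraussei", f"{couplet}? petiole hair unknown → kraussei reachable")
        else_branch(t)
        return
    if hair > threshold:
        t.leaf("kraussei",
               f"{couplet}a longest erect petiole hair {hair:g} > {threshold:g} μm → kraussei")
        t.note(_hair_note(caste, "kraussei", hair) or "")
        return
    if hair == threshold:
        t.note(
            f"borderline: petiole hair exactly {threshold:g} μm; the printed couplets "
            "use strict inequalities in both directions"
        )
    t.step(f"{couplet}b longest erect petiole hair {hair:g} < {threshold:g} μm → next")
    else_branch(t)
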