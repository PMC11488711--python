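"""Reusable simulation studies: parameter recovery of the delimitation
workflow on synthetic data drawn from the published envelopes.

These are the package's benchmark experiments. The worker study asks
whether recursive two-engine partitioning of nest shape centroids
recovers the six multi-sample worker species; the gyne study asks
whether LOOCV-LDA on individual gynes reproduces high classification
accuracy for the nine gyne species. Both are driven by explicit seeds
and scaled by arguments so callers (tests, acceptance, analysis
scripts) state their own problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clustering, discriminant, preprocess, synthetic

__all__ = ["worker_recovery_study", "gyne_loocv_study", "RecoveryStudy"]


@dataclass
class RecoveryStudy:
    """Per-seed outcomes of the worker clustering recovery study."""

    records: pd.DataFrame
    n_species: int = 6
    ari_threshold: float = 0.95

    @property
    def success_fraction(self) -> float:
        """Fraction of seeds with both engines at the true k and ARI vs
        ground truth at least the threshold."""
        ok = (
            (self.records["k_hierarchical"] == self.n_species)
            & (self.records["k_kmeans"] == self.n_species)
            & (self.records[["ari_hierarchical", "ari_kmeans"]].min(axis=1)
               >= self.ari_threshold)
        )
        return float(ok.mean())

    @property
    def consensus_fraction(self) -> float:
        """Fraction of seeds where the relaxed consensus accepted the
        partition at the true k."""
        ok = self.records["consensus_accepted"] & (
            self.records["k_consensus"] == self.n_species
        )
        return float(ok.mean())


def _single_worker_recovery(seed: int, B: int, tau: float,
                            n_nests: int, individuals_per_nest: int) -> dict:
    spec = synthetic.preset_corsicus_group(
        "worker", n_nests=n_nests, individuals_per_nest=individuals_per_nest,
        tau=tau, seed=seed,
    )
    table, _ = synthetic.generate(spec)
    cent = preprocess.nest_shape_centroids(table).dropna(axis=1, how="any")
    z, _, _ = preprocess.standardize(cent)
    truth = table.data.groupby("nest_id")["species"].first().loc[z.index]

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)]
    parts = {}
    rec: dict = {"seed": seed}
    for engine, eng_seed in zip(("hierarchical", "kmeans"), seeds):
        p = clustering.part(z, engine=engine, B=B, min_size=5, seed=eng_seed)
        parts[engine] = p
        mask = p.labels != 0
        rec[f"k_{engine}"] = p.k
        rec[f"ari_{engine}"] = (
            adjusted_rand_score(truth[mask], p.labels[mask]) if mask.any() else 0.0
        )
    verdict = clustering.consensus(parts["hierarchical"], parts["kmeans"], strict=False)
    rec["consensus_accepted"] = verdict.accepted
    rec["k_consensus"] = verdict.k_a if verdict.accepted else 0
    return rec


def worker_recovery_study(
    n_seeds: int = 50,
    B: int = 100,
    tau: float = synthetic.DEFAULT_TAU,
    n_nests: int = 10,
    individuals_per_nest: int = 3,
    base_seed: int = 0,
) -> RecoveryStudy:
    """Clustering recovery across seeds on the worker preset.

    Each seed draws a fresh dataset (6 multi-sample species × n_nests ×
    individuals_per_nest), clusters standardized nest shape centroids
    with both engines and records k, ARI versus the generating labels,
    and the consensus verdict.
    """
    rows = [
        _single_worker_recovery(base_seed + i, B, tau, n_nests, individuals_per_nest)
        for i in range(n_seeds)
    ]
    return RecoveryStudy(pd.DataFrame(rows))


def gyne_loocv_study(
    seed: int = 0,
    tau: float = synthetic.DEFAULT_TAU,
    n_nests: int = 10,
    individuals_per_nest: int = 3,
) -> discriminant.ConfusionMatrix:
    """LOOCV-LDA confusion matrix for one draw of the gyne preset
    (9 species), classifying individual gynes on all complete traits."""
    spec = synthetic.preset_corsicus_group(
        "gyne", n_nests=n_nests, individuals_per_nest=individuals_per_nest,
        tau=tau, seed=seed,
    )
    table, _ = synthetic.generate(spec)
    df = table.data
    traits = [t for t in table.traits if df[t].notna().all()]
    return discriminant.loocv_confusion(df[traits], df["species"])
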