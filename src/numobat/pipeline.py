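"""End-to-end orchestration of the delimitation workflow.

read → validate → nest centroids → (standardize) → recursive
partitioning under both engines → consensus → LOOCV-LDA on the accepted
partition → artifacts (Newick dendrogram, partition/consensus JSON,
confusion CSV/JSON, ratio summary). Consensus rejection is an analytic
outcome, not a failure: both partitions are still written and the run
reports a distinct status.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import clustering, discriminant, preprocess
from .traits import TraitTable, read_trait_table, validate_traits

log = logging.getLogger("numobat")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

#: Exit-status taxonomy: analytic outcomes are not failures.
STATUS_OK = 0
STATUS_DATA_ERROR = 2
STATUS_CONFIG_ERROR = 3
STATUS_CONSENSUS_REJECTED = 4


@dataclass
class PipelineConfig:
    """Everything a run needs; defaults follow the published protocol
    (B = 1000 bootstrap references, minimum cluster size 5)."""

    input_path: str | None = None
    caste: str | None = None
    unit_hint: str = "auto"
    traits: list[str] | None = None
    standardize: bool = True
    shape_ratios: bool = True  # cluster nest means of trait/CS shape ratios
    remove_allometry: bool = False
    B: int = 1000
    min_size: int = 5
    kmax: int = 8
    seed: int = 0
    consensus_strict: bool = True
    ari_threshold: float = 0.95
    equal_priors: bool = True
    out_dir: str = "numobat_run"

    def validate(self) -> None:
        if self.B < 1 or self.min_size < 1 or self.kmax < 2:
            raise ValueError("need B ≥ 1, min_size ≥ 1, kmax ≥ 2")
        if self.unit_hint not in ("um", "mm", "auto"):
            raise ValueError("unit_hint must be um, mm or auto")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    status: int
    out_dir: Path
    verdict: clustering.ConsensusVerdict | None = None
    confusion: discriminant.ConfusionMatrix | None = None
    artifacts: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: PipelineConfig, table: TraitTable | None = None) -> PipelineResult:
    """Run the whole workflow; ``table`` may be passed directly instead
    of ``config.input_path``. All randomness flows from ``config.seed``
    via named substreams per stage. A run log is written alongside the
    artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_pipeline(config, table, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_pipeline(
    config: PipelineConfig, table: TraitTable | None, out: Path
) -> PipelineResult:

    if table is None:
        if not config.input_path:
            raise ValueError("need input_path or an in-memory table")
        table = read_trait_table(config.input_path, config.caste, config.unit_hint)

    report = validate_traits(table)
    (out / "validation.json").write_text(report.to_json())
    if not report.ok:
        log.warning("validation flagged %d violations", len(report.violations))

    traits = config.traits or table.traits
    if config.shape_ratios and {"CL", "CWb"} <= set(table.data.columns):
        # size-corrected delimitation: cluster nest means of trait/CS
        centroid_values = preprocess.nest_shape_centroids(table)
    else:
        centroid_values = preprocess.nest_centroids(table, traits).values
    usable = centroid_values.dropna(axis=1, how="any")
    dropped = sorted(set(centroid_values.columns) - set(usable.columns))
    if dropped:
        log.info("dropping traits with missing centroids: %s", dropped)
    if usable.shape[1] < 2 or len(usable) < config.min_size:
        raise ValueError("too few complete centroid columns or nests")

    matrix = usable
    if config.standardize:
        matrix, _, _ = preprocess.standardize(usable)
    if config.remove_allometry and "CL" in usable.columns:
        matrix = preprocess.remove_allometry(usable).residuals
        if config.standardize:
            matrix, _, _ = preprocess.standardize(matrix)

    dist = pd.DataFrame(
        squareform(pdist(matrix.to_numpy())), index=matrix.index, columns=matrix.index
    )
    tree = clustering.upgma(dist)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")

    # independent seed substreams per engine
    ss = np.random.SeedSequence(config.seed)
    seed_h, seed_k = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    part_h = clustering.part(
        matrix, engine="hierarchical", B=config.B, min_size=config.min_size,
        kmax=config.kmax, seed=seed_h,
    )
    part_k = clustering.part(
        matrix, engine="kmeans", B=config.B, min_size=config.min_size,
        kmax=config.kmax, seed=seed_k,
    )
    verdict = clustering.consensus(
        part_h, part_k, strict=config.consensus_strict, ari_threshold=config.ari_threshold
    )
    (out / "partition_hierarchical.json").write_text(json.dumps(part_h.to_json_dict(), indent=2))
    (out / "partition_kmeans.json").write_text(json.dumps(part_k.to_json_dict(), indent=2))
    (out / "consensus.json").write_text(json.dumps(verdict.to_json_dict(), indent=2))

    result = PipelineResult(STATUS_OK, out, verdict=verdict)
    result.artifacts = {
        "dendrogram": "dendrogram.nwk",
        "consensus": "consensus.json",
        "validation": "validation.json",
    }

    if "species" in table.data.columns and table.data["species"].notna().all():
        summary = preprocess.ratio_summary(table)
        summary.to_csv(out / "ratio_summary.csv", index=False)
        result.artifacts["ratio_summary"] = "ratio_summary.csv"

    if not verdict.accepted:
        result.status = STATUS_CONSENSUS_REJECTED
        _write_manifest(config, result)
        return result

    # LOOCV-LDA on individuals labelled by their nest's accepted cluster
    labels_by_nest = verdict.merged_labels
    ind = table.data.copy()
    ind["cluster"] = ind["nest_id"].map(labels_by_nest)
    ind = ind[ind["cluster"].notna() & (ind["cluster"] != 0)]
    use_cols = [c for c in traits if c in ind.columns and ind[c].notna().all()]
    X = ind[use_cols].dropna()
    labels = ind.loc[X.index, "cluster"].astype(int)
    if labels.value_counts().min() >= 3 and labels.nunique() >= 2:
        confusion = discriminant.loocv_confusion(X, labels)
        confusion.counts.to_csv(out / "loocv_confusion.csv")
        (out / "loocv_confusion.json").write_text(
            json.dumps(confusion.to_json_dict(), indent=2)
        )
        result.confusion = confusion
        result.artifacts["loocv_confusion"] = "loocv_confusion.csv"
    _write_manifest(config, result)
    return result


def _write_manifest(config: PipelineConfig, result: PipelineResult) -> None:
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "status": result.status,
        "artifacts": result.artifacts,
    }
    if result.verdict is not None:
        manifest["consensus"] = {
            "accepted": result.verdict.accepted,
            "k_hierarchical": result.verdict.k_a,
            "k_kmeans": result.verdict.k_b,
            "ari": result.verdict.ari,
        }
    if result.confusion is not None:
        manifest["loocv"] = {
            "accuracy": result.confusion.accuracy,
            "ci": [result.confusion.ci_lower, result.confusion.ci_upper],
        }
    (result.out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
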