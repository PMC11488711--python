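"""Exploratory species hypothesis for the simulated workers:
nest-centroid UPGMA dendrogram, recursive gap-statistic partitioning
under both engines, and the consensus verdict, with ARI against the
generating species."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from numobat import clustering, preprocess
from numobat.traits import read_trait_table

OUT = Path(__file__).resolve().parents[1] / "results"

table = read_trait_table(OUT / "synthetic_worker.csv")
centroids = preprocess.nest_shape_centroids(table).dropna(axis=1, how="any")
z, _, _ = preprocess.standardize(centroids)
truth = table.data.groupby("nest_id")["species"].first().loc[z.index]

dist = pd.DataFrame(squareform(pdist(z.to_numpy())), index=z.index, columns=z.index)
tree = clustering.upgma(dist)
(OUT / "worker_nc_dendrogram.nwk").write_text(tree.to_newick() + "\n")

parts = {}
for engine, seed in (("hierarchical", 11), ("kmeans", 12)):
    p = clustering.part(z, engine=engine, B=1000, min_size=5, seed=seed)
    parts[engine] = p
    mask = p.labels != 0
    ari = adjusted_rand_score(truth[mask], p.labels[mask])
    print(f"{engine}: k = {p.k}, ARI vs generating species = {ari:.3f}")
    (OUT / f"worker_partition_{engine}.json").write_text(
        json.dumps(p.to_json_dict(), indent=2)
    )

verdict = clustering.consensus(parts["hierarchical"], parts["kmeans"], strict=False)
(OUT / "worker_consensus.json").write_text(json.dumps(verdict.to_json_dict(), indent=2))
print(
    f"consensus: accepted={verdict.accepted} (k_hclust={verdict.k_a}, "
    f"k_kmeans={verdict.k_b}, between-engine ARI={verdict.ari:.3f}) "
    "→ results/worker_consensus.json"
)
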