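import numpy as np
import pandas as pd
import pytest

from numobat.traits import TraitTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def tiny_worker_table() -> TraitTable:
    """Three nests, five specimens, two traits; values in μm."""
    df = pd.DataFrame(
        {
            "specimen_id": ["a", "b", "c", "d", "e"],
            "nest_id": ["n1", "n1", "n2", "n2", "n3"],
            "caste": "worker",
            "species": ["sp1", "sp1", "sp1", "sp1", "sp2"],
            "CL": [600.0, 620.0, 700.0, 710.0, 650.0],
            "CWb": [500.0, 510.0, 560.0, 570.0, 530.0],
        }
    )
    return TraitTable(df, "worker")


def make_table(n_nests=4, per_nest=3, traits=("CL", "CWb", "ML", "SL"),
               seed=7, caste="worker", species="spX") -> TraitTable:
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_nests):
        for j in range(per_nest):
            base = {"CL": 650, "CWb": 540, "ML": 780, "SL": 450}
            rows.append(
                {
                    "specimen_id": f"n{i}_i{j}",
                    "nest_id": f"n{i}",
                    "caste": caste,
                    "species": species,
                    **{t: base.get(t, 400) + rng.normal(0, 15) for t in traits},
                }
            )
    return TraitTable(pd.DataFrame(rows), caste)
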