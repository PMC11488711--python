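"""Published reference tables shipped with the package.

Two kinds of published numbers ride along as data files: the
species-level ratio envelopes (mean ± SD per summary row) that
parameterize the synthetic generator, and the published LOOCV confusion
matrices, usable as worked inputs for the accuracy machinery. They are
inputs, never re-derived.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["printed_ratio_envelopes", "printed_confusion"]


def _read(fname: str, **kw) -> pd.DataFrame:
    with resources.files("numobat.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh, **kw)


def printed_ratio_envelopes(caste: str) -> pd.DataFrame:
    """Published per-species ratio summary (columns: species, n, row,
    mean, sd) for 'worker' or 'gyne'."""
    if caste not in ("worker", "gyne"):
        raise ValueError("caste must be 'worker' or 'gyne'")
    return _read(f"ratio_envelopes_{caste}.csv")


def printed_confusion(caste: str) -> pd.DataFrame:
    """Published LOOCV-LDA confusion matrix (true × predicted counts)."""
    if caste not in ("worker", "gyne"):
        raise ValueError("caste must be 'worker' or 'gyne'")
    return _read(f"loocv_confusion_{caste}.csv", index_col=0)
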