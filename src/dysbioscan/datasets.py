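"""Packaged worked-example data."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_synthetic_score_table"]


def load_synthetic_score_table() -> pd.DataFrame:
    """The 23-subject lysophospholipid rank-order score worked example.

    SYNTHETIC stand-in: the original per-subject score list is published
    only as a figure, so this table was constructed to satisfy every printed
    summary statistic of that cohort exactly — 12 healthy controls and 11
    Crohn's-disease cases, totals consistent with a five-species panel
    ranked 1..23 (grand sum 1380 = 5 x 276), Mann-Whitney AUC 0.7992,
    a 100%-specificity cutoff of 78 points attained by a case, and 6 of 11
    cases (54.5%) at or above it.  It is a worked example for the scoring
    arithmetic, not patient data.

    Returns a DataFrame indexed by sample id with ``group`` ("HC"/"CD") and
    ``total_score`` columns.
    """
    ref = resources.files("dysbioscan.data") / "lysophospholipid_scores_synthetic.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col=0)
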