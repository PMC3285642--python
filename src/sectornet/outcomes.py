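"""Collaboration outcome indices built from binary survey items.

Three unweighted item-sum indices per member: community activities (4 items,
0-4), grants and publications (3 items, 0-3), and policy engagement
(2 items, 0-2).  Items are strictly binary and complete for every respondent;
anything else is a hard error rather than an imputation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import OUTCOME_ITEM_GROUPS, OutcomeItems

INDEX_NAMES = tuple(OUTCOME_ITEM_GROUPS)
INDEX_MAXIMA = {name: len(items) for name, items in OUTCOME_ITEM_GROUPS.items()}


def build_indices(items: OutcomeItems) -> pd.DataFrame:
    """Row-wise item sums: one integer index column per outcome.

    Validation (0/1 items, completeness) happens when ``OutcomeItems`` is
    constructed, so here the sums are plain arithmetic.
    """
    out = pd.DataFrame({"member_id": list(items.member_ids)})
    for name, cols in OUTCOME_ITEM_GROUPS.items():
        out[name] = items.table[list(cols)].sum(axis=1).astype(np.int64)
    return out


def summarize_outcomes(indices: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Mean and SD per index (population SD by default), with the index range."""
    rows = []
    for name in INDEX_NAMES:
        col = indices[name]
        rows.append(
            {
                "index": name,
                "n_items": INDEX_MAXIMA[name],
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=ddof)),
            }
        )
    return pd.DataFrame(rows)
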