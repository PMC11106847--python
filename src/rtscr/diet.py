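"""Diet composition statistics from spraint-prey incidence tables.

Each spraint (fecal sample) is scored for the prey categories it contains and
the minimum number of prey individuals per category (from diagnostic hard
parts).  Importance of a category is summarized by N (summed minimum counts),
FO (% of spraints containing it) and RFO (% of all prey occurrences).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["diet_stats", "read_spraints"]


def diet_stats(incidence: pd.DataFrame) -> pd.DataFrame:
    """Diet table from long-form spraint records (spraint_id, category, min_count).

    For category c over S spraints:
        N_c   = sum of minimum prey counts
        FO_c  = 100 * (# spraints containing c) / S
        RFO_c = 100 * occurrences_c / total occurrences
    A category counts once per spraint as an occurrence regardless of its
    minimum count within that spraint, so RFO sums to 100 (up to rounding).
    Full precision is retained; round for display.
    """
    req = {"spraint_id", "category", "min_count"}
    if not req.issubset(incidence.columns):
        raise ValueError(f"incidence table needs columns {sorted(req)}")
    if len(incidence) == 0:
        raise ValueError("empty incidence table")
    if (incidence["min_count"] < 0).any():
        raise ValueError("min_count must be non-negative")
    present = incidence[incidence["min_count"] > 0]
    n_spraints = incidence["spraint_id"].nunique()
    occ = present.groupby("category")["spraint_id"].nunique()
    n = present.groupby("category")["min_count"].sum()
    total_occ = int(occ.sum())
    out = pd.DataFrame(
        {
            "N": n,
            "occurrences": occ,
            "FO": 100.0 * occ / n_spraints,
            "RFO": 100.0 * occ / total_occ,
        }
    )
    out.index.name = "category"
    out.attrs["n_spraints"] = int(n_spraints)
    out.attrs["total_occurrences"] = total_occ
    return out


def read_spraints(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"spraint_id", "category", "min_count"} - set(df.columns)
    if missing:
        raise ValueError(f"spraint CSV missing columns: {sorted(missing)}")
    return df
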