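"""Descriptive summaries: cohort table, outcome quintiles, centred log-ratio
bar data, and ternary plot coordinates.

The quintile bar data mirror a standard CoDA display: within each quintile of
an outcome, the log of each part's geometric mean relative to the overall
geometric mean, centred across the five categories so that per part the bars
sum to zero.  A positive bar marks a quintile whose relative mean of that
fatty acid sits above the overall mean composition.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .composition import close

__all__ = [
    "summary_table",
    "quintile_assign",
    "quintile_clr_bars",
    "amalgamate",
    "ternary_coords",
]

_COUNT_COLUMNS = ("sex", "physical_activity", "single_parent", "screen_time", "siblings")


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD per numeric column (SD with divisor N-1); counts (%) for
    binary/ordinal covariates."""
    if table.empty:
        raise ValueError("empty table")
    rows = []
    for col in table.columns:
        x = table[col].dropna()
        if col in _COUNT_COLUMNS:
            # report count (%) of the modal/affirmative level for binaries,
            # mean +/- SD for ordinals alongside the level counts
            counts = x.value_counts().sort_index()
            for level, cnt in counts.items():
                rows.append({
                    "variable": col, "statistic": f"count[{level:g}]",
                    "value": float(cnt), "pct": 100.0 * cnt / len(x), "n": len(x),
                })
        else:
            rows.append({
                "variable": col, "statistic": "mean", "value": float(x.mean()),
                "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0, "n": len(x),
            })
    return pd.DataFrame(rows)


def quintile_assign(values) -> np.ndarray:
    """Quintile category 1..5 with cuts at the 20/40/60/80 percentiles.

    Values exactly at a cut point go to the lower category.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ValueError("need a 1-D vector with at least 5 values")
    if np.ptp(x) == 0:
        raise ValueError("all values equal: quintiles undefined")
    cuts = np.percentile(x, [20, 40, 60, 80])
    return 1 + (x[:, None] > cuts[None, :]).sum(axis=1)


def quintile_clr_bars(
    table: pd.DataFrame,
    outcome: str,
    parts: Sequence[str],
    part_suffix: str = "_pct",
) -> pd.DataFrame:
    """Centred log-ratio bar heights per outcome quintile.

    For quintile q and part f: ``ln(gm_q(f) / gm_all(f))``, then centred by
    subtracting each part's mean across the five quintiles.  Returns a 5×D
    frame (rows quintile 1..5, columns parts); each column sums to zero.
    """
    cols = [f"{p}{part_suffix}" for p in parts]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing part columns: {missing}")
    sub = table.dropna(subset=cols + [outcome])
    X = sub[cols].to_numpy(dtype=float)
    if np.any(X <= 0):
        raise ValueError("non-positive part values")
    q = quintile_assign(sub[outcome].to_numpy())
    logX = np.log(X)
    overall = logX.mean(axis=0)
    heights = np.empty((5, len(parts)))
    for k in range(1, 6):
        mask = q == k
        if not mask.any():
            raise ValueError(f"empty quintile category {k}")
        heights[k - 1] = logX[mask].mean(axis=0) - overall
    heights -= heights.mean(axis=0, keepdims=True)
    return pd.DataFrame(heights, index=pd.RangeIndex(1, 6, name="quintile"),
                        columns=list(parts))


def amalgamate(sample, parts: Sequence[str], merge: Sequence[str],
               merged_label: str | None = None) -> tuple[np.ndarray, list[str]]:
    """Sum a group of parts into one, returning the reduced sample and labels.

    Amalgamation (summing raw parts) precedes closure; because closure is a
    rescaling, the two operations commute.
    """
    arr = np.atleast_2d(np.asarray(sample, dtype=float))
    parts = list(parts)
    idx = [parts.index(p) for p in merge]
    if len(idx) < 2:
        raise ValueError("amalgamation needs at least 2 parts")
    keep = [i for i in range(len(parts)) if i not in idx]
    merged = arr[:, idx].sum(axis=1, keepdims=True)
    out = np.hstack([arr[:, keep], merged])
    labels = [parts[i] for i in keep] + [merged_label or "+".join(merge)]
    return out, labels


def ternary_coords(sub) -> np.ndarray:
    """Barycentric (x, y) plot coordinates for 3-part compositions.

    For parts (a, b, c): ``x = (2b + c) / (2(a+b+c))``,
    ``y = sqrt(3)/2 * c / (a+b+c)``.  Vertex a maps to (0, 0), b to (1, 0),
    c (the triangle top) to (1/2, sqrt(3)/2).
    """
    arr = np.atleast_2d(np.asarray(sub, dtype=float))
    if arr.shape[1] != 3:
        raise ValueError(
            "ternary coordinates need exactly 3 parts; amalgamate a pair first"
        )
    if np.any(arr <= 0):
        raise ValueError("non-positive part values")
    arr = close(arr, kappa=1.0)
    a, b, c = arr[:, 0], arr[:, 1], arr[:, 2]
    xy = np.column_stack([0.5 * (2 * b + c), (np.sqrt(3) / 2) * c])
    return xy if np.asarray(sub).ndim == 2 else xy[0]
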