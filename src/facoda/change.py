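"""Reallocation change matrices.

Around a reference (mean) composition, move a fixed number of percentage
points ``delta`` from one part to another and predict the outcome change
implied by a fitted compositional model:

    d_eta = a . (clr(x') - clr(x_bar))

where ``a`` are the clr-space coefficients.  For outcomes modelled on the
natural-log scale the entry is the multiplicative ratio ``exp(d_eta)``;
otherwise it is the additive difference.  Entries are indexed
``M[to, from]`` — row: the part receiving the delta, column: the donor.

``delta`` is in absolute percentage points of the closed composition (a
"compositional 4 %" moves 4 points of the 100 % total, not 4 % of the donor
part).  Donor parts smaller than ``delta`` leave no valid reallocation; such
entries are NaN and listed in the result's metadata.  Reallocations that
leave a donor part below ``extrapolation_floor`` remain defined but are
flagged as extreme extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .composition import clr, close, reallocate

__all__ = ["ChangeMatrix", "change_matrix"]


@dataclass
class ChangeMatrix:
    """D×D predicted outcome changes for pairwise delta-point reallocation."""

    outcome: str
    kind: str  # "difference" or "ratio"
    delta: float
    parts: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    undefined: list[tuple[str, str]] = field(default_factory=list)
    extrapolated: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Rows: receiving part ('to'); columns: donor part ('from')."""
        return pd.DataFrame(self.values, index=list(self.parts),
                            columns=list(self.parts))

    def __getitem__(self, key: tuple[str, str]) -> float:
        to, frm = key
        return float(self.values[self.parts.index(to), self.parts.index(frm)])


def change_matrix(
    clr_coefs,
    mean_composition,
    parts: Sequence[str],
    delta: float = 4.0,
    kind: str = "difference",
    outcome: str = "",
    extrapolation_floor: float = 1.0,
    close_mean: bool = True,
) -> ChangeMatrix:
    """Build the change matrix for one outcome.

    Parameters
    ----------
    clr_coefs : clr-space coefficient vector, one per part.
    mean_composition : reference composition (closed to 100; closed here if
        not already — entries are insensitive to small closure error).
    delta : percentage points reallocated (default 4).
    kind : "difference" for raw-scale outcomes, "ratio" for log-scale ones.
    extrapolation_floor : donor remainders below this many percentage points
        are flagged in ``extrapolated`` metadata.
    close_mean : close the reference composition to exactly 100 first
        (default).  Reference vectors of rounded per-part geometric means sum
        slightly below 100; either reading shifts entries by well under 1e-3.
    """
    if kind not in ("difference", "ratio"):
        raise ValueError("kind must be 'difference' or 'ratio'")
    parts = tuple(parts)
    a = np.asarray(clr_coefs, dtype=float)
    xbar = np.asarray(mean_composition, dtype=float)
    if close_mean:
        xbar = close(xbar, kappa=100.0)
    if a.size != len(parts) or xbar.size != len(parts):
        raise ValueError("clr_coefs, mean_composition and parts must align")
    D = len(parts)
    base = 0.0 if kind == "difference" else 1.0
    M = np.full((D, D), base)
    clr_bar = clr(xbar)
    undefined, extrapolated = [], []
    for i_from in range(D):
        for i_to in range(D):
            if i_from == i_to:
                continue
            if delta >= xbar[i_from]:
                M[i_to, i_from] = np.nan
                undefined.append((parts[i_to], parts[i_from]))
                continue
            x_new = reallocate(xbar, i_from, i_to, delta)
            d_eta = float(a @ (clr(x_new) - clr_bar))
            M[i_to, i_from] = np.exp(d_eta) if kind == "ratio" else d_eta
            if xbar[i_from] - delta < extrapolation_floor:
                extrapolated.append((parts[i_to], parts[i_from]))
    return ChangeMatrix(
        outcome=outcome, kind=kind, delta=delta, parts=parts, values=M,
        undefined=undefined, extrapolated=extrapolated,
    )
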