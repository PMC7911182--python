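"""Aitchison-geometry primitives for compositional data.

A composition is a vector of strictly positive parts carrying only relative
information; closure rescales it to a constant sum (here 100 %).  The module
provides the centred log-ratio (clr) and pivot isometric log-ratio (ilr)
transforms, pivot orthonormal bases, the variation matrix, per-part
compositional geometric means, pairwise reallocation, and reconstruction of
clr-space coefficients from first-pivot regression coefficients.

Conventions
-----------
* Closure constant ``kappa`` defaults to 100 (percentages).
* Sample variances use divisor N - 1.
* Pivot coordinate ``i`` (1-based, for part order ``o``) is
  ``sqrt((D-i)/(D-i+1)) * ln(x_{o_i} / gmean(x_{o_{i+1}}, ..., x_{o_D}))``,
  so a positive first coordinate means more of the first part relative to the
  geometric mean of the remaining parts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Composition",
    "PivotBasis",
    "close",
    "clr",
    "clr_inv",
    "pivot_basis",
    "ilr",
    "ilr_inv",
    "variation_matrix",
    "compositional_geometric_mean",
    "reallocate",
    "clr_coeffs_from_first_pivot",
]


def _as_2d(x) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim == 2:
        return arr, False
    raise ValueError(f"expected 1-D or 2-D input, got ndim={arr.ndim}")


def _check_positive(arr: np.ndarray, labels: Sequence[str] | None = None) -> None:
    if arr.size == 0:
        raise ValueError("empty composition")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite part values")
    bad = np.nonzero(~(arr > 0))
    if bad[0].size:
        j = int(bad[-1][0])
        name = labels[j] if labels is not None else f"part {j}"
        raise ValueError(f"non-positive value in {name!r}: all parts must be > 0")


def close(values, kappa: float = 100.0, labels: Sequence[str] | None = None) -> np.ndarray:
    """Rescale positive parts (rows) to sum to ``kappa``.

    Accepts a single composition (1-D) or a sample (2-D, one row per subject).
    """
    if kappa <= 0:
        raise ValueError("closure constant must be positive")
    arr, was_1d = _as_2d(values)
    if arr.shape[1] < 2:
        raise ValueError("a composition needs at least 2 parts")
    _check_positive(arr, labels)
    out = kappa * arr / arr.sum(axis=1, keepdims=True)
    return out[0] if was_1d else out


def clr(x, labels: Sequence[str] | None = None) -> np.ndarray:
    """Centred log-ratio: ln(x_i / geometric mean of the row).

    Rows sum to zero; invariant under row rescaling (hence under closure).
    """
    arr, was_1d = _as_2d(x)
    _check_positive(arr, labels)
    lx = np.log(arr)
    out = lx - lx.mean(axis=1, keepdims=True)
    return out[0] if was_1d else out


def clr_inv(y, kappa: float = 100.0) -> np.ndarray:
    """Map clr coordinates back to a closed composition."""
    arr, was_1d = _as_2d(y)
    out = close(np.exp(arr), kappa=kappa)
    return out if not was_1d else out


@dataclass(frozen=True)
class PivotBasis:
    """Orthonormal pivot (ilr) contrast matrix for an ordered set of parts.

    Attributes
    ----------
    labels : tuple of str
        Part names in their original (storage) order.
    order : tuple of int
        Permutation of part indices; ``order[0]`` is the pivot ("first") part.
    V : ndarray, shape (D, D-1)
        Contrast matrix in storage order: ``z = V.T @ clr(x)``; columns are
        orthonormal and sum to zero.
    """

    labels: tuple[str, ...]
    order: tuple[int, ...]
    V: np.ndarray = field(repr=False)

    @property
    def first(self) -> str:
        return self.labels[self.order[0]]


def pivot_basis(labels: Sequence[str], first: str | None = None,
                order: Sequence[str] | None = None) -> PivotBasis:
    """Build the pivot ilr basis that places ``first`` in the leading position.

    Parameters
    ----------
    labels : part names in storage order.
    first : the part contrasted against the geometric mean of all others by
        the first coordinate.  Remaining parts keep their storage order.
    order : full explicit part order (overrides ``first``).
    """
    labels = tuple(labels)
    D = len(labels)
    if D < 2:
        raise ValueError("need at least 2 parts")
    if order is not None:
        order_lab = tuple(order)
        if sorted(order_lab) != sorted(labels):
            raise ValueError(f"order {order_lab} is not a permutation of {labels}")
        idx = tuple(labels.index(l) for l in order_lab)
    else:
        if first is None:
            first = labels[0]
        if first not in labels:
            raise ValueError(f"unknown part {first!r}; expected one of {labels}")
        rest = [l for l in labels if l != first]
        idx = tuple(labels.index(l) for l in [first, *rest])

    V = np.zeros((D, D - 1))
    for i in range(D - 1):  # coordinate i contrasts ordered part i vs parts after it
        r = D - 1 - i
        V[idx[i], i] = np.sqrt(r / (r + 1))
        for j in range(i + 1, D):
            V[idx[j], i] = -1.0 / np.sqrt(r * (r + 1))
    return PivotBasis(labels=labels, order=idx, V=V)


def ilr(x, basis: PivotBasis) -> np.ndarray:
    """Pivot isometric log-ratio coordinates ``z = V.T @ ln(x)``."""
    arr, was_1d = _as_2d(x)
    if arr.shape[1] != len(basis.labels):
        raise ValueError(
            f"composition has {arr.shape[1]} parts, basis expects {len(basis.labels)}"
        )
    _check_positive(arr, basis.labels)
    # columns of V sum to zero, so V.T @ log x equals V.T @ clr x
    z = np.log(arr) @ basis.V
    return z[0] if was_1d else z


def ilr_inv(z, basis: PivotBasis, kappa: float = 100.0) -> np.ndarray:
    """Invert pivot coordinates to a closed composition."""
    arr, was_1d = _as_2d(z)
    if arr.shape[1] != basis.V.shape[1]:
        raise ValueError(
            f"got {arr.shape[1]} coordinates, basis expects {basis.V.shape[1]}"
        )
    out = close(np.exp(arr @ basis.V.T), kappa=kappa)
    return out if not was_1d else out


def variation_matrix(sample) -> np.ndarray:
    """Variation matrix T[i, j] = sample variance (ddof=1) of ln(x_i / x_j).

    Symmetric with zero diagonal; invariant under row rescaling.  Equivalently
    ``var(clr_i - clr_j)``.
    """
    arr, _ = _as_2d(sample)
    if arr.shape[0] < 2:
        raise ValueError("variation matrix needs at least 2 rows")
    _check_positive(arr)
    lx = np.log(arr)
    # var(ln xi - ln xj) = C_ii + C_jj - 2 C_ij with C = cov of log parts
    C = np.cov(lx, rowvar=False, ddof=1)
    d = np.diag(C)
    T = d[:, None] + d[None, :] - 2.0 * C
    np.fill_diagonal(T, 0.0)
    return np.maximum(T, 0.0)


def compositional_geometric_mean(sample, kappa: float = 100.0) -> np.ndarray:
    """Per-part geometric mean across subjects of the closed composition.

    The result is *not* re-closed: per-part geometric means of closed rows sum
    to less than ``kappa`` whenever the sample has any dispersion.
    Rows not already closed are closed first (with a warning).
    """
    arr, _ = _as_2d(sample)
    _check_positive(arr)
    sums = arr.sum(axis=1)
    if not np.allclose(sums, kappa, atol=1e-6):
        warnings.warn(
            "rows are not closed; closing to kappa before computing geometric means",
            stacklevel=2,
        )
        arr = close(arr, kappa=kappa)
    return np.exp(np.log(arr).mean(axis=0))


def reallocate(x, source: str | int, target: str | int, delta: float,
               labels: Sequence[str] | None = None) -> np.ndarray:
    """Move ``delta`` percentage points from part ``source`` to part ``target``.

    The composition must be closed; the donor part must remain positive.
    """
    arr = np.asarray(x, dtype=float).copy()
    if arr.ndim != 1:
        raise ValueError("reallocate expects a single composition")
    _check_positive(arr, labels)

    def _idx(part):
        if isinstance(part, str):
            if labels is None or part not in labels:
                raise ValueError(f"unknown part {part!r}")
            return list(labels).index(part)
        return int(part)

    i, j = _idx(source), _idx(target)
    if i == j:
        raise ValueError("source and target parts must differ")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if delta >= arr[i]:
        name = labels[i] if labels is not None else f"part {i}"
        raise ValueError(
            f"cannot move {delta} points out of {name!r} ({arr[i]}): "
            "resulting part would be non-positive"
        )
    arr[i] -= delta
    arr[j] += delta
    return arr


def clr_coeffs_from_first_pivot(betas) -> tuple[np.ndarray, float]:
    """Reconstruct clr-space coefficients from D first-pivot coefficients.

    For a D-part composition fitted D times, each rotation placing a different
    part first, the first-pivot coefficient ``beta_j`` relates to the clr-space
    coefficient of part j by ``a_j = sqrt((D-1)/D) * beta_j``.  Coefficients
    from a single underlying model satisfy ``sum(a) = 0`` exactly; the returned
    residual ``r = sum(a)`` flags rounded or inconsistent inputs.

    Returns
    -------
    (a, r) : clr coefficient vector and its sum.
    """
    b = np.asarray(betas, dtype=float)
    if b.ndim != 1 or b.size < 2:
        raise ValueError("expected a 1-D vector of at least 2 coefficients")
    D = b.size
    a = np.sqrt((D - 1) / D) * b
    return a, float(a.sum())


@dataclass
class Composition:
    """A single validated, closed composition.

    Parameters
    ----------
    labels : ordered part names.
    values : strictly positive part values; closed to ``kappa`` on construction.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kappa: float = 100.0

    def __post_init__(self):
        self.labels = tuple(self.labels)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != len(self.labels):
            raise ValueError("values must be 1-D and match labels")
        self.values = close(vals, kappa=self.kappa, labels=self.labels)

    def __getitem__(self, part: str) -> float:
        return float(self.values[self.labels.index(part)])

    def clr(self) -> np.ndarray:
        return clr(self.values, self.labels)

    def reallocate(self, source: str, target: str, delta: float) -> "Composition":
        return Composition(
            self.labels,
            reallocate(self.values, source, target, delta, self.labels),
            self.kappa,
        )
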