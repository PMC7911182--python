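"""Compositional linear regression with pivot-coordinate rotation.

The model regresses an outcome (natural-log transformed for right-skewed
serum measures) on the D-1 pivot ilr coordinates of a D-part composition plus
confounders.  Refitting with each part rotated into the first pivot position
("rotation") leaves fitted values, R² and the F test unchanged — the bases
span the same subspace — but makes the first coordinate's coefficient
interpretable as the effect of that part relative to the geometric mean of
the remaining parts.  The full clr-space coefficient vector is recovered from
any single rotation as ``a = V @ b`` and satisfies ``sum(a) = 0``.

The unadjusted R² and F-test p reported alongside come from the
composition-only model (intercept + coordinates, no confounders).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import reference as ref
from .composition import PivotBasis, ilr, pivot_basis

__all__ = [
    "CONFOUNDERS_ANTHROPOMETRIC",
    "CONFOUNDERS_WITH_ZBMI",
    "default_confounders",
    "CompositionalOLS",
    "CompositionalOLSResults",
    "fit_compositional",
    "sensitivity_suite",
    "SensitivityResult",
]

#: confounder set for anthropometric outcomes (height, weight, zBMI)
CONFOUNDERS_ANTHROPOMETRIC = (
    "age", "sex", "energy_kcal", "carb_pcte", "sodium_mg_per_1000kcal",
    "physical_activity", "sleep_h", "screen_time", "single_parent", "siblings",
)
#: the same plus zBMI, for blood-derived and blood-pressure outcomes
CONFOUNDERS_WITH_ZBMI = CONFOUNDERS_ANTHROPOMETRIC + ("zbmi",)

_ANTHROPOMETRIC = {"height", "weight", "zbmi"}


def default_confounders(outcome: str) -> tuple[str, ...]:
    """Outcome-appropriate confounder set: zBMI is itself an outcome for the
    anthropometric models and a confounder everywhere else."""
    return (
        CONFOUNDERS_ANTHROPOMETRIC if outcome in _ANTHROPOMETRIC
        else CONFOUNDERS_WITH_ZBMI
    )


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, s, vt = np.linalg.svd(A, full_matrices=False)
        null = vt[rank:]
        involved = sorted({
            X.columns[j]
            for row in null
            for j in np.nonzero(np.abs(row) > 1e-8)[0]
        })
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]}); "
            f"collinear columns: {involved}"
        )


class CompositionalOLS:
    """OLS of an outcome on pivot ilr coordinates of a composition plus
    confounders, fitted once per rotation.

    Parameters
    ----------
    data : DataFrame with part columns ``<part><part_suffix>``, the outcome,
        and the confounders.
    outcome : outcome column name.
    parts : ordered part names (default the four fatty-acid classes).
    confounders : covariate columns; default chosen by outcome (zBMI included
        except for the anthropometric outcomes).  Pass ``()`` for none.
    log_outcome : model ln(outcome); default by outcome name.
    rotation_order : sequence of parts to rotate first; default all parts in
        their canonical order.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        parts: tuple[str, ...] = ref.FA_PARTS,
        part_suffix: str = "_pct",
        confounders: tuple[str, ...] | None = None,
        log_outcome: bool | None = None,
        rotation_order: tuple[str, ...] | None = None,
    ):
        self.outcome = outcome
        self.parts = tuple(parts)
        self.part_suffix = part_suffix
        self.confounders = (
            default_confounders(outcome) if confounders is None else tuple(confounders)
        )
        self.log_outcome = (
            outcome in ref.LOG_SCALE_OUTCOMES if log_outcome is None else bool(log_outcome)
        )
        self.rotation_order = tuple(rotation_order or self.parts)

        part_cols = [f"{p}{part_suffix}" for p in self.parts]
        needed = [outcome, *part_cols, *self.confounders]
        missing = [c for c in needed if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sub = data.dropna(subset=needed)
        self.data = sub
        self._X = sub[part_cols].to_numpy(dtype=float)
        if np.any(self._X <= 0):
            raise ValueError("non-positive composition parts in data")
        y = sub[outcome].to_numpy(dtype=float)
        self.endog = np.log(y) if self.log_outcome else y
        self.nobs = len(sub)

    def _coords(self, basis: PivotBasis) -> pd.DataFrame:
        z = ilr(self._X, basis)
        names = [f"z{i+1}[{basis.labels[basis.order[i]]}|rest]" for i in range(z.shape[1])]
        return pd.DataFrame(z, columns=names, index=self.data.index)

    def fit(self) -> "CompositionalOLSResults":
        rotations: dict[str, sm.regression.linear_model.RegressionResultsWrapper] = {}
        bases: dict[str, PivotBasis] = {}
        conf = self.data[list(self.confounders)].astype(float) if self.confounders else None
        first_rot = None
        for first in self.rotation_order:
            basis = pivot_basis(self.parts, first=first)
            Z = self._coords(basis)
            X = Z if conf is None else pd.concat([Z, conf], axis=1)
            X = sm.add_constant(X, prepend=True)
            _check_full_rank(X)
            res = sm.OLS(self.endog, X).fit()
            rotations[first] = res
            bases[first] = basis
            if first_rot is None:
                first_rot = first

        # unadjusted model: intercept + coordinates only
        basis0 = bases[first_rot]
        Z0 = sm.add_constant(self._coords(basis0), prepend=True)
        unadj = sm.OLS(self.endog, Z0).fit()

        # clr coefficients from one rotation's full coordinate vector: a = V b
        b = rotations[first_rot].params.iloc[1:len(self.parts)].to_numpy()
        a = basis0.V @ b
        return CompositionalOLSResults(
            model=self,
            bases=bases,
            sm_results=rotations,
            sm_unadjusted=unadj,
            clr_coefs=pd.Series(a, index=list(self.parts), name="clr_coef"),
        )


@dataclass
class CompositionalOLSResults:
    """Fit results across the D rotations of one compositional model."""

    model: CompositionalOLS
    bases: dict[str, PivotBasis]
    sm_results: dict = field(repr=False)
    sm_unadjusted: object = field(repr=False)
    clr_coefs: pd.Series = field(repr=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def rsquared_unadjusted(self) -> float:
        return float(self.sm_unadjusted.rsquared)

    @property
    def f_pvalue_unadjusted(self) -> float:
        return float(self.sm_unadjusted.f_pvalue)

    @property
    def first_pivot(self) -> pd.DataFrame:
        """First-pivot coefficient, SE and two-sided t-test p per rotation."""
        rows = []
        for first, res in self.sm_results.items():
            rows.append({
                "first_part": first,
                "beta": float(res.params.iloc[1]),
                "se": float(res.bse.iloc[1]),
                "pvalue": float(res.pvalues.iloc[1]),
            })
        return pd.DataFrame(rows).set_index("first_part")

    def fittedvalues(self, rotation: str | None = None) -> np.ndarray:
        first = rotation or next(iter(self.sm_results))
        return np.asarray(self.sm_results[first].fittedvalues)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Compositional OLS: {'ln ' if m.log_outcome else ''}{m.outcome}"
            f"  (n = {self.nobs})",
            f"  parts: {', '.join(m.parts)}",
            f"  confounders: {', '.join(m.confounders) or '(none)'}",
            f"  unadjusted R^2 = {self.rsquared_unadjusted:.4f}, "
            f"F p = {self.f_pvalue_unadjusted:.4g}",
            "",
            "  first-pivot coefficients (part vs geometric mean of the rest):",
        ]
        fp = self.first_pivot
        for part, row in fp.iterrows():
            lines.append(
                f"    {part:>8}: beta = {row['beta']:+.4f}  "
                f"SE = {row['se']:.4f}  p = {row['pvalue']:.4g}"
            )
        lines.append("")
        lines.append("  clr coefficients (sum = {:.2e}):".format(self.clr_coefs.sum()))
        for part, val in self.clr_coefs.items():
            lines.append(f"    {part:>8}: {val:+.5f}")
        return "\n".join(lines)

    def to_row(self) -> dict:
        """Flat record for tidy CSV export."""
        out = {
            "outcome": self.model.outcome,
            "log_scale": self.model.log_outcome,
            "n": self.nobs,
            "rsquared": self.rsquared_unadjusted,
            "f_pvalue": self.f_pvalue_unadjusted,
        }
        fp = self.first_pivot
        for part in self.model.parts:
            out[f"beta_{part}"] = fp.loc[part, "beta"] if part in fp.index else np.nan
            out[f"se_{part}"] = fp.loc[part, "se"] if part in fp.index else np.nan
            out[f"p_{part}"] = fp.loc[part, "pvalue"] if part in fp.index else np.nan
        for part, val in self.clr_coefs.items():
            out[f"clr_{part}"] = val
        return out


def fit_compositional(data: pd.DataFrame, outcome: str, **kwargs) -> CompositionalOLSResults:
    """Convenience wrapper: build and fit a :class:`CompositionalOLS`."""
    return CompositionalOLS(data, outcome, **kwargs).fit()


@dataclass
class SensitivityResult:
    label: str
    result: CompositionalOLSResults | None
    skipped_reason: str | None = None


_MACROS = ("energy_kcal", "protein_pcte", "fat_pcte", "carb_pcte")


def _with_fat_other(data: pd.DataFrame) -> pd.DataFrame:
    data = data.copy()
    fa_sum = sum(data[f"{p}_pcte"] for p in ref.FA_PARTS)
    data["fat_other_pcte"] = data["fat_pcte"] - fa_sum
    return data


def sensitivity_suite(data: pd.DataFrame, outcome: str) -> list[SensitivityResult]:
    """The three families of sensitivity models for one outcome.

    (i) total fat %E replacing carbohydrate %E among the confounders;
    (ii) every subset of {energy, protein, fat, carbohydrate} as the
    macronutrient adjustment (16 variants; rank-deficient ones are reported
    as skipped, not silently dropped);
    (iii) the 7-part energy-nutrient composition (protein, carbohydrate, the
    four fatty acids, and fat other than the named fatty acids) through the
    same pivot machinery, with the macronutrient confounders removed.
    """
    results: list[SensitivityResult] = []
    base = default_confounders(outcome)
    non_macro = tuple(c for c in base if c not in _MACROS)

    def run(label, **kwargs):
        try:
            res = fit_compositional(data_fo, outcome, **kwargs)
            results.append(SensitivityResult(label, res))
        except np.linalg.LinAlgError as e:
            results.append(SensitivityResult(label, None, skipped_reason=str(e)))

    data_fo = _with_fat_other(data)

    # (i) fat instead of carbohydrate
    conf_i = tuple(c if c != "carb_pcte" else "fat_pcte" for c in base)
    run("fat-for-carbohydrate", confounders=conf_i)

    # (ii) macro-adjustment subsets
    for subset in chain.from_iterable(
        combinations(_MACROS, k) for k in range(len(_MACROS) + 1)
    ):
        run(f"macros:{'+'.join(subset) or 'none'}", confounders=non_macro + subset)

    # (iii) all energy-generating nutrients as a 7-part composition
    parts7 = ("protein", "carb", "SFA", "MUFA", "omega6", "omega3", "fat_other")
    conf_iii = tuple(c for c in non_macro) + ("energy_kcal",)
    run("seven-part-composition", parts=parts7, part_suffix="_pcte",
        confounders=conf_iii)
    return results
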