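"""Traditional isocaloric substitution regressions.

Each model regresses an outcome on total energy (kcal), protein and
carbohydrate (%E), all fatty-acid classes *except one* (%E), and fat other
than the named fatty acids (%E), plus the usual confounders.  Because total
energy and every other energy source are held fixed, the coefficient of an
included fatty acid is the predicted effect of consuming one extra %E of it
at the expense of the omitted fatty acid.

Convention: the omitted (substituted-out) class is omega-6 PUFA for the SFA
model and SFA for the MUFA, omega-6 and omega-3 models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import reference as ref
from .regression import default_confounders, _check_full_rank

__all__ = ["SubstitutionOLS", "SubstitutionOLSResults", "fit_substitution"]

_NUTRIENT_BASE = ("energy_kcal", "protein_pcte", "carb_pcte")


def _default_omitted(target: str) -> str:
    return "omega6" if target == "SFA" else "SFA"


class SubstitutionOLS:
    """Isocaloric substitution model for one target fatty acid.

    Parameters
    ----------
    data : cohort table with ``<part>_pcte`` columns, ``fat_pcte``, nutrient
        and confounder columns.
    outcome : outcome column (log-modelled for the skewed serum measures).
    target : the substituted-in fatty acid whose coefficient is read.
    omitted : the substituted-out class left out of the model; default
        omega-6 PUFA when the target is SFA, otherwise SFA.
    include_fat_other : include the fat-minus-fatty-acids %E term (default
        True; required for a clean isocaloric reading).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        target: str,
        omitted: str | None = None,
        parts: tuple[str, ...] = ref.FA_PARTS,
        confounders: tuple[str, ...] | None = None,
        log_outcome: bool | None = None,
        include_fat_other: bool = True,
    ):
        if target not in parts:
            raise ValueError(f"unknown target fatty acid {target!r}")
        self.outcome = outcome
        self.target = target
        self.omitted = omitted or _default_omitted(target)
        if self.omitted == target:
            raise ValueError("target and omitted fatty acid must differ")
        if self.omitted not in parts:
            raise ValueError(f"unknown omitted fatty acid {self.omitted!r}")
        self.parts = tuple(parts)
        self.included_fas = tuple(p for p in parts if p != self.omitted)
        self.confounders = (
            default_confounders(outcome) if confounders is None else tuple(confounders)
        )
        # energy and carbohydrate are already explicit nutrient terms
        self.confounders = tuple(c for c in self.confounders if c not in _NUTRIENT_BASE)
        self.log_outcome = (
            outcome in ref.LOG_SCALE_OUTCOMES if log_outcome is None else bool(log_outcome)
        )
        self.include_fat_other = include_fat_other

        data = data.copy()
        fa_sum = sum(data[f"{p}_pcte"] for p in parts)
        data["fat_other_pcte"] = data["fat_pcte"] - fa_sum
        neg = (data["fat_other_pcte"] < 0).mean()
        if neg > 0.01:
            warnings.warn(
                f"fat-without-fatty-acids negative in {neg:.1%} of rows: "
                "fat and fatty-acid %E columns are inconsistent",
                stacklevel=2,
            )
        fa_cols = [f"{p}_pcte" for p in self.included_fas]
        cols = list(_NUTRIENT_BASE) + fa_cols + list(self.confounders) + [outcome]
        if include_fat_other:
            cols.insert(len(_NUTRIENT_BASE) + len(fa_cols), "fat_other_pcte")
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        sub = data.dropna(subset=cols)
        self.data = sub
        self.exog_names = [c for c in cols if c != outcome]
        y = sub[outcome].to_numpy(dtype=float)
        self.endog = np.log(y) if self.log_outcome else y
        self.nobs = len(sub)

    def fit(self) -> "SubstitutionOLSResults":
        X = sm.add_constant(self.data[self.exog_names].astype(float), prepend=True)
        _check_full_rank(X)
        res = sm.OLS(self.endog, X).fit()
        fa_cols = [f"{p}_pcte" for p in self.included_fas]
        table = pd.DataFrame({
            "coef": res.params[fa_cols].to_numpy(),
            "se": res.bse[fa_cols].to_numpy(),
            "pvalue": res.pvalues[fa_cols].to_numpy(),
        }, index=list(self.included_fas))
        return SubstitutionOLSResults(model=self, sm_result=res, fa_table=table)


@dataclass
class SubstitutionOLSResults:
    model: SubstitutionOLS
    sm_result: object = field(repr=False)
    fa_table: pd.DataFrame = field(repr=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def target_coef(self) -> float:
        """Effect of 1 %E of the target fatty acid replacing the omitted one."""
        return float(self.fa_table.loc[self.model.target, "coef"])

    @property
    def target_se(self) -> float:
        return float(self.fa_table.loc[self.model.target, "se"])

    @property
    def target_pvalue(self) -> float:
        return float(self.fa_table.loc[self.model.target, "pvalue"])

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Substitution OLS: {'ln ' if m.log_outcome else ''}{m.outcome}"
            f"  (n = {self.nobs})",
            f"  {m.target} substituted for {m.omitted} (omitted)",
            "  coefficients per 1 %E (replacing the omitted fatty acid):",
        ]
        for part, row in self.fa_table.iterrows():
            mark = " <- target" if part == m.target else ""
            lines.append(
                f"    {part:>8}: {row['coef']:+.4f}  SE = {row['se']:.4f}  "
                f"p = {row['pvalue']:.4g}{mark}"
            )
        return "\n".join(lines)

    def to_row(self) -> dict:
        m = self.model
        return {
            "outcome": m.outcome,
            "log_scale": m.log_outcome,
            "target": m.target,
            "omitted": m.omitted,
            "n": self.nobs,
            "coef": self.target_coef,
            "se": self.target_se,
            "pvalue": self.target_pvalue,
        }


def fit_substitution(data: pd.DataFrame, outcome: str, target: str,
                     **kwargs) -> SubstitutionOLSResults:
    """Convenience wrapper: build and fit a :class:`SubstitutionOLS`."""
    return SubstitutionOLS(data, outcome, target, **kwargs).fit()
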