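"""Calibrated logistic-normal synthetic cohort generator.

The study cohort is not publicly deposited, so the pipeline is exercised on
synthetic subject tables with the statistical structure the analysis assumes:

* the closed 4-part fatty-acid composition is logistic-normal — clr
  coordinates are multivariate Gaussian with covariance derived from a target
  variation matrix by double-centering, and a mean calibrated so the per-part
  geometric means of the *closed* draws hit their targets;
* dietary totals (energy, macronutrient %E, sodium) are truncated Gaussians
  with the reported cohort marginals;
* outcomes follow linear models ``eta = intercept + a . clr(x) + gamma .
  confounders + Normal(0, sigma)`` on the raw scale, or on the natural-log
  scale (then exponentiated) for the right-skewed serum measures.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference as ref
from .composition import close, clr

__all__ = [
    "clr_cov_from_variation",
    "calibrate_center",
    "OutcomeModel",
    "GeneratorConfig",
    "generate",
    "write_cohort",
]

#: fraction of total fat energy contributed by the four named fatty acids
FA_SHARE_OF_FAT = 0.87


def clr_cov_from_variation(T) -> np.ndarray:
    """clr-space covariance realizing a variation matrix.

    ``Sigma = -0.5 * G @ T @ G`` with ``G = I - (1/D) 11'`` (double-centering).
    Rows of Sigma sum to zero and the induced ``var(clr_i - clr_j)`` equals
    ``T[i, j]`` exactly.  T must be symmetric with zero diagonal; a T whose
    double-centred form has an eigenvalue below -1e-8 is not realizable by any
    composition distribution and is rejected.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("variation matrix must be square")
    if not np.allclose(T, T.T, atol=1e-12):
        raise ValueError("variation matrix must be symmetric")
    if not np.allclose(np.diag(T), 0.0, atol=1e-12):
        raise ValueError("variation matrix must have zero diagonal")
    D = T.shape[0]
    G = np.eye(D) - np.ones((D, D)) / D
    Sigma = -0.5 * G @ T @ G
    w = np.linalg.eigvalsh(Sigma)
    if w.min() < -1e-8:
        raise ValueError(
            f"variation matrix is not realizable: clr covariance has eigenvalue {w.min():.3g}"
        )
    return Sigma


def _mvn_sqrt(Sigma: np.ndarray) -> np.ndarray:
    """Symmetric square root tolerant of the (structural) zero eigenvalue."""
    w, U = np.linalg.eigh(Sigma)
    return U @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ U.T


def calibrate_center(
    gm_target,
    Sigma,
    kappa: float = 100.0,
    n_pilot: int = 100_000,
    tol: float = 0.05,
    max_iter: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """clr-space mean such that closed draws reproduce target geometric means.

    Closure is nonlinear, so the geometric means of closed logistic-normal
    draws are not simply ``exp(mu)``; a multiplicative fixed-point iteration
    on pilot samples corrects for the shift.  Converges when every per-part
    geometric mean is within ``tol`` percentage points of its target.

    Raises ``RuntimeError`` with the achieved values if it does not converge —
    target vectors whose implied scale is incompatible with Sigma cannot be
    matched exactly (geometric means of closed draws are proportional to
    ``exp(mu)`` with a scale factor fixed by Sigma).
    """
    target = np.asarray(gm_target, dtype=float)
    if np.any(target <= 0):
        raise ValueError("geometric-mean targets must be positive")
    Sigma = np.asarray(Sigma, dtype=float)
    rng = np.random.default_rng(seed)
    A = _mvn_sqrt(Sigma)
    mu = np.log(target)
    mu -= mu.mean()
    if np.allclose(Sigma, 0.0):
        # degenerate sample: closure is deterministic, gm == closed target
        return mu
    achieved = None
    for _ in range(max_iter):
        eps = rng.standard_normal((n_pilot, len(target))) @ A.T
        x = close(np.exp(mu + eps), kappa=kappa)
        achieved = np.exp(np.log(x).mean(axis=0))
        if np.max(np.abs(achieved - target)) < tol:
            return mu
        mu = mu + np.log(target / achieved)
        mu -= mu.mean()
    raise RuntimeError(
        f"geometric-mean calibration did not converge in {max_iter} iterations; "
        f"achieved {np.round(achieved, 3)} vs target {target}"
    )


@dataclass
class OutcomeModel:
    """Generating model for one outcome.

    ``eta = intercept + clr_coefs . clr(x) + sum_k confounder_coefs[k] * z_k
    + Normal(0, sigma)``; the outcome is ``exp(eta)`` when ``log_scale``.
    ``intercept=None`` means: choose it so the expected linear predictor
    matches ``loc`` (the target mean, or log-mean minus ``sigma^2/2`` for
    log-scale outcomes, so the raw-scale mean is approximately right).
    """

    clr_coefs: np.ndarray
    sigma: float
    log_scale: bool = False
    confounder_coefs: dict[str, float] = field(default_factory=dict)
    intercept: float | None = None
    loc: float | None = None

    def __post_init__(self):
        self.clr_coefs = np.asarray(self.clr_coefs, dtype=float)
        if self.sigma <= 0:
            raise ValueError("residual sigma must be positive")


def _default_outcome_models() -> dict[str, OutcomeModel]:
    scale = np.sqrt(3.0) / 2.0  # first-pivot beta -> clr coefficient, D = 4
    log_sigmas = {"ldl": 0.21, "hdl": 0.20, "ast": 0.26, "alt": 0.45, "ggt": 0.30}
    conf = {
        "height": {"sex": 5.0, "age": 2.0},
        "weight": {"sex": 3.0, "age": 2.0, "zbmi_dummy": 0.0},
        "sbp": {"sex": 2.0},
        "dbp": {"sex": 1.0},
    }
    models: dict[str, OutcomeModel] = {}
    for name, betas in ref.FIRST_PIVOT_COEFS.items():
        log_scale = name in ref.LOG_SCALE_OUTCOMES
        mean, sd = ref.MARGINALS[name]
        if log_scale:
            sigma = log_sigmas[name]
            loc = np.log(mean) - 0.5 * sigma**2
        else:
            sigma = sd
            loc = mean
        models[name] = OutcomeModel(
            clr_coefs=scale * np.asarray(betas),
            sigma=sigma,
            log_scale=log_scale,
            confounder_coefs={k: v for k, v in conf.get(name, {}).items()
                              if k != "zbmi_dummy"},
            loc=loc,
        )
    return models


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort.

    Defaults reproduce the reported cohort: N = 5485 subjects, the published
    fatty-acid geometric means and variation matrix, the marginal diet and
    outcome distributions, and clr-space outcome coefficients reconstructed
    from the published first-pivot coefficients.
    """

    n: int = 5485
    seed: int = 0
    fa_parts: tuple[str, ...] = ref.FA_PARTS
    gm_target: dict[str, float] = field(default_factory=lambda: dict(ref.GEOMETRIC_MEANS))
    T_target: np.ndarray = field(default_factory=lambda: ref.VARIATION_MATRIX.copy())
    marginals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(ref.MARGINALS)
    )
    confounder_dists: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in ref.CONFOUNDER_DISTS.items()}
    )
    outcome_models: dict[str, OutcomeModel] = field(default_factory=_default_outcome_models)
    fa_share_of_fat: float = FA_SHARE_OF_FAT
    disease_prevalence: float = ref.DISEASE_PREVALENCE
    trunc_sds: float = 4.0  # symmetric truncation of Gaussian marginals
    n_pilot: int = 100_000
    calibration_tol: float = 0.05
    #: optional {confounder: clr-loading vector} adding composition-confounder
    #: correlation (stress hook for adjustment; off by default)
    confounder_clr_loadings: dict[str, np.ndarray] | None = None

    def gm_vector(self) -> np.ndarray:
        return np.array([self.gm_target[p] for p in self.fa_parts])

    def validate(self) -> None:
        T = np.asarray(self.T_target, dtype=float)
        if T.shape != (len(self.fa_parts),) * 2:
            raise ValueError("T_target shape does not match fa_parts")
        if np.any(self.gm_vector() <= 0):
            raise ValueError("gm_target values must be positive")
        if not 0 < self.fa_share_of_fat <= 1:
            raise ValueError("fa_share_of_fat must be in (0, 1]")
        for name, model in self.outcome_models.items():
            if model.clr_coefs.size != len(self.fa_parts):
                raise ValueError(f"outcome {name!r}: clr coefficient length mismatch")

    def to_manifest(self) -> dict:
        """JSON-serializable record of every generator parameter."""
        d = asdict(self)
        d["T_target"] = np.asarray(self.T_target).tolist()
        d["outcome_models"] = {
            k: {**asdict(m), "clr_coefs": m.clr_coefs.tolist()}
            for k, m in self.outcome_models.items()
        }
        if self.confounder_clr_loadings:
            d["confounder_clr_loadings"] = {
                k: np.asarray(v).tolist() for k, v in self.confounder_clr_loadings.items()
            }
        return d


def _trunc_normal(rng, mean, sd, n, n_sds, lower=0.0):
    """Gaussian truncated to mean +/- n_sds SDs and above ``lower`` (resampling)."""
    lo = max(mean - n_sds * sd, lower)
    hi = mean + n_sds * sd
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


_SCHEMA = [
    "sex", "age", "physical_activity", "sleep_h", "screen_time",
    "single_parent", "siblings", "diagnosed_disease",
    "energy_kcal", "protein_pcte", "carb_pcte", "fat_pcte",
    "sodium_mg_per_1000kcal", "fa_total_pcte",
    "SFA_pcte", "MUFA_pcte", "omega6_pcte", "omega3_pcte",
    "SFA_pct", "MUFA_pct", "omega6_pct", "omega3_pct",
    "height", "weight", "zbmi", "ldl", "hdl", "sbp", "dbp", "ast", "alt", "ggt",
]


def _confounder_expectation(dist: Mapping) -> float:
    kind = dist["kind"]
    if kind == "bernoulli":
        return dist["p"]
    if kind == "normal":
        return dist["mean"]
    if kind == "categorical":
        return float(np.dot(dist["levels"], dist["p"]))
    raise ValueError(f"unknown confounder distribution kind {kind!r}")


def _draw_confounder(rng, dist: Mapping, n: int) -> np.ndarray:
    kind = dist["kind"]
    if kind == "bernoulli":
        return (rng.random(n) < dist["p"]).astype(float)
    if kind == "normal":
        return rng.normal(dist["mean"], dist["sd"], size=n)
    if kind == "categorical":
        return rng.choice(np.asarray(dist["levels"], dtype=float), size=n, p=dist["p"])
    raise ValueError(f"unknown confounder distribution kind {kind!r}")


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a synthetic cohort table.

    Columns: confounders (sex 1 = male, age in years, binary physical
    activity, sleep in hours, ordinal screen time 1–5, binary single parent,
    sibling count), a binary excludable-disease flag, diet variables (energy
    kcal, macronutrients %E, sodium mg/1000 kcal, fatty acids as %E and closed
    %), and the ten outcomes on their raw scales.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(config.n)
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in _SCHEMA})

    D = len(config.fa_parts)
    Sigma = clr_cov_from_variation(config.T_target)
    mu = calibrate_center(
        config.gm_vector(), Sigma,
        n_pilot=config.n_pilot, tol=config.calibration_tol,
        seed=int(rng.integers(2**31)),
    )
    A = _mvn_sqrt(Sigma)
    eps = rng.standard_normal((n, D)) @ A.T
    parts_pct = close(np.exp(mu + eps), kappa=100.0)
    clr_x = clr(parts_pct)

    m = config.marginals
    fa_total = _trunc_normal(rng, *m["fa_total_pcte"], n, config.trunc_sds, lower=1.0)
    fat = fa_total / config.fa_share_of_fat
    energy = _trunc_normal(rng, *m["energy_kcal"], n, config.trunc_sds, lower=1.0)
    protein = _trunc_normal(rng, *m["protein_pcte"], n, config.trunc_sds, lower=1.0)
    carb = _trunc_normal(rng, *m["carb_pcte"], n, config.trunc_sds, lower=1.0)
    sodium = _trunc_normal(rng, *m["sodium_mg_per_1000kcal"], n, config.trunc_sds, lower=1.0)

    confs: dict[str, np.ndarray] = {}
    for name, dist in config.confounder_dists.items():
        confs[name] = _draw_confounder(rng, dist, n)
        if config.confounder_clr_loadings and name in config.confounder_clr_loadings:
            confs[name] = confs[name] + clr_x @ np.asarray(
                config.confounder_clr_loadings[name], dtype=float
            )
    disease = (rng.random(n) < config.disease_prevalence).astype(float)

    table = {
        **confs,
        "diagnosed_disease": disease,
        "energy_kcal": energy,
        "protein_pcte": protein,
        "carb_pcte": carb,
        "fat_pcte": fat,
        "sodium_mg_per_1000kcal": sodium,
        "fa_total_pcte": fa_total,
    }
    for j, p in enumerate(config.fa_parts):
        table[f"{p}_pcte"] = parts_pct[:, j] / 100.0 * fa_total
        table[f"{p}_pct"] = parts_pct[:, j]

    conf_means = {k: _confounder_expectation(d) for k, d in config.confounder_dists.items()}
    for name, model in config.outcome_models.items():
        eta = clr_x @ model.clr_coefs
        for cname, coef in model.confounder_coefs.items():
            eta = eta + coef * confs[cname]
        if model.intercept is not None:
            intercept = model.intercept
        else:
            # expected clr is mu (already centred); expected confounders analytic
            loc = model.loc if model.loc is not None else 0.0
            intercept = loc - float(mu @ model.clr_coefs) - sum(
                coef * conf_means[cname] for cname, coef in model.confounder_coefs.items()
            )
        eta = eta + intercept + rng.normal(0.0, model.sigma, size=n)
        table[name] = np.exp(eta) if model.log_scale else eta

    df = pd.DataFrame(table)
    return df[[c for c in _SCHEMA if c in df.columns]]


def write_cohort(df: pd.DataFrame, path, config: GeneratorConfig | None = None) -> None:
    """Write the cohort CSV; alongside it a JSON run manifest if config given."""
    df.to_csv(path, index=False)
    if config is not None:
        manifest = str(path) + ".manifest.json"
        with open(manifest, "w") as fh:
            json.dump(config.to_manifest(), fh, indent=2)
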