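"""Published calibration constants for the Japanese adolescent cohort analysis.

These are the reported summary statistics of a cross-sectional cohort of
eighth-grade students (N = 5485): marginal means and SDs of diet and
cardiometabolic outcomes, the compositional geometric means and variation
matrix of the four dietary fatty-acid classes, and the first-pivot regression
coefficients of the compositional outcome models.  They serve two purposes:

* defaults for the synthetic cohort generator (:mod:`facoda.simulate`), and
* inputs for the deterministic worked example that reconstructs the
  reallocation change matrices from printed coefficients
  (:mod:`facoda.change`).
"""

from __future__ import annotations

import numpy as np

#: The four fatty-acid classes, in the canonical rotation order:
#: saturated, monounsaturated, omega-6 polyunsaturated, omega-3 polyunsaturated.
FA_PARTS: tuple[str, ...] = ("SFA", "MUFA", "omega6", "omega3")

#: Per-part compositional geometric means of the closed (sum = 100 %) fatty-acid
#: composition.  They sum to 99.2, not 100: per-part geometric means of closed
#: rows are not themselves closed.
GEOMETRIC_MEANS: dict[str, float] = {
    "SFA": 36.1,
    "MUFA": 38.9,
    "omega6": 20.0,
    "omega3": 4.2,
}

#: Variation matrix T[i][j] = var(ln(x_i / x_j)) across subjects, ordered as
#: FA_PARTS.  Symmetric, zero diagonal.
VARIATION_MATRIX: np.ndarray = np.array(
    [
        [0.0, 0.031, 0.077, 0.112],
        [0.031, 0.0, 0.018, 0.046],
        [0.077, 0.018, 0.0, 0.038],
        [0.112, 0.046, 0.038, 0.0],
    ]
)

#: Reported first-pivot coefficients beta (one per rotation, ordered as
#: FA_PARTS) of the confounder-adjusted compositional regressions, per outcome.
#: Outcomes marked log-scale model the natural log of the measurement.
FIRST_PIVOT_COEFS: dict[str, tuple[float, float, float, float]] = {
    "height": (-0.22, 0.78, -0.32, -0.06),
    "weight": (-0.83, 2.55, -1.52, 0.92),
    "zbmi": (0.01, 0.10, -0.17, 0.17),
    "ldl": (0.02, 0.08, -0.11, 0.00),
    "hdl": (0.03, -0.03, 0.02, -0.02),
    "sbp": (-0.85, 1.44, 1.32, -2.35),
    "dbp": (-0.47, 0.57, 1.68, -2.41),
    "ast": (0.01, -0.01, -0.01, 0.02),
    "alt": (0.05, -0.10, -0.01, 0.10),
    "ggt": (0.07, -0.08, -0.01, 0.03),
}

#: Outcomes modelled on the natural-log scale (right-skewed serum measures).
LOG_SCALE_OUTCOMES: frozenset[str] = frozenset({"ldl", "hdl", "ast", "alt", "ggt"})

#: Outcomes whose change-matrix entries are multiplicative ratios (log-scale
#: models); the rest are additive differences.
OUTCOME_UNITS: dict[str, str] = {
    "height": "cm",
    "weight": "kg",
    "zbmi": "z-score",
    "ldl": "mg/dL",
    "hdl": "mg/dL",
    "sbp": "mmHg",
    "dbp": "mmHg",
    "ast": "IU/L",
    "alt": "IU/L",
    "ggt": "IU/L",
}

#: Marginal mean and SD of diet variables and outcomes (raw scale).
MARGINALS: dict[str, tuple[float, float]] = {
    "energy_kcal": (2238.0, 640.0),
    "protein_pcte": (14.2, 2.4),
    "fat_pcte": (30.1, 5.6),
    "carb_pcte": (54.2, 6.7),
    "fa_total_pcte": (26.2, 5.1),
    "sodium_mg_per_1000kcal": (1848.0, 429.0),
    "height": (156.8, 7.1),
    "weight": (47.2, 8.6),
    "zbmi": (0.0, 1.0),
    "ldl": (86.9, 19.0),
    "hdl": (67.2, 13.8),
    "sbp": (114.5, 11.5),
    "dbp": (67.7, 8.6),
    "ast": (21.1, 5.9),
    "alt": (13.5, 6.9),
    "ggt": (15.4, 5.0),
}

#: Share of total fat energy contributed by the four named fatty-acid classes
#: (glycerol backbone and minor lipids make up the rest).
def fatty_acid_share_of_fat() -> float:
    """Mean fatty-acid %E divided by mean fat %E, as a percentage."""
    fa = MARGINALS["fa_total_pcte"][0]
    fat = MARGINALS["fat_pcte"][0]
    return 100.0 * fa / fat


#: Confounder marginals: sex Bernoulli(male), age Normal, binary physical
#: activity, sleep Normal (h), 5-level ordinal screen time, binary single
#: parent, sibling count 1..3.
CONFOUNDER_DISTS: dict[str, dict] = {
    "sex": {"kind": "bernoulli", "p": 0.521},
    "age": {"kind": "normal", "mean": 13.56, "sd": 0.29},
    "physical_activity": {"kind": "bernoulli", "p": 0.55},
    "sleep_h": {"kind": "normal", "mean": 7.3, "sd": 0.9},
    "screen_time": {"kind": "categorical", "levels": [1, 2, 3, 4, 5],
                    "p": [0.25, 0.30, 0.22, 0.13, 0.10]},
    "single_parent": {"kind": "bernoulli", "p": 0.13},
    "siblings": {"kind": "categorical", "levels": [1, 2, 3],
                 "p": [0.20, 0.55, 0.25]},
}

#: Prevalence of physician-diagnosed excludable disease in the generator.
DISEASE_PREVALENCE: float = 0.02
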