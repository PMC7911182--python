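"""Synthetic cohort generator: covariance construction, geometric-mean
calibration, reproducibility, and recovery of the configured structure."""

import json

import numpy as np
import pandas as pd
import pytest

from facoda import reference as ref
from facoda.composition import variation_matrix
from facoda.simulate import (
    GeneratorConfig,
    calibrate_center,
    clr_cov_from_variation,
    generate,
)


class TestClrCovFromVariation:
    def test_zero_variation_gives_zero_cov(self):
        T = np.zeros((4, 4))
        assert np.allclose(clr_cov_from_variation(T), 0.0)

    def test_two_part_closed_form(self):
        t = 0.37
        Sigma = clr_cov_from_variation(np.array([[0.0, t], [t, 0.0]]))
        assert np.allclose(Sigma, (t / 4) * np.array([[1, -1], [-1, 1]]), atol=1e-14)
        # induced var(clr_1 - clr_2) equals t
        assert Sigma[0, 0] + Sigma[1, 1] - 2 * Sigma[0, 1] == pytest.approx(t)

    def test_reference_matrix_round_trips_exactly(self):
        T = ref.VARIATION_MATRIX
        Sigma = clr_cov_from_variation(T)
        d = np.diag(Sigma)
        T_back = d[:, None] + d[None, :] - 2 * Sigma
        np.fill_diagonal(T_back, 0.0)
        assert np.allclose(T_back, T, atol=1e-14)
        assert np.allclose(Sigma.sum(axis=1), 0.0, atol=1e-14)

    def test_rejects_invalid_matrices(self):
        with pytest.raises(ValueError, match="symmetric"):
            clr_cov_from_variation(np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            clr_cov_from_variation(np.array([[0.2, 0.1], [0.1, 0.0]]))
        # a large 1-2 log-ratio variance with both parts rigidly tied to part 3
        # is internally contradictory and not realizable
        bad = np.array([[0.0, 10.0, 0.0], [10.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="not realizable"):
            clr_cov_from_variation(bad)


class TestCalibrateCenter:
    def test_degenerate_cov_closed_form(self):
        target = np.array([40.0, 35.0, 25.0])  # sums to the closure constant
        mu = calibrate_center(target, np.zeros((3, 3)))
        expected = np.log(target) - np.log(target).mean()
        assert np.allclose(mu, expected, atol=1e-12)

    def test_target_scale_irrelevant(self):
        Sigma = clr_cov_from_variation(ref.VARIATION_MATRIX)
        t = np.array([36.1, 38.9, 20.0, 4.2])
        mu1 = calibrate_center(t, Sigma, kappa=100.0, n_pilot=20_000,
                               tol=0.05, seed=5)
        # tol is in absolute units of kappa, so it scales along with it
        mu2 = calibrate_center(2 * t, Sigma, kappa=200.0, n_pilot=20_000,
                               tol=0.10, seed=5)
        # doubling the closure constant and the targets together leaves the
        # clr-space centre (and hence the closed draws) unchanged
        assert np.allclose(mu1, mu2, atol=1e-9)

    def test_nonconvergence_fails_loudly(self):
        Sigma = clr_cov_from_variation(ref.VARIATION_MATRIX)
        with pytest.raises(RuntimeError, match="did not converge"):
            calibrate_center([36.1, 38.9, 20.0, 4.2], Sigma,
                             n_pilot=5_000, tol=1e-6, max_iter=3, seed=1)

    def test_rejects_nonpositive_targets(self):
        with pytest.raises(ValueError):
            calibrate_center([1.0, -1.0], np.zeros((2, 2)))


class TestGenerate:
    def test_empty_table_has_full_schema(self):
        df = generate(GeneratorConfig(n=0, seed=1))
        assert len(df) == 0
        for col in ("SFA_pct", "energy_kcal", "ldl", "sex", "zbmi"):
            assert col in df.columns

    def test_seed_reproducibility(self):
        cfg = dict(n=300, seed=11, n_pilot=10_000)
        df1 = generate(GeneratorConfig(**cfg))
        df2 = generate(GeneratorConfig(**cfg))
        pd.testing.assert_frame_equal(df1, df2)

    def test_different_seeds_differ(self):
        df1 = generate(GeneratorConfig(n=300, seed=11, n_pilot=10_000))
        df2 = generate(GeneratorConfig(n=300, seed=12, n_pilot=10_000))
        assert not df1["ldl"].equals(df2["ldl"])

    def test_energy_mean_at_study_size(self):
        df = generate(GeneratorConfig(n=5485, seed=9, n_pilot=20_000))
        mean, sd = ref.MARGINALS["energy_kcal"]
        se = sd / np.sqrt(len(df))
        assert abs(df["energy_kcal"].mean() - mean) < 2 * se + 1.0

    def test_schema_invariants(self, cohort):
        df = cohort
        closed = df[[f"{p}_pct" for p in ref.FA_PARTS]].to_numpy()
        assert np.allclose(closed.sum(axis=1), 100.0, atol=1e-9)
        pcte = df[[f"{p}_pcte" for p in ref.FA_PARTS]].to_numpy()
        assert np.all(pcte.sum(axis=1) < df["fat_pcte"].to_numpy() + 1e-9)
        assert np.all(pcte > 0)
        assert df[["height", "ldl", "ggt", "sbp"]].to_numpy().min() > 0
        assert set(np.unique(df["screen_time"])) <= {1.0, 2.0, 3.0, 4.0, 5.0}

    def test_variation_matrix_recovered(self):
        df = generate(GeneratorConfig(n=20_000, seed=3, n_pilot=20_000))
        X = df[[f"{p}_pct" for p in ref.FA_PARTS]].to_numpy()
        T = variation_matrix(X)
        target = ref.VARIATION_MATRIX
        mc_se = target * np.sqrt(2.0 / (len(df) - 1))
        off = ~np.eye(4, dtype=bool)
        assert np.all(np.abs(T[off] - target[off]) < 3 * mc_se[off] + 1e-12)

    def test_closure_invariance_of_statistics(self, cohort):
        # variation matrix identical whether parts are stored as %E or closed %
        Xpct = cohort[[f"{p}_pct" for p in ref.FA_PARTS]].to_numpy()
        Xpcte = cohort[[f"{p}_pcte" for p in ref.FA_PARTS]].to_numpy()
        assert np.allclose(variation_matrix(Xpct), variation_matrix(Xpcte), atol=1e-10)

    def test_confounder_correlation_hook(self):
        loadings = {"sleep_h": np.array([2.0, 0.0, -2.0, 0.0])}
        cfg = GeneratorConfig(n=8_000, seed=21, n_pilot=10_000,
                              confounder_clr_loadings=loadings)
        df = generate(cfg)
        from facoda.composition import clr
        c = clr(df[[f"{p}_pct" for p in ref.FA_PARTS]].to_numpy())
        r = np.corrcoef(df["sleep_h"], c[:, 0] - c[:, 2])[0, 1]
        assert r > 0.3

    def test_manifest_is_json_serializable(self):
        cfg = GeneratorConfig(n=10)
        blob = json.dumps(cfg.to_manifest())
        assert "T_target" in blob

    def test_invalid_config_rejected(self):
        cfg = GeneratorConfig(n=10, fa_share_of_fat=1.5)
        with pytest.raises(ValueError):
            generate(cfg)
        with pytest.raises(ValueError):
            from facoda.simulate import OutcomeModel
            OutcomeModel(clr_coefs=np.zeros(4), sigma=0.0)
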