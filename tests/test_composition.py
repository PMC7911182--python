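"""Aitchison-geometry primitives: closure, log-ratio transforms, pivot bases,
variation matrix, reallocation, clr-coefficient reconstruction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from facoda.composition import (
    Composition,
    clr,
    clr_coeffs_from_first_pivot,
    close,
    compositional_geometric_mean,
    ilr,
    ilr_inv,
    pivot_basis,
    reallocate,
    variation_matrix,
)
from conftest import random_compositions

PARTS = ("SFA", "MUFA", "omega6", "omega3")
XBAR = np.array([36.1, 38.9, 20.0, 4.2])

positive_parts = st.lists(
    st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=8
)


class TestClose:
    def test_uniform(self):
        assert np.allclose(close([1, 1, 1, 1], 100.0), [25, 25, 25, 25])

    def test_mean_intake_shares(self):
        # 9.6 + 10.3 + 5.3 + 1.1 %E of fatty acids, as % of their 26.3 total
        vals = np.array([9.6, 10.3, 5.3, 1.1])
        expected = vals * 100.0 / 26.3
        out = close(vals, 100.0)
        assert np.allclose(out, expected)
        assert out[0] == pytest.approx(36.50190114, abs=1e-6)

    def test_two_part_unit_kappa(self):
        assert np.allclose(close([2, 2], 1.0), [0.5, 0.5])

    def test_rejects_nonpositive_naming_part(self):
        with pytest.raises(ValueError, match="MUFA"):
            close([1.0, 0.0, 2.0], labels=("SFA", "MUFA", "omega6"))

    def test_rejects_empty_and_single_part(self):
        with pytest.raises(ValueError):
            close([])
        with pytest.raises(ValueError):
            close([5.0])

    @given(positive_parts, st.floats(min_value=0.1, max_value=1000))
    def test_sum_and_proportionality(self, vals, kappa):
        out = close(vals, kappa)
        assert out.sum() == pytest.approx(kappa, abs=1e-9 * max(1, kappa))
        ratio = out / np.asarray(vals)
        assert np.allclose(ratio, ratio[0])


class TestClr:
    def test_uniform_is_zero(self):
        assert np.allclose(clr([25.0, 25, 25, 25]), 0.0)

    def test_known_first_entry(self):
        # ln(36.1 / geometric mean of all four parts)
        g = np.prod(XBAR) ** 0.25
        out = clr(XBAR)
        assert out[0] == pytest.approx(np.log(36.1 / g), abs=1e-12)
        assert out[0] == pytest.approx(0.66677, abs=5e-5)

    def test_sums_to_zero(self, rng):
        X = random_compositions(rng, 50, 5)
        assert np.allclose(clr(X).sum(axis=1), 0.0, atol=1e-10)

    @given(positive_parts, st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, vals, lam):
        assert np.allclose(clr(vals), clr(lam * np.asarray(vals)), atol=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            clr([1.0, -2.0])


class TestPivotBasis:
    def test_two_part_closed_form(self):
        b = pivot_basis(("a", "b"), first="a")
        x = np.array([3.0, 7.0])
        assert ilr(x, b)[0] == pytest.approx(np.log(3 / 7) / np.sqrt(2), abs=1e-12)

    def test_first_coordinate_pivot_form(self):
        b = pivot_basis(PARTS, first="SFA")
        z1 = ilr(XBAR, b)[0]
        expected = np.sqrt(3 / 4) * np.log(36.1 / (38.9 * 20.0 * 4.2) ** (1 / 3))
        assert z1 == pytest.approx(expected, abs=1e-12)
        assert z1 == pytest.approx(0.770, abs=5e-4)

    @pytest.mark.parametrize("first", PARTS)
    def test_orthonormal_zero_sum_columns(self, first):
        b = pivot_basis(PARTS, first=first)
        assert np.allclose(b.V.T @ b.V, np.eye(3), atol=1e-12)
        assert np.allclose(b.V.sum(axis=0), 0.0, atol=1e-12)

    def test_first_column_closed_form_pattern(self):
        b = pivot_basis(PARTS, first="omega6")
        D = 4
        col = b.V[:, 0]
        i = PARTS.index("omega6")
        assert col[i] == pytest.approx(np.sqrt((D - 1) / D))
        others = np.delete(col, i)
        assert np.allclose(others, -1 / np.sqrt(D * (D - 1)))

    def test_all_coordinates_follow_recursion(self):
        # coordinate i contrasts ordered part i against the parts after it
        b = pivot_basis(PARTS, order=PARTS)
        z = ilr(XBAR, b)
        for i in range(3):
            r = 4 - 1 - i
            gm_rest = np.prod(XBAR[i + 1:]) ** (1.0 / r)
            expected = np.sqrt(r / (r + 1)) * np.log(XBAR[i] / gm_rest)
            assert z[i] == pytest.approx(expected, abs=1e-12)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown part"):
            pivot_basis(PARTS, first="trans-fat")
        with pytest.raises(ValueError, match="permutation"):
            pivot_basis(PARTS, order=("SFA", "MUFA"))


class TestIlr:
    def test_round_trip(self):
        b = pivot_basis(PARTS, first="SFA")
        x = close(XBAR)
        back = ilr_inv(ilr(x, b), b)
        assert np.allclose(back, x, atol=1e-9)

    def test_uniform_maps_to_origin(self):
        b = pivot_basis(PARTS)
        assert np.allclose(ilr([25.0, 25, 25, 25], b), 0.0, atol=1e-12)

    def test_isometry_matches_clr_distance(self, rng):
        b = pivot_basis(PARTS, first="MUFA")
        X = random_compositions(rng, 20, 4)
        Y = random_compositions(rng, 20, 4)
        d_ilr = np.linalg.norm(ilr(X, b) - ilr(Y, b), axis=1)
        d_clr = np.linalg.norm(clr(X) - clr(Y), axis=1)
        assert np.allclose(d_ilr, d_clr, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        b = pivot_basis(PARTS)
        with pytest.raises(ValueError):
            ilr([1.0, 2.0], b)
        with pytest.raises(ValueError):
            ilr_inv([0.1, 0.2], b)


class TestVariationMatrix:
    def test_scalar_multiple_rows_give_zero(self, rng):
        base = np.array([36.1, 38.9, 20.0, 4.2])
        X = np.outer(rng.uniform(0.5, 2.0, size=8), base)
        assert np.allclose(variation_matrix(X), 0.0, atol=1e-12)

    def test_two_subject_hand_value(self):
        T = variation_matrix(np.array([[1.0, 2.0], [2.0, 1.0]]))
        # sample variance (ddof=1) of {ln(1/2), ln 2} = 2 ln(2)^2
        assert T[0, 1] == pytest.approx(2 * np.log(2) ** 2, abs=1e-12)
        assert T[0, 1] == pytest.approx(0.9609, abs=5e-5)

    def test_matches_naive_loop_oracle(self, rng):
        X = random_compositions(rng, 9, 5)
        T = variation_matrix(X)
        D = X.shape[1]
        for i in range(D):
            for j in range(D):
                naive = np.var(np.log(X[:, i] / X[:, j]), ddof=1)
                assert T[i, j] == pytest.approx(naive, abs=1e-12)
        assert np.allclose(T, T.T)
        assert np.allclose(np.diag(T), 0.0)

    def test_scale_invariance(self, rng):
        X = random_compositions(rng, 30, 4)
        scales = rng.uniform(0.1, 10, size=(30, 1))
        assert np.allclose(variation_matrix(X), variation_matrix(X * scales), atol=1e-10)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            variation_matrix(np.array([[1.0, 2.0]]))


class TestGeometricMean:
    def test_identical_rows(self):
        X = np.tile(close(XBAR), (6, 1))
        assert np.allclose(compositional_geometric_mean(X), close(XBAR), atol=1e-9)

    def test_two_row_hand_value(self):
        X = close(np.array([[50.0, 50.0], [25.0, 75.0]]))
        gm = compositional_geometric_mean(X)
        assert gm[0] == pytest.approx(np.sqrt(50 * 25), abs=1e-9)
        assert gm[1] == pytest.approx(np.sqrt(50 * 75), abs=1e-9)
        # not re-closed: the per-part geometric means sum below 100
        assert gm.sum() < 100

    def test_warns_and_closes_unclosed_rows(self):
        X = np.array([[1.0, 1.0, 2.0], [2.0, 1.0, 1.0]])
        with pytest.warns(UserWarning, match="not closed"):
            gm = compositional_geometric_mean(X)
        assert gm.sum() <= 100 + 1e-9


class TestReallocate:
    def test_four_point_shift(self):
        out = reallocate(XBAR, "SFA", "omega6", 4.0, labels=PARTS)
        assert np.allclose(out, [32.1, 38.9, 24.0, 4.2])
        assert out.sum() == pytest.approx(XBAR.sum())

    def test_zero_delta_is_identity(self):
        assert np.allclose(reallocate(XBAR, 0, 1, 0.0), XBAR)

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError, match="omega3"):
            reallocate(XBAR, "omega3", "SFA", 4.3, labels=PARTS)

    def test_same_part_rejected(self):
        with pytest.raises(ValueError):
            reallocate(XBAR, 1, 1, 1.0)


class TestClrCoeffReconstruction:
    def test_zero_vector(self):
        a, r = clr_coeffs_from_first_pivot([0.0, 0, 0, 0])
        assert np.allclose(a, 0.0) and r == 0.0

    def test_published_ldl_row(self):
        a, r = clr_coeffs_from_first_pivot([0.02, 0.08, -0.11, 0.00])
        assert np.allclose(a, np.sqrt(3) / 2 * np.array([0.02, 0.08, -0.11, 0.0]))
        assert a[0] == pytest.approx(0.01732, abs=5e-6)
        assert a[1] == pytest.approx(0.06928, abs=5e-6)
        assert a[2] == pytest.approx(-0.09526, abs=5e-6)
        # rounded printed inputs leave a nonzero residual
        assert r == pytest.approx(-0.0087, abs=5e-5)

    def test_rejects_scalar(self):
        with pytest.raises(ValueError):
            clr_coeffs_from_first_pivot([1.0])


class TestCompositionClass:
    def test_closes_on_construction(self):
        c = Composition(PARTS, [9.6, 10.3, 5.3, 1.1])
        assert c.values.sum() == pytest.approx(100.0)
        assert c["SFA"] == pytest.approx(9.6 * 100 / 26.3)

    def test_reallocate_returns_new_closed(self):
        c = Composition(PARTS, XBAR)
        c2 = c.reallocate("SFA", "omega6", 4.0)
        assert c2.values.sum() == pytest.approx(100.0)
        assert c2["SFA"] < c["SFA"]
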