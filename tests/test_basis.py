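"""Spline bases and cross-basis construction."""

import numpy as np
import pytest

from ccdlnm.basis import (BasisSpec, assemble_design, cross_basis,
                          evaluate_basis, lag_basis_spec, log_lag_knots,
                          natural_cubic_basis)


def ns_truncated_power(x, knots_all):
    """Independent natural-cubic-spline basis via the truncated-power
    representation: {1, x, d_k(x) - d_{K-1}(x)}.  Valid on the whole line,
    linear outside the outermost knots."""
    x = np.asarray(x, dtype=float)
    xi = np.asarray(knots_all, dtype=float)
    K = len(xi)

    def d(k):
        return ((np.maximum(x - xi[k], 0.0) ** 3
                 - np.maximum(x - xi[-1], 0.0) ** 3) / (xi[-1] - xi[k]))

    cols = [np.ones_like(x), x]
    cols += [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def hat(A):
    return A @ np.linalg.pinv(A)


class TestNaturalCubicBasis:
    spec = BasisSpec("natural_cubic", knots=(3.0, 7.0), boundary=(0.0, 10.0))

    def test_df_matches_knot_count(self):
        x = np.linspace(0, 10, 40)
        assert natural_cubic_basis(x, self.spec).shape == (40, 3)
        with_icpt = BasisSpec("natural_cubic", knots=(3.0, 7.0),
                              boundary=(0.0, 10.0), intercept=True)
        assert natural_cubic_basis(x, with_icpt).shape == (40, 4)

    def test_linear_beyond_boundary_knots(self):
        # second differences vanish outside the boundary on both sides
        for xs in (np.array([10.5, 11.0, 11.5]), np.array([-2.0, -1.5, -1.0])):
            B = natural_cubic_basis(xs, self.spec)
            second = B[0] - 2 * B[1] + B[2]
            assert np.abs(second).max() < 1e-8

    def test_linear_functions_in_span(self):
        x = np.linspace(0, 10, 50)
        A = np.column_stack([np.ones(50), natural_cubic_basis(x, self.spec)])
        y = 2 * x + 1
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.abs(y - A @ coef).max() < 1e-10

    def test_continuous_second_derivative_at_knots(self):
        h = 1e-5
        for knot in self.spec.knots:
            pts = np.array([knot - 2 * h, knot - h, knot, knot + h, knot + 2 * h])
            B = natural_cubic_basis(pts, self.spec)
            left = (B[0] - 2 * B[1] + B[2]) / h**2
            right = (B[2] - 2 * B[3] + B[4]) / h**2
            assert np.abs(left - right).max() < 1e-3

    def test_span_matches_truncated_power_oracle(self):
        # same function space as the independent truncated-power natural
        # spline construction, inside and beyond the boundary knots
        x = np.concatenate([np.linspace(-3, 13, 60), self.spec.knots])
        mine = np.column_stack([np.ones_like(x),
                                natural_cubic_basis(x, self.spec)])
        oracle = ns_truncated_power(x, [0.0, 3.0, 7.0, 10.0])
        assert np.abs(hat(mine) - hat(oracle)).max() < 1e-8

    def test_nan_propagates(self):
        B = natural_cubic_basis(np.array([1.0, np.nan]), self.spec)
        assert np.isfinite(B[0]).all() and np.isnan(B[1]).all()

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            BasisSpec("natural_cubic", knots=(5.0,), boundary=(10.0, 0.0))
        with pytest.raises(ValueError):
            BasisSpec("natural_cubic", knots=(12.0,), boundary=(0.0, 10.0))
        with pytest.raises(ValueError):
            BasisSpec("cubic", knots=(), boundary=(0.0, 1.0))


class TestLogLagKnots:
    def test_closed_form(self):
        got = log_lag_knots(24, 3)
        expected = np.exp(np.arange(1, 4) * np.log(24) / 4)
        assert np.allclose(got, expected, rtol=0, atol=1e-12)

    def test_single_knot_is_sqrt_of_max_lag(self):
        assert log_lag_knots(24, 1)[0] == pytest.approx(np.sqrt(24), abs=1e-12)

    @pytest.mark.parametrize("L,n", [(24, 1), (24, 3), (48, 5), (36, 2)])
    def test_strictly_increasing_interior(self, L, n):
        k = log_lag_knots(L, n)
        assert np.all(np.diff(k) > 0) and k[0] > 0 and k[-1] < L

    def test_rejects_too_many_knots(self):
        with pytest.raises(ValueError):
            log_lag_knots(4, 4)


class TestCrossBasis:
    def test_dimensions_exposure_major(self):
        Q = np.random.default_rng(0).normal(15, 5, (7, 25))
        spec = BasisSpec.from_quantiles(Q.ravel(), df=3)
        cb = cross_basis(Q, spec, lag_basis_spec(24, 2))
        assert cb.W.shape == (7, 12) and cb.v_x == 3 and cb.v_l == 4

    def test_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        Q = rng.normal(10, 6, (5, 25))
        spec = BasisSpec.from_quantiles(Q.ravel(), df=3)
        lag_spec = lag_basis_spec(24, 2)
        cb = cross_basis(Q, spec, lag_spec)
        B = evaluate_basis(Q.ravel(), spec).reshape(5, 25, 3)
        C = evaluate_basis(np.arange(25.0), lag_spec)
        for i in range(5):
            for j in range(3):
                for k in range(4):
                    w = sum(B[i, l, j] * C[l, k] for l in range(25))
                    assert cb.W[i, j * 4 + k] == pytest.approx(w, abs=1e-12)

    def test_linear_exposure_constant_lag_collapses_to_window_sum(self):
        Q = np.arange(50.0).reshape(2, 25)
        cb = cross_basis(Q, BasisSpec("linear"), BasisSpec("constant"))
        assert cb.W.shape == (2, 1)
        assert np.allclose(cb.W[:, 0], Q.sum(axis=1))

    def test_additive_in_Q_for_linear_exposure_basis(self):
        rng = np.random.default_rng(5)
        Q1, Q2 = rng.normal(size=(2, 4, 25))
        lag_spec = lag_basis_spec(24, 2)
        lin = BasisSpec("linear")
        total = cross_basis(Q1 + Q2, lin, lag_spec).W
        parts = cross_basis(Q1, lin, lag_spec).W + cross_basis(Q2, lin, lag_spec).W
        assert np.allclose(total, parts, atol=1e-10)

    def test_masked_input_rejected(self):
        Q = np.ones((3, 25))
        Q[1, 5] = np.nan
        spec = BasisSpec("natural_cubic", knots=(0.4,), boundary=(0.0, 1.0))
        with pytest.raises(ValueError, match="masked"):
            cross_basis(Q, spec, lag_basis_spec(24, 2))


class TestAssembleDesign:
    def _cb(self, n, name, seed=0):
        rng = np.random.default_rng(seed)
        Q = rng.normal(15, 5, (n, 25))
        spec = BasisSpec.from_quantiles(Q.ravel(), df=3)
        return cross_basis(Q, spec, lag_basis_spec(24, 2), exposure_name=name)

    def test_block_arithmetic(self):
        t = self._cb(6, "temperature", 1)
        rh = self._cb(6, "relative_humidity", 2)
        d = assemble_design([t, rh])
        assert d.X.shape == (6, 24)
        d2 = assemble_design([t, rh], interaction_with=np.ones(6))
        assert d2.X.shape == (6, 36)
        assert d2.block("interaction") == slice(24, 36)

    def test_interaction_is_elementwise_product(self):
        t = self._cb(5, "temperature", 1)
        z = np.arange(5.0)
        d = assemble_design([t], interaction_with=z)
        assert np.allclose(d.X[:, d.block("interaction")], t.W * z[:, None])

    def test_misaligned_rows_rejected_with_block_name(self):
        t = self._cb(6, "temperature", 1)
        rh = self._cb(5, "relative_humidity", 2)
        with pytest.raises(ValueError, match="relative_humidity"):
            assemble_design([t, rh])
        with pytest.raises(ValueError, match="pollutants"):
            assemble_design([t], pollutants=np.ones((4, 2)))


def test_spec_serialization_round_trip():
    spec = BasisSpec("natural_cubic", knots=(2.0, 5.0), boundary=(0.0, 24.0),
                     intercept=True)
    assert BasisSpec.from_dict(spec.to_dict()) == spec
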