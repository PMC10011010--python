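import numpy as np
import pytest
import scipy.integrate
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.interpolate import BSpline

from mbebfda.basis import (
    DEFAULT_OMEGA,
    SmoothingError,
    harmonic_penalty,
    make_bspline_basis,
    penalized_smooth,
    select_lambda,
    smooth_sample,
)


def deboor_basis_value(knots, degree, j, x):
    """Independent Cox-de Boor recursion for one basis function value."""
    if degree == 0:
        if knots[j] <= x < knots[j + 1]:
            return 1.0
        # right-closed convention at the domain end (nonempty interval only)
        if knots[j] < knots[j + 1] == knots[-1] and x == knots[j + 1]:
            return 1.0
        return 0.0
    out = 0.0
    d1 = knots[j + degree] - knots[j]
    if d1 > 0:
        out += (x - knots[j]) / d1 * deboor_basis_value(knots, degree - 1, j, x)
    d2 = knots[j + degree + 1] - knots[j + 1]
    if d2 > 0:
        out += (
            (knots[j + degree + 1] - x) / d2 * deboor_basis_value(knots, degree - 1, j + 1, x)
        )
    return out


class TestBasisConstruction:
    def test_725_basis_functions(self):
        b = make_bspline_basis(720, 6, 1)
        assert len(b.breakpoints) == 721
        assert b.n_basis == 725

    def test_small_count_formula(self):
        b = make_bspline_basis(10, 4, 5)
        assert b.n_basis == 5  # 1 interior breakpoint + order 4

    def test_values_match_deboor_recursion(self):
        b = make_bspline_basis(10, 4, 2.5)
        xs = np.array([0.0, 0.7, 2.5, 3.3, 6.2, 9.1, 10.0])
        D = b.design_matrix(xs).toarray()
        knots = b.knots.astype(float)
        for xi, x in enumerate(xs):
            for j in range(b.n_basis):
                assert D[xi, j] == pytest.approx(
                    deboor_basis_value(knots, b.degree, j, x), abs=1e-12
                )

    def test_spacing_must_divide(self):
        with pytest.raises(ValueError):
            make_bspline_basis(10, 4, 3)

    def test_local_support(self):
        b = make_bspline_basis(100, 6, 10)
        D = b.design_matrix(np.linspace(0, 100, 501)).toarray()
        for j in range(b.n_basis):
            support = np.flatnonzero(D[:, j] > 1e-14)
            width = (support[-1] - support[0]) * 0.2
            assert width <= b.order * 10 + 1e-9

    def test_nonnegative(self):
        b = make_bspline_basis(720, 6, 20)
        D = b.design_matrix(np.linspace(0, 720, 333)).toarray()
        assert D.min() >= 0


@settings(max_examples=30, deadline=None)
@given(st.floats(0, 720))
def test_partition_of_unity(t):
    b = make_bspline_basis(720, 6, 30)
    total = b.design_matrix(np.array([t])).sum()
    assert total == pytest.approx(1.0, abs=1e-10)


@pytest.fixture(scope="module")
def hp_basis():
    return make_bspline_basis(720, 6, 30)


@pytest.fixture(scope="module")
def hp_penalty(hp_basis):
    return harmonic_penalty(hp_basis, DEFAULT_OMEGA)


class TestHarmonicPenalty:
    def _lsq_coef(self, basis, f):
        t = np.linspace(*basis.domain, 8 * basis.n_basis)
        Phi = basis.design_matrix(t).toarray()
        return np.linalg.lstsq(Phi, f(t), rcond=None)[0]

    def test_constant_in_null_space(self, hp_basis, hp_penalty):
        basis, penalty = hp_basis, hp_penalty
        ones = self._lsq_coef(basis, lambda t: np.ones_like(t))
        ref = self._lsq_coef(basis, lambda t: np.sin(2 * DEFAULT_OMEGA * t))
        assert penalty.quadratic_form(ones) < 1e-8 * penalty.quadratic_form(ref)

    def test_sin_cos_in_null_space(self):
        # fine spacing so sin(wt) is representable well below the contrast
        basis = make_bspline_basis(360, 6, 5)
        penalty = harmonic_penalty(basis, DEFAULT_OMEGA)
        w = penalty.omega
        ref = penalty.quadratic_form(self._lsq_coef(basis, lambda t: np.sin(2 * w * t)))
        for f in (lambda t: np.sin(w * t), lambda t: np.cos(w * t)):
            q = penalty.quadratic_form(self._lsq_coef(basis, f))
            assert q <= 1e-6 * ref

    def test_symmetric_psd(self, hp_penalty):
        penalty = hp_penalty
        R = penalty.matrix
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        evals = np.linalg.eigvalsh(R)
        assert evals.min() > -1e-8 * max(evals.max(), 1.0)

    def test_omega_zero_matches_independent_d3_quadrature(self):
        # oracle route: on each interval reconstruct every basis function as
        # a polynomial from plain (0th-order) evaluations, differentiate the
        # polynomial three times, and integrate products in closed form
        basis = make_bspline_basis(6, 5, 1)
        R = harmonic_penalty(basis, omega=0.0).matrix
        oracle = np.zeros_like(R)
        deg = basis.degree
        for a, b in zip(basis.breakpoints[:-1], basis.breakpoints[1:]):
            xs = np.linspace(a + 1e-9, b - 1e-9, deg + 3)
            V = basis.design_matrix(xs).toarray()
            d3 = []
            for j in range(basis.n_basis):
                p = np.polynomial.Polynomial.fit(xs, V[:, j], deg)
                d3.append(p.deriv(3))
            for j in range(basis.n_basis):
                for k in range(j, basis.n_basis):
                    prod = d3[j] * d3[k]
                    val = prod.integ()(b) - prod.integ()(a)
                    oracle[j, k] += val
                    if k != j:
                        oracle[k, j] += val
        scale = np.abs(oracle).max()
        np.testing.assert_allclose(R, oracle, atol=1e-8 * scale)

    def test_order_below_4_rejected(self):
        with pytest.raises(ValueError):
            harmonic_penalty(make_bspline_basis(10, 3, 1))

    def test_simpson_step_agrees_with_exact(self, hp_basis):
        basis = hp_basis
        exact = harmonic_penalty(basis, DEFAULT_OMEGA).matrix
        stepped = harmonic_penalty(basis, DEFAULT_OMEGA, quadrature_step_s=0.5).matrix
        assert np.abs(exact - stepped).max() < 1e-6 * np.abs(exact).max()


def _ridge_oracle(Phi, R, lam, y):
    """Generic ridge route: augmented least squares with sqrt(lam)*chol(R)."""
    w, V = np.linalg.eigh(R)
    w = np.maximum(w, 0.0)
    Rhalf = V @ np.diag(np.sqrt(w)) @ V.T
    A = np.vstack([Phi, np.sqrt(lam) * Rhalf])
    b = np.r_[y, np.zeros(R.shape[0])]
    return np.linalg.lstsq(A, b, rcond=None)[0]


@pytest.fixture(scope="module")
def setup():
    basis = make_bspline_basis(720, 6, 30)
    penalty = harmonic_penalty(basis)
    t = np.arange(0.0, 721.0, 3.0)
    return basis, penalty, t


@pytest.fixture(scope="module")
def fine_setup():
    # fine spacing: sin(wt) representable to well below 1e-6 relative
    basis = make_bspline_basis(360, 6, 5)
    penalty = harmonic_penalty(basis)
    t = np.arange(0.0, 361.0, 1.0)
    return basis, penalty, t


class TestPenalizedSmooth:
    def test_null_space_reproduced_any_lambda(self, fine_setup):
        basis, penalty, t = fine_setup
        w = penalty.omega
        y = 2.0 + 1.5 * np.sin(w * t) - 0.7 * np.cos(w * t)
        for lam in (1e-2, 1e4, 1e10):
            fit = penalized_smooth(t, y, basis, penalty, lam)
            yhat = fit(t)
            assert np.abs(yhat - y).max() < 1e-6 * np.abs(y).max()

    def test_huge_lambda_is_nullspace_projection(self):
        # scales chosen so lambda=1e12 dominates the data term by ~1e10
        # while staying clear of double-precision round-off in the solve
        w0 = 2 * np.pi / 112.5
        basis = make_bspline_basis(225, 6, 6.25)
        penalty = harmonic_penalty(basis, omega=w0)
        t = np.linspace(0.0, 225.0, 181)
        rng = np.random.default_rng(0)
        y = 5 + 2 * np.sin(3 * w0 * t) + rng.normal(0, 0.5, t.size)
        fit = penalized_smooth(t, y, basis, penalty, 1e12)
        X = np.column_stack([np.ones_like(t), np.sin(w0 * t), np.cos(w0 * t)])
        yref = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        data_range = y.max() - y.min()
        assert np.abs(fit(t) - yref).max() < 1e-4 * data_range

    def test_sse_minimal_at_lambda_zero(self, setup):
        basis, penalty, t = setup
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, t.size)
        sse0 = penalized_smooth(t, y, basis, penalty, 0.0).sse
        for lam in np.logspace(-2, 6, 9):
            assert sse0 <= penalized_smooth(t, y, basis, penalty, lam).sse + 1e-10

    def test_singular_at_zero_lambda_underdetermined(self):
        basis = make_bspline_basis(720, 6, 10)  # 77 basis functions
        penalty = harmonic_penalty(basis)
        t = np.linspace(0, 720, 20)
        y = np.sin(t / 50)
        with pytest.raises(SmoothingError, match="positive lambda"):
            penalized_smooth(t, y, basis, penalty, 0.0)

    def test_matches_generic_ridge_on_random_small_problems(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            order = int(rng.integers(4, 7))
            n_intervals = int(rng.integers(2, 9 - order + 4))
            n_basis_target = n_intervals + order - 1
            if n_basis_target > 12:
                continue
            t_end = float(rng.integers(5, 30))
            basis = make_bspline_basis(t_end, order, t_end / n_intervals)
            penalty = harmonic_penalty(basis, omega=float(rng.uniform(0.01, 0.5)))
            n = int(rng.integers(basis.n_basis, 41))
            t = np.sort(rng.uniform(0, t_end, n))
            y = rng.normal(0, 1, n)
            lam = float(10 ** rng.uniform(-3, 3))
            fit = penalized_smooth(t, y, basis, penalty, lam)
            Phi = basis.design_matrix(t).toarray()
            oracle = _ridge_oracle(Phi, penalty.matrix, lam, y)
            scale = np.abs(oracle).max() + 1.0
            np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-8 * scale)

    def test_df_full_rank_zero_lambda(self):
        basis = make_bspline_basis(10, 4, 2)
        penalty = harmonic_penalty(basis)
        t = np.linspace(0, 10, 40)
        y = np.sin(t)
        fit = penalized_smooth(t, y, basis, penalty, 0.0)
        assert fit.df == pytest.approx(basis.n_basis, abs=1e-8)

    def test_df_is_sum_of_hat_eigenvalues_and_gcv_two_ways(self):
        basis = make_bspline_basis(12, 4, 2)
        penalty = harmonic_penalty(basis)
        t = np.linspace(0, 12, 30)
        rng = np.random.default_rng(5)
        y = np.cos(t) + rng.normal(0, 0.1, t.size)
        lam = 3.7
        fit = penalized_smooth(t, y, basis, penalty, lam)
        Phi = basis.design_matrix(t).toarray()
        S = Phi @ np.linalg.solve(Phi.T @ Phi + lam * penalty.matrix, Phi.T)
        assert fit.df == pytest.approx(np.linalg.eigvals(S).real.sum(), abs=1e-10)
        resid = y - S @ y
        gcv_explicit = t.size * float(resid @ resid) / (t.size - np.trace(S)) ** 2
        assert fit.gcv == pytest.approx(gcv_explicit, rel=1e-10)

    def test_fitted_values_equal_phi_c(self, setup):
        basis, penalty, t = setup
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, t.size)
        fit = penalized_smooth(t, y, basis, penalty, 10.0)
        Phi = basis.design_matrix(t)
        np.testing.assert_allclose(fit(t), Phi @ fit.coefficients, atol=1e-12)

    def test_dense_and_banded_agree(self, setup):
        basis, penalty, t = setup
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, t.size)
        a = penalized_smooth(t, y, basis, penalty, 7.0, method="dense")
        b = penalized_smooth(t, y, basis, penalty, 7.0, method="banded")
        scale = np.abs(a.coefficients).max() + 1.0
        np.testing.assert_allclose(a.coefficients, b.coefficients, atol=1e-8 * scale)
        assert a.df == pytest.approx(b.df, abs=1e-8)


@pytest.fixture(scope="module")
def sel_setup():
    basis = make_bspline_basis(360, 6, 15)
    penalty = harmonic_penalty(basis, DEFAULT_OMEGA)
    t = np.arange(0.0, 361.0, 2.0)
    return basis, penalty, t


class TestSelectLambda:
    def test_noise_free_nullspace_ties_to_largest(self, sel_setup):
        basis, penalty, t = sel_setup
        w = penalty.omega
        y = 1.0 + 0.5 * np.sin(w * t)
        grid = np.logspace(-2, 6, 9)
        fit, table = select_lambda(t, y, basis, penalty, grid)
        assert fit.lam == pytest.approx(grid.max())

    def test_df_nonincreasing_in_lambda(self, sel_setup):
        basis, penalty, t = sel_setup
        rng = np.random.default_rng(3)
        y = np.sin(t / 40.0) + rng.normal(0, 0.2, t.size)
        _, table = select_lambda(t, y, basis, penalty, np.logspace(-2, 6, 17))
        df = table["df"].to_numpy()
        assert np.all(np.diff(df) <= 1e-8)

    def test_selected_beats_grid_extremes(self, sel_setup):
        basis, penalty, t = sel_setup
        rng = np.random.default_rng(12)
        truth = 40 * np.sin(t / 50.0) + 10 * np.cos(t / 11.0)
        y = truth + rng.normal(0, 5.0, t.size)
        grid = np.logspace(-2, 8, 21)
        fit, _ = select_lambda(t, y, basis, penalty, grid)
        rmse = lambda f: float(np.sqrt(np.mean((f(t) - truth) ** 2)))
        lo = penalized_smooth(t, y, basis, penalty, grid[0])
        hi = penalized_smooth(t, y, basis, penalty, grid[-1])
        assert rmse(fit) <= rmse(lo) + 1e-12
        assert rmse(fit) <= rmse(hi) + 1e-12

    def test_table_has_all_lambdas(self, sel_setup):
        basis, penalty, t = sel_setup
        y = np.sin(t / 30.0)
        grid = np.logspace(0, 4, 5)
        _, table = select_lambda(t, y, basis, penalty, grid)
        np.testing.assert_allclose(sorted(table["lambda"]), sorted(grid))

    def test_empty_grid_rejected(self, sel_setup):
        basis, penalty, t = sel_setup
        with pytest.raises(ValueError):
            select_lambda(t, np.sin(t), basis, penalty, np.array([]))


class TestSmoothSample:
    def test_cohort_78_curves_on_725_basis(self, grid721):
        basis = make_bspline_basis(720, 6, 1)
        assert basis.n_basis == 725
        penalty = harmonic_penalty(basis)
        rng = np.random.default_rng(0)
        t = grid721
        Y = np.vstack(
            [100 + 30 * np.sin(t / 40 + rng.normal()) + rng.normal(0, 2, t.size) for _ in range(78)]
        )
        fs = smooth_sample(t, Y, basis, penalty, np.logspace(1, 4, 4))
        assert fs.n_curves == 78
        assert fs.coefficients.shape == (78, 725)
        assert np.unique(fs.lam).size == 1  # shared lambda per signal

    def test_single_curve_matches_select_lambda(self, small_basis, small_penalty, grid721):
        rng = np.random.default_rng(8)
        y = 50 + 10 * np.sin(grid721 / 60) + rng.normal(0, 1, grid721.size)
        grid = np.logspace(-1, 5, 7)
        fit, _ = select_lambda(grid721, y, small_basis, small_penalty, grid)
        fs = smooth_sample(grid721, y[None, :], small_basis, small_penalty, grid)
        assert fs.lam[0] == pytest.approx(fit.lam)
        np.testing.assert_allclose(fs.coefficients[0], fit.coefficients, atol=1e-10)

    def test_deterministic(self, small_basis, small_penalty, grid721):
        rng = np.random.default_rng(4)
        Y = rng.normal(60, 5, (5, grid721.size))
        g = np.logspace(0, 4, 5)
        a = smooth_sample(grid721, Y, small_basis, small_penalty, g)
        b = smooth_sample(grid721, Y, small_basis, small_penalty, g)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        assert a.lam[0] == b.lam[0]

    def test_evaluate_shape(self, small_basis, small_penalty, grid721):
        Y = np.vstack([np.sin(grid721 / 60), np.cos(grid721 / 60)])
        fs = smooth_sample(grid721, Y, small_basis, small_penalty, np.array([1.0]))
        out = fs.evaluate(np.linspace(0, 720, 33))
        assert out.shape == (2, 33)
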