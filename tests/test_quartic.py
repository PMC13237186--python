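import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import AXIAL, BVALUE, ISO, RADIAL, random_quartic_coefficients
from finslermri import (FitOptions, GradientTable, QuarticTensor,
                        evaluate_quartic, fit_quartic_tensor, fit_quartic_field,
                        gradient_table, monomial_design_matrix,
                        symmetrized_square, uniform_directions)
from finslermri.phantom import canonical_group_config, multi_fiber_signal
from finslermri.quartic import (MONOMIAL_EXPONENTS, MULTIPLICITIES,
                                SingularFitError, dump_coefficients,
                                floor_signals)


def brute_force_quartic(coeffs, y):
    """Independent oracle: full 81-term sum over all index quadruples."""
    full = np.zeros((3, 3, 3, 3))
    for m, (a, b, c) in enumerate(MONOMIAL_EXPONENTS):
        base = (0,) * a + (1,) * b + (2,) * c
        for quad in set(itertools.permutations(base)):
            full[quad] = coeffs[m]
    total = 0.0
    for i, j, k, l in itertools.product(range(3), repeat=4):
        total += full[i, j, k, l] * y[i] * y[j] * y[k] * y[l]
    return total


class TestMonomialConvention:
    def test_multiplicities_are_multinomial_counts(self):
        assert list(MULTIPLICITIES) == [1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12]

    @pytest.mark.parametrize("axis,column", [(0, 0), (1, 1), (2, 2)])
    def test_axis_direction_activates_single_monomial(self, axis, column):
        row = monomial_design_matrix(np.eye(3)[axis][None])[0]
        expected = np.zeros(15)
        expected[column] = 1.0
        np.testing.assert_array_equal(row, expected)

    def test_design_row_equals_brute_force_form(self, rng):
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            coeffs = random_quartic_coefficients(rng)
            row = monomial_design_matrix(v[None])[0]
            assert row @ coeffs == pytest.approx(brute_force_quartic(coeffs, v),
                                                 rel=1e-12)

    def test_design_matrix_rejects_non_unit(self):
        with pytest.raises(ValueError, match="unit"):
            monomial_design_matrix(np.array([[2.0, 0.0, 0.0]]))


class TestEvaluateQuartic:
    def test_isotropic_profile_value(self):
        iso = QuarticTensor.isotropic(ISO)
        assert evaluate_quartic(iso, np.array([1.0, 0.0, 0.0])) == pytest.approx(ISO)

    def test_symmetrized_square_at_eigenvector(self):
        t = symmetrized_square(np.diag([AXIAL, RADIAL, RADIAL]))
        assert evaluate_quartic(t, np.array([1.0, 0.0, 0.0])) == \
            pytest.approx(AXIAL ** 2)  # 2.89e-6

    def test_matches_brute_force_expansion(self, rng):
        y = np.array([0.6, 0.8, 0.0])
        for _ in range(10):
            coeffs = random_quartic_coefficients(rng)
            assert evaluate_quartic(QuarticTensor(coeffs), y) == \
                pytest.approx(brute_force_quartic(coeffs, y), rel=1e-12)

    @given(s=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_degree_four_homogeneity(self, s):
        rng = np.random.default_rng(5)
        t = QuarticTensor(random_quartic_coefficients(rng))
        y = np.array([0.3, -0.5, 0.81])
        assert evaluate_quartic(t, s * y) == \
            pytest.approx(s ** 4 * evaluate_quartic(t, y), rel=1e-10)

    def test_full_tensor_round_trip(self, rng):
        coeffs = random_quartic_coefficients(rng)
        t = QuarticTensor(coeffs)
        back = QuarticTensor.from_full(t.to_full())
        np.testing.assert_allclose(back.coefficients, coeffs, rtol=1e-14)
        # full tensor is totally symmetric
        full = t.to_full()
        for perm in itertools.permutations(range(4)):
            np.testing.assert_array_equal(full, np.transpose(full, perm))


class TestSymmetrizedSquare:
    def test_identity_gives_norm_fourth(self):
        t = symmetrized_square(np.eye(3))
        y = np.array([0.3, 1.2, -0.7])
        assert evaluate_quartic(t, y) == pytest.approx(np.sum(y * y) ** 2, rel=1e-12)

    def test_diag_321_on_diagonal_direction(self):
        t = symmetrized_square(np.diag([3.0, 2.0, 1.0]))
        y = np.ones(3) / np.sqrt(3)
        assert evaluate_quartic(t, y) == pytest.approx(4.0, rel=1e-12)

    def test_square_identity_on_random_probes(self, rng):
        a = rng.normal(size=(3, 3))
        d2 = (a + a.T) / 2
        t = symmetrized_square(d2)
        for _ in range(100):
            y = rng.normal(size=3)
            assert evaluate_quartic(t, y) == pytest.approx((y @ d2 @ y) ** 2,
                                                           rel=1e-12, abs=1e-15)


class TestFit:
    def test_isotropic_exact_recovery(self, gtab81, dirs81):
        signals = np.exp(-gtab81.bvalues * ISO)
        t = fit_quartic_tensor(signals, 1.0, gtab81, FitOptions(0.0))
        q = evaluate_quartic(t, dirs81.vectors)
        np.testing.assert_allclose(q, ISO, atol=1e-9)

    def test_linearity_recovers_generating_coefficients(self, gtab81, rng):
        # strictly positive quartic profile so the log-signal model is exact
        a = rng.normal(size=(3, 3))
        true = symmetrized_square(2e-2 * (a @ a.T + 0.5 * np.eye(3))).coefficients
        adc = monomial_design_matrix(gtab81) @ true
        signals = np.exp(-gtab81.bvalues * adc)
        fit = fit_quartic_tensor(signals, 1.0, gtab81, FitOptions(0.0))
        np.testing.assert_allclose(fit.coefficients, true, rtol=1e-8)

    def test_huge_lambda_shrinks_to_zero(self, gtab81):
        signals = np.exp(-gtab81.bvalues * ISO)
        t = fit_quartic_tensor(signals, 1.0, gtab81, FitOptions(1e9))
        np.testing.assert_allclose(t.coefficients, 0.0, atol=1e-6)

    def test_matches_independent_normal_equations(self, gtab81):
        config = canonical_group_config("two_orthogonal")
        signals = multi_fiber_signal(config, gtab81)
        fit = fit_quartic_tensor(signals, 1.0, gtab81, FitOptions(0.0))
        A = monomial_design_matrix(gtab81)
        adc = -np.log(signals) / gtab81.bvalues
        oracle = np.linalg.solve(A.T @ A, A.T @ adc)
        res_fit = adc - A @ fit.coefficients
        res_oracle = adc - A @ oracle
        assert np.linalg.norm(res_fit) == pytest.approx(np.linalg.norm(res_oracle),
                                                        abs=1e-10)

    def test_rotation_equivariance(self, gtab81, rng):
        """Fitting rotated signals equals rotating the fitted tensor."""
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(3, 3))
        true = symmetrized_square(2e-2 * (a @ a.T + 0.5 * np.eye(3)))
        R = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        A = monomial_design_matrix(gtab81)
        sig = np.exp(-gtab81.bvalues * (A @ true.coefficients))
        sig_rot = np.exp(-gtab81.bvalues * (A @ true.rotate(R).coefficients))
        t_plain = fit_quartic_tensor(sig, 1.0, gtab81, FitOptions(0.0))
        t_rot = fit_quartic_tensor(sig_rot, 1.0, gtab81, FitOptions(0.0))
        probes = rng.normal(size=(25, 3))
        probes /= np.linalg.norm(probes, axis=1, keepdims=True)
        q_rot = evaluate_quartic(t_rot, (R @ probes.T).T)
        q_plain = evaluate_quartic(t_plain, probes)
        np.testing.assert_allclose(q_rot, q_plain, rtol=1e-6)

    def test_monotone_ridge_shrinkage(self, gtab81, rng):
        signals = floor_signals(multi_fiber_signal(
            canonical_group_config("two_orthogonal"), gtab81)
            + rng.normal(0, 0.02, gtab81.count))
        norms = [np.linalg.norm(
            fit_quartic_tensor(signals, 1.0, gtab81, FitOptions(lam)).coefficients)
            for lam in (0.0, 1e-3, 1e-1, 10.0)]
        assert np.all(np.diff(norms) <= 1e-15)

    def test_rejects_nonpositive_signals(self, gtab81):
        signals = np.ones(gtab81.count)
        signals[3] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_quartic_tensor(signals, 1.0, gtab81)

    def test_rejects_too_few_directions(self):
        gtab = gradient_table(uniform_directions(10), BVALUE)
        with pytest.raises(ValueError, match="15"):
            fit_quartic_tensor(np.ones(10), 1.0, gtab)

    def test_rank_deficient_unregularized_raises(self):
        # coplanar directions cannot identify z-bearing monomials
        phi = np.linspace(0, np.pi, 20, endpoint=False)
        dirs = np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])
        gtab = GradientTable(dirs, np.full(20, BVALUE))
        with pytest.raises(SingularFitError):
            fit_quartic_tensor(np.full(20, 0.5), 1.0, gtab, FitOptions(0.0))

    def test_field_fit_matches_single_voxel(self, gtab81, rng):
        signals = floor_signals(
            np.stack([multi_fiber_signal(canonical_group_config(g), gtab81)
                      for g in ("one_fiber", "two_orthogonal")])
            + rng.normal(0, 0.01, (2, gtab81.count)))
        field = fit_quartic_field(signals, 1.0, gtab81, FitOptions(0.01))
        for row, sig in zip(field, signals):
            single = fit_quartic_tensor(sig, 1.0, gtab81, FitOptions(0.01))
            np.testing.assert_allclose(row, single.coefficients, rtol=1e-10)


def test_coefficient_dump_round_trip(tmp_path, rng):
    coeffs = np.stack([random_quartic_coefficients(rng) for _ in range(4)])
    path = tmp_path / "coeffs.txt"
    dump_coefficients(coeffs, path)
    text = path.read_text()
    assert "D400" in text and "D112" in text  # header names exponent triples
    back = np.loadtxt(path)
    np.testing.assert_allclose(back, coeffs, rtol=1e-6)
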