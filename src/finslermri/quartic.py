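"""Fourth-order (quartic) diffusion tensor: representation, evaluation, fitting.

A totally symmetric 4th-order tensor D_ijkl has 15 unique components.  The
directional apparent diffusion coefficient (ADC) profile is the homogeneous
quartic form

    Q(y) = D_ijkl y^i y^j y^k y^l  =  sum_m  mult_m * c_m * x^a y^b z^c

where the sum runs over the 15 monomials x^a y^b z^c with a+b+c = 4, c_m is
the unique tensor component for that exponent triple and mult_m = 4!/(a!b!c!)
counts the index quadruples collapsing onto it.

Monomial order (fixed convention, used by every coefficient dump):
400 040 004 310 301 130 031 103 013 220 202 022 211 121 112
with multiplicities 1 1 1 4 4 4 4 4 4 6 6 6 12 12 12.

Fitting is linear least squares of the quartic form against per-direction
ADC values -ln(S/S0)/b, optionally with an identity (ridge) Tikhonov penalty
on the 15 coefficients.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .gradients import GradientTable, _as_direction_array

#: exponent triples (a, b, c) of x^a y^b z^c, a+b+c = 4, in the fixed order
MONOMIAL_EXPONENTS: tuple[tuple[int, int, int], ...] = (
    (4, 0, 0), (0, 4, 0), (0, 0, 4),
    (3, 1, 0), (3, 0, 1), (1, 3, 0), (0, 3, 1), (1, 0, 3), (0, 1, 3),
    (2, 2, 0), (2, 0, 2), (0, 2, 2),
    (2, 1, 1), (1, 2, 1), (1, 1, 2),
)

#: multinomial multiplicities 4!/(a!b!c!) matching MONOMIAL_EXPONENTS
MULTIPLICITIES = np.array(
    [math.factorial(4) // (math.factorial(a) * math.factorial(b) * math.factorial(c))
     for a, b, c in MONOMIAL_EXPONENTS],
    dtype=float,
)

_EXP = np.array(MONOMIAL_EXPONENTS, dtype=int)  # (15, 3)


def _index_quadruples():
    """For each monomial class, the distinct index quadruples (i,j,k,l)."""
    classes = []
    for a, b, c in MONOMIAL_EXPONENTS:
        base = (0,) * a + (1,) * b + (2,) * c
        classes.append(sorted(set(itertools.permutations(base))))
    return classes


_QUAD_CLASSES = _index_quadruples()


class SingularFitError(np.linalg.LinAlgError):
    """Raised when an unregularized fit meets a rank-deficient design."""


@dataclass(frozen=True)
class FitOptions:
    """Options for the quartic least-squares fit.

    tikhonov_lambda
        Nonnegative ridge weight on the 15-coefficient vector (identity
        penalty, no column scaling of the design).
    clamp_epsilon
        Floor applied downstream to nonpositive quartic values before the
        fourth root / metric computation.
    """

    tikhonov_lambda: float = 0.0
    clamp_epsilon: float = 1e-12

    def __post_init__(self):
        if self.tikhonov_lambda < 0:
            raise ValueError("tikhonov_lambda must be >= 0")
        if self.clamp_epsilon <= 0:
            raise ValueError("clamp_epsilon must be > 0")


class QuarticTensor:
    """The 15 unique components of a totally symmetric 4th-order tensor.

    Components are stored in the fixed monomial order of
    :data:`MONOMIAL_EXPONENTS`; units are mm^2/s when the tensor models an
    ADC profile on unit vectors.
    """

    __slots__ = ("coefficients",)

    def __init__(self, coefficients):
        coeffs = np.asarray(coefficients, dtype=float)
        if coeffs.shape != (15,):
            raise ValueError(f"expected 15 coefficients, got shape {coeffs.shape}")
        self.coefficients = coeffs

    def __repr__(self):  # pragma: no cover
        return f"QuarticTensor({np.array2string(self.coefficients, precision=4)})"

    def to_full(self) -> np.ndarray:
        """Expand to the full symmetric (3,3,3,3) component array."""
        return coefficients_to_full(self.coefficients)

    @classmethod
    def from_full(cls, full: np.ndarray) -> "QuarticTensor":
        """Extract the 15 unique components of a symmetric (3,3,3,3) array."""
        full = np.asarray(full, dtype=float)
        coeffs = np.array([full[c[0]] for c in _QUAD_CLASSES])
        return cls(coeffs)

    @classmethod
    def isotropic(cls, diffusivity: float) -> "QuarticTensor":
        """Tensor with Q(y) = d * ||y||^4 (constant profile d on unit vectors)."""
        return symmetrized_square(np.eye(3) * np.sqrt(diffusivity))

    def evaluate(self, y) -> float | np.ndarray:
        return evaluate_quartic(self, y)

    def rotate(self, rotation: np.ndarray) -> "QuarticTensor":
        """Tensor of the rotated profile: Q'(y) = Q(R^T y)."""
        R = np.asarray(rotation, dtype=float)
        full = np.einsum("ia,jb,kc,ld,abcd->ijkl", R, R, R, R, self.to_full())
        return QuarticTensor.from_full(full)


def coefficients_to_full(coefficients: np.ndarray) -> np.ndarray:
    """Expand (..., 15) coefficient arrays to full (..., 3, 3, 3, 3) tensors."""
    coeffs = np.asarray(coefficients, dtype=float)
    full = np.zeros(coeffs.shape[:-1] + (3, 3, 3, 3))
    for m, quads in enumerate(_QUAD_CLASSES):
        for i, j, k, l in quads:
            full[..., i, j, k, l] = coeffs[..., m]
    return full


def _monomials(y: np.ndarray) -> np.ndarray:
    """(..., 15) array of x^a y^b z^c for points y (..., 3)."""
    y = np.asarray(y, dtype=float)
    return (
        y[..., None, 0] ** _EXP[:, 0]
        * y[..., None, 1] ** _EXP[:, 1]
        * y[..., None, 2] ** _EXP[:, 2]
    )


def evaluate_quartic(tensor: QuarticTensor | np.ndarray, y) -> float | np.ndarray:
    """Q(y) = D_ijkl y^i y^j y^k y^l; homogeneous of degree 4 (y need not be unit)."""
    coeffs = tensor.coefficients if isinstance(tensor, QuarticTensor) else np.asarray(tensor)
    vals = _monomials(y) @ (MULTIPLICITIES * coeffs)
    if np.ndim(y) == 1:
        return float(vals)
    return vals


def monomial_design_matrix(gtab: GradientTable | np.ndarray) -> np.ndarray:
    """(count, 15) design matrix A with A[s, m] = mult_m * v_s^(a,b,c).

    The row-coefficient dot product equals the quartic form at v_s exactly.
    """
    dirs = gtab.directions if isinstance(gtab, GradientTable) else _as_direction_array(gtab)
    return _monomials(dirs) * MULTIPLICITIES


def symmetrized_square(d2: np.ndarray) -> QuarticTensor:
    """Unique totally symmetric quartic tensor with Q(y) = (y^T D2 y)^2.

    Useful as an exact-reduction oracle: for these tensors the Finsler
    metric equals D2 at every direction.
    """
    d2 = np.asarray(d2, dtype=float)
    if d2.shape != (3, 3) or not np.allclose(d2, d2.T, atol=1e-12):
        raise ValueError("d2 must be a symmetric 3x3 matrix")
    # polynomial square: quadratic monomial coefficients of y^T D2 y
    quad = {
        (2, 0, 0): d2[0, 0], (0, 2, 0): d2[1, 1], (0, 0, 2): d2[2, 2],
        (1, 1, 0): 2 * d2[0, 1], (1, 0, 1): 2 * d2[0, 2], (0, 1, 1): 2 * d2[1, 2],
    }
    quartic: dict[tuple[int, int, int], float] = {}
    for e1, c1 in quad.items():
        for e2, c2 in quad.items():
            e = (e1[0] + e2[0], e1[1] + e2[1], e1[2] + e2[2])
            quartic[e] = quartic.get(e, 0.0) + c1 * c2
    coeffs = np.array([quartic.get(e, 0.0) for e in MONOMIAL_EXPONENTS]) / MULTIPLICITIES
    return QuarticTensor(coeffs)


def signals_to_adc(signals, s0, gtab: GradientTable) -> np.ndarray:
    """Per-direction apparent diffusion coefficients -ln(S/S0)/b."""
    signals = np.asarray(signals, dtype=float)
    if np.any(signals <= 0):
        raise ValueError(
            "signals must be strictly positive; floor noisy magnitudes "
            "(e.g. with floor_signals) before fitting"
        )
    if np.ndim(s0) == 0 and float(np.asarray(s0)) <= 0:
        raise ValueError("s0 must be > 0")
    return -np.log(signals / s0) / gtab.bvalues


def floor_signals(signals, s0=1.0, floor_frac: float = 1e-6) -> np.ndarray:
    """Floor nonpositive/tiny magnitudes at floor_frac * S0 before the log."""
    return np.maximum(np.asarray(signals, dtype=float), floor_frac * np.asarray(s0))


def _solve_ridge(A: np.ndarray, rhs: np.ndarray, lam: float) -> np.ndarray:
    """argmin ||A d - rhs||^2 + lam ||d||^2 for rhs of shape (..., count)."""
    if lam > 0:
        gram = A.T @ A + lam * np.eye(A.shape[1])
        return np.linalg.solve(gram, (rhs @ A)[..., None])[..., 0]
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise SingularFitError(
            "design matrix is rank-deficient; add directions or use "
            "tikhonov_lambda > 0"
        )
    sol, *_ = np.linalg.lstsq(A, rhs.reshape(-1, rhs.shape[-1]).T, rcond=None)
    return sol.T.reshape(rhs.shape[:-1] + (A.shape[1],))


def fit_quartic_tensor(signals, s0, gtab: GradientTable,
                       opts: FitOptions | None = None) -> QuarticTensor:
    """Least-squares quartic tensor from one voxel's diffusion-weighted signals.

    Fits the quartic ADC profile to adc_s = -ln(S_s/S0)/b_s; with
    tikhonov_lambda = 0 and a full-rank design this is ordinary least squares.
    """
    opts = opts or FitOptions()
    signals = np.asarray(signals, dtype=float)
    if signals.ndim != 1:
        raise ValueError("fit_quartic_tensor expects one voxel; use fit_quartic_field")
    if gtab.count < 15:
        raise ValueError(f"need >= 15 gradient directions, got {gtab.count}")
    adc = signals_to_adc(signals, s0, gtab)
    A = monomial_design_matrix(gtab)
    return QuarticTensor(_solve_ridge(A, adc, opts.tikhonov_lambda))


def fit_quartic_field(signals, s0, gtab: GradientTable,
                      opts: FitOptions | None = None) -> np.ndarray:
    """Vectorized fit: signals (..., count) -> coefficients (..., 15)."""
    opts = opts or FitOptions()
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != gtab.count:
        raise ValueError(
            f"last signal axis ({signals.shape[-1]}) must match gradient "
            f"count ({gtab.count})"
        )
    if gtab.count < 15:
        raise ValueError(f"need >= 15 gradient directions, got {gtab.count}")
    adc = signals_to_adc(signals, s0, gtab)
    A = monomial_design_matrix(gtab)
    return _solve_ridge(A, adc, opts.tikhonov_lambda)


def dump_coefficients(coefficients: np.ndarray, path) -> None:
    """Plain-text coefficient table, one voxel per row, 15 columns.

    Column order is the fixed monomial convention; the header names the
    exponent triples.
    """
    coeffs = np.asarray(coefficients, dtype=float).reshape(-1, 15)
    header = (
        "quartic tensor components D_(abc) in fixed monomial order "
        "(exponents of x,y,z summing to 4); multiplicities "
        + " ".join(str(int(m)) for m in MULTIPLICITIES)
        + "\n" + " ".join(f"D{a}{b}{c}" for a, b, c in MONOMIAL_EXPONENTS)
    )
    np.savetxt(path, coeffs, header=header)
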