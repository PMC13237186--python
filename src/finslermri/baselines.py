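"""Baseline anisotropy scalars computed from the quartic ADC profile.

Both baselines sample the quartic form on a direction set and summarize the
profile: generalized anisotropy (GA) maps the variance of normalized
diffusivities through a saturating transform, and generalized fractional
anisotropy (GFA) is the std/rms ratio of the profile.  Both live in [0, 1]
and share the quartic tensor pipeline with FFA, so all scalars compare the
same fitted model.
"""
from __future__ import annotations

import numpy as np

from .finsler import ScalarMap, ffa
from .gradients import DirectionSet
from .quartic import QuarticTensor, monomial_design_matrix

MIN_PROFILE_SAMPLES = 15


def adc_profile(tensor, dirs: DirectionSet) -> np.ndarray:
    """Quartic-form samples Q(v_s) for tensors (..., 15) or a QuarticTensor."""
    coeffs = tensor.coefficients if isinstance(tensor, QuarticTensor) else np.asarray(tensor)
    return coeffs @ monomial_design_matrix(dirs.vectors).T


def _check_dirs(dirs: DirectionSet):
    if dirs.p < MIN_PROFILE_SAMPLES:
        raise ValueError(f"profile scalars need >= {MIN_PROFILE_SAMPLES} directions")


def _ga_from_profile(psi: np.ndarray) -> np.ndarray:
    mean = psi.mean(axis=-1)
    ok = mean > 0
    safe_mean = np.where(ok, mean, 1.0)
    v = np.var(psi / safe_mean[..., None], axis=-1)
    # saturating variance map: GA = 1 - 1/(1 + (250 V)^eps(V)),
    # eps(V) = 1 + 1/(1 + 5000 V)
    eps = 1.0 + 1.0 / (1.0 + 5000.0 * v)
    ga = 1.0 - 1.0 / (1.0 + (250.0 * v) ** eps)
    return np.clip(np.where(ok, ga, 0.0), 0.0, 1.0)


def _gfa_from_profile(psi: np.ndarray) -> np.ndarray:
    n = psi.shape[-1]
    sumsq = np.sum(psi * psi, axis=-1)
    ok = sumsq > 0
    num = n * np.sum((psi - psi.mean(axis=-1, keepdims=True)) ** 2, axis=-1)
    gfa = np.sqrt(num / ((n - 1) * np.where(ok, sumsq, 1.0)))
    return np.clip(np.where(ok, gfa, 0.0), 0.0, 1.0)


def generalized_anisotropy(tensor: QuarticTensor, dirs: DirectionSet) -> float:
    """GA of the sampled ADC profile, in [0, 1]; 0 for a flat (isotropic) profile."""
    _check_dirs(dirs)
    return float(_ga_from_profile(adc_profile(tensor, dirs)))


def generalized_fractional_anisotropy(tensor: QuarticTensor, dirs: DirectionSet) -> float:
    """GFA = std/rms of the sampled ADC profile, in [0, 1]."""
    _check_dirs(dirs)
    return float(_gfa_from_profile(adc_profile(tensor, dirs)))


def ga_map(tensor_field, dirs: DirectionSet, affine=None) -> ScalarMap:
    _check_dirs(dirs)
    psi = adc_profile(tensor_field, dirs)
    return ScalarMap(_ga_from_profile(psi), affine=np.eye(4) if affine is None else affine)


def gfa_map(tensor_field, dirs: DirectionSet, affine=None) -> ScalarMap:
    _check_dirs(dirs)
    psi = adc_profile(tensor_field, dirs)
    return ScalarMap(_gfa_from_profile(psi), affine=np.eye(4) if affine is None else affine)


# Registry of per-voxel scalar descriptors, so additional higher-order
# measures (e.g. Kelvin-invariant scalars) can be plugged in later.
SCALAR_REGISTRY = {
    "ffa": ffa,
    "ga": generalized_anisotropy,
    "gfa": generalized_fractional_anisotropy,
}


def register_scalar(name: str, func) -> None:
    """Register a scalar descriptor func(tensor, dirs) -> float."""
    if not callable(func):
        raise TypeError("func must be callable")
    SCALAR_REGISTRY[name] = func


def compute_scalar(name: str, tensor: QuarticTensor, dirs: DirectionSet) -> float:
    try:
        func = SCALAR_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown scalar {name!r}; registered: {sorted(SCALAR_REGISTRY)}")
    return float(func(tensor, dirs))
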