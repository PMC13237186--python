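"""Sampling geometry: gradient tables and unit-direction sets.

Diffusion MRI signals are antipodally symmetric (the signal for gradient g
equals the signal for -g), so direction sets keep one representative per
antipodal pair.  The deterministic spherical-Fibonacci lattice is used for
all synthetic sampling schemes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: tolerance on unit-norm directions
UNIT_TOL = 1e-6
#: angular tolerance (rad) below which two directions count as duplicates
ANTIPODAL_TOL_RAD = 1e-6


def _as_direction_array(directions, name: str = "directions") -> np.ndarray:
    arr = np.atleast_2d(np.asarray(directions, dtype=float))
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{name} must be an (n, 3) array, got shape {arr.shape}")
    norms = np.linalg.norm(arr, axis=1)
    if np.any(np.abs(norms - 1.0) > UNIT_TOL):
        bad = int(np.argmax(np.abs(norms - 1.0)))
        raise ValueError(
            f"{name}[{bad}] has norm {norms[bad]:.8f}; all directions must be "
            f"unit vectors within {UNIT_TOL:g}"
        )
    return arr


def _check_no_antipodal_duplicates(dirs: np.ndarray, tol_rad: float = ANTIPODAL_TOL_RAD):
    # |u.v| ~ 1 means u ~ +/- v; duplicates collapse under antipodal symmetry
    gram = np.abs(dirs @ dirs.T)
    np.fill_diagonal(gram, 0.0)
    limit = np.cos(tol_rad)
    if np.any(gram > limit):
        i, j = np.unravel_index(int(np.argmax(gram)), gram.shape)
        raise ValueError(
            f"directions {i} and {j} are duplicates up to antipodal symmetry "
            f"(|dot| = {gram[i, j]:.12f})"
        )


@dataclass(frozen=True)
class GradientTable:
    """Unit gradient directions with per-direction b-values (s/mm^2).

    Stores one representative per antipodal pair; construction rejects
    duplicate or antipodal-duplicate directions.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self):
        dirs = _as_direction_array(self.directions)
        bvals = np.atleast_1d(np.asarray(self.bvalues, dtype=float))
        if len(dirs) != len(bvals):
            raise ValueError(
                f"directions ({len(dirs)}) and bvalues ({len(bvals)}) must have "
                "equal length"
            )
        _check_no_antipodal_duplicates(dirs)
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "bvalues", bvals)

    @property
    def count(self) -> int:
        return len(self.directions)


@dataclass(frozen=True)
class DirectionSet:
    """Unit vectors used to sample the direction argument of the Finsler metric,
    one representative per antipodal pair."""

    vectors: np.ndarray

    def __post_init__(self):
        vecs = _as_direction_array(self.vectors, name="vectors")
        if len(vecs) < 1:
            raise ValueError("a DirectionSet needs at least one vector")
        object.__setattr__(self, "vectors", vecs)

    @property
    def p(self) -> int:
        return len(self.vectors)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic points on the unit sphere (spherical-Fibonacci lattice)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden angle
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def uniform_directions(n: int, antipodal_dedup: bool = True) -> DirectionSet:
    """Deterministic, near-uniform set of ``n`` unit directions.

    With ``antipodal_dedup`` (the default) a 2n-point full-sphere lattice is
    built and the upper hemisphere kept, yielding exactly n representatives,
    one per antipodal pair.
    """
    if antipodal_dedup:
        pts = _fibonacci_sphere(2 * n)
        pts = pts[pts[:, 2] > 0.0]
        assert len(pts) == n
    else:
        pts = _fibonacci_sphere(n)
    return DirectionSet(pts)


def gradient_table(directions, bvalue: float = 1500.0) -> GradientTable:
    """Gradient table with a single shared b-value (s/mm^2)."""
    if isinstance(directions, DirectionSet):
        dirs = directions.vectors
    else:
        dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    return GradientTable(dirs, np.full(len(dirs), float(bvalue)))


def direction_fingerprint(dirs: DirectionSet | np.ndarray) -> str:
    """Short stable hash of a direction set, for run logging."""
    import hashlib

    vecs = dirs.vectors if isinstance(dirs, DirectionSet) else np.asarray(dirs)
    payload = np.round(np.asarray(vecs, dtype=float), 12).tobytes()
    return hashlib.sha256(payload).hexdigest()[:12]
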