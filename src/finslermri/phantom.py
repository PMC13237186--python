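"""Synthetic multi-fiber diffusion phantoms.

Signals follow an equal-volume-fraction Gaussian mixture: a voxel with K
fibers produces

    S(g) = S0 * (1/K) * sum_k exp(-b g^T D_k g)

where each fiber's diffusion tensor D_k has axial diffusivity lambda1 along
its orientation and radial diffusivities lambda2, lambda3 across it.  K = 0
denotes isotropic diffusion with a single scalar diffusivity.  Rician noise
is produced by adding independent zero-mean Gaussians of standard deviation
sigma to real and imaginary channels and taking the magnitude; SNR = S0/sigma.

Default diffusivities: lambda1 = 1.7e-3, lambda2 = lambda3 = 0.2e-3 mm^2/s
(typical white-matter values at b = 1500 s/mm^2); the isotropic default is
their mean, 0.7e-3 mm^2/s.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gradients import DirectionSet, GradientTable, gradient_table, uniform_directions

AXIAL_DIFFUSIVITY = 1.7e-3     # mm^2/s
RADIAL_DIFFUSIVITY = 0.2e-3    # mm^2/s
ISO_DIFFUSIVITY = (AXIAL_DIFFUSIVITY + 2 * RADIAL_DIFFUSIVITY) / 3.0
DEFAULT_BVALUE = 1500.0        # s/mm^2
DEFAULT_N_DIRECTIONS = 81

GROUP_NAMES = ("isotropic", "one_fiber", "two_orthogonal", "three_orthogonal")


@dataclass(frozen=True)
class FiberConfig:
    """Fiber geometry and diffusivities of one synthetic voxel.

    ``orientations`` holds K unit vectors (K in 0..3); K = 0 is isotropic
    diffusion at ``isotropic_diffusivity``.
    """

    orientations: np.ndarray
    axial_diffusivity: float = AXIAL_DIFFUSIVITY
    radial_diffusivity_2: float = RADIAL_DIFFUSIVITY
    radial_diffusivity_3: float = RADIAL_DIFFUSIVITY
    isotropic_diffusivity: float = ISO_DIFFUSIVITY

    def __post_init__(self):
        arr = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        if len(arr) > 0:
            norms = np.linalg.norm(arr, axis=1)
            if np.any(np.abs(norms - 1) > 1e-8):
                arr = arr / norms[:, None]
        l1, l2, l3 = (self.axial_diffusivity, self.radial_diffusivity_2,
                      self.radial_diffusivity_3)
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError("diffusivities must satisfy l1 >= l2 >= l3 > 0")
        if self.isotropic_diffusivity <= 0:
            raise ValueError("isotropic_diffusivity must be > 0")
        object.__setattr__(self, "orientations", arr)

    @property
    def n_fibers(self) -> int:
        return len(self.orientations)

    def rotated(self, rotation: np.ndarray) -> "FiberConfig":
        """Apply one rotation matrix jointly to all orientations."""
        return replace(self, orientations=self.orientations @ np.asarray(rotation).T)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to regenerate one synthetic dataset."""

    config: FiberConfig
    gtab: GradientTable
    s0: float = 1.0
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.s0 <= 0:
            raise ValueError("s0 must be > 0")

    def realize(self) -> np.ndarray:
        """Simulate the (noisy) per-direction signals."""
        clean = multi_fiber_signal(self.config, self.gtab, self.s0)
        return add_rician_noise(clean, self.sigma, self.seed)


def _orthonormal_complement(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    p = helper - np.dot(helper, u) * u
    p /= np.linalg.norm(p)
    return p, np.cross(u, p)


def fiber_tensor(orientation, axial: float = AXIAL_DIFFUSIVITY,
                 radial2: float = RADIAL_DIFFUSIVITY,
                 radial3: float = RADIAL_DIFFUSIVITY) -> np.ndarray:
    """Single-fiber diffusion tensor with given principal axis and eigenvalues."""
    u = np.asarray(orientation, dtype=float)
    u = u / np.linalg.norm(u)
    if radial2 == radial3:  # axially symmetric: frame choice irrelevant
        return radial2 * np.eye(3) + (axial - radial2) * np.outer(u, u)
    p, q = _orthonormal_complement(u)
    return axial * np.outer(u, u) + radial2 * np.outer(p, p) + radial3 * np.outer(q, q)


def multi_fiber_signal(config: FiberConfig, gtab: GradientTable,
                       s0: float = 1.0) -> np.ndarray:
    """Noise-free equal-fraction Gaussian-mixture signals, one per direction."""
    g = gtab.directions
    b = gtab.bvalues
    if config.n_fibers == 0:
        return s0 * np.exp(-b * config.isotropic_diffusivity)
    acc = np.zeros(gtab.count)
    for u in config.orientations:
        D = fiber_tensor(u, config.axial_diffusivity,
                         config.radial_diffusivity_2, config.radial_diffusivity_3)
        acc += np.exp(-b * np.einsum("si,ij,sj->s", g, D, g))
    return s0 * acc / config.n_fibers


def add_rician_noise(signals, sigma: float, seed=None) -> np.ndarray:
    """Rician magnitude noise: sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2).

    ``seed`` may be an int or a numpy Generator; sigma = 0 returns the input
    unchanged.
    """
    signals = np.asarray(signals, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return signals.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signals.shape)
    n2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2 ** 2)


def snr(s0: float, sigma: float) -> float:
    """Signal-to-noise ratio S0/sigma; sigma = 0 maps to infinity."""
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return math.inf if sigma == 0 else s0 / sigma


def random_rotations(n: int, seed=None) -> np.ndarray:
    """(n, 3, 3) rotation matrices uniform over SO(3) (unit-quaternion method)."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)], -1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)], -1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)], -1),
    ], axis=-2)


def rotation_ensemble(config: FiberConfig, n_instances: int, seed=None) -> list[FiberConfig]:
    """n_instances copies of ``config``, each under one uniform random joint
    rotation; pairwise fiber angles are preserved exactly."""
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    return [config.rotated(R) for R in random_rotations(n_instances, seed)]


def canonical_group_config(group: str) -> FiberConfig:
    """Canonical fiber geometry of the four simulation groups.

    One fiber along x; two fibers along x, y; three along x, y, z (crossing
    angles fixed at 90 degrees); isotropic has no fibers.
    """
    axes = {"isotropic": np.empty((0, 3)),
            "one_fiber": np.eye(3)[:1],
            "two_orthogonal": np.eye(3)[:2],
            "three_orthogonal": np.eye(3)}
    if group not in axes:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUP_NAMES}")
    return FiberConfig(axes[group])


def group_dataset(group: str, n_instances: int = 50, sigma: float = 0.0,
                  gtab: GradientTable | None = None, seed=0,
                  s0: float = 1.0) -> list[np.ndarray]:
    """Signal sets for one simulation group: rotate, simulate, add noise.

    Returns ``n_instances`` per-direction signal arrays; rotations act
    trivially on the isotropic group but each instance still draws its own
    noise.
    """
    gtab = gtab or gradient_table(uniform_directions(DEFAULT_N_DIRECTIONS), DEFAULT_BVALUE)
    base = canonical_group_config(group)
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rot_seed, noise_seed = seq.spawn(2)
    configs = rotation_ensemble(base, n_instances, rot_seed)
    noise_rng = np.random.default_rng(noise_seed)
    return [add_rician_noise(multi_fiber_signal(c, gtab, s0), sigma, noise_rng)
            for c in configs]


# ---------------------------------------------------------------------------
# 2D structured field phantom: two straight fiber bands and one circular
# fiber in the XY plane, whose overlaps create 1-, 2- and 3-fiber voxels on
# an isotropic background.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FieldGeometry:
    """Band/annulus layout of the 2D field phantom, as grid-size fractions.

    Defaults put a horizontal x-fiber band and a vertical y-fiber band
    (each 2*band_halfwidth_frac wide) crossing at the center, with a
    tangential circular fiber annulus inside the crossing; at the default
    64x64 grid every region class (isotropic/1/2/3 fibers) has >= 50 voxels.
    """

    band_halfwidth_frac: float = 0.125
    annulus_inner_frac: float = 0.0625
    annulus_outer_frac: float = 0.1171875


@dataclass
class FieldPhantom:
    """Grid of per-voxel fiber configurations with ground-truth labels.

    ``labels[i, j]`` is the number of fibers (0 = isotropic); ``configs`` is
    indexed ``[i][j]`` in the same row-major order.
    """

    configs: list
    labels: np.ndarray
    geometry: FieldGeometry

    @property
    def grid_size(self) -> int:
        return self.labels.shape[0]


def field_phantom(grid_size: int = 64,
                  geometry: FieldGeometry | None = None) -> FieldPhantom:
    """Build the structured 2D phantom (two linear fibers + one circular)."""
    if grid_size < 32:
        raise ValueError("grid_size must be >= 32")
    geom = geometry or FieldGeometry()
    center = (grid_size - 1) / 2.0
    hw = geom.band_halfwidth_frac * grid_size
    r_in = geom.annulus_inner_frac * grid_size
    r_out = geom.annulus_outer_frac * grid_size

    labels = np.zeros((grid_size, grid_size), dtype=int)
    configs: list[list[FiberConfig]] = []
    x_fiber = np.array([1.0, 0.0, 0.0])
    y_fiber = np.array([0.0, 1.0, 0.0])
    for i in range(grid_size):
        row = []
        for j in range(grid_size):
            dx, dy = i - center, j - center
            orientations = []
            if abs(dy) < hw:            # horizontal band: fibers along x
                orientations.append(x_fiber)
            if abs(dx) < hw:            # vertical band: fibers along y
                orientations.append(y_fiber)
            r = math.hypot(dx, dy)
            if r_in <= r <= r_out and r > 0:  # circular fiber: tangent direction
                orientations.append(np.array([-dy / r, dx / r, 0.0]))
            cfg = FiberConfig(np.array(orientations).reshape(-1, 3))
            labels[i, j] = cfg.n_fibers
            row.append(cfg)
        configs.append(row)
    return FieldPhantom(configs, labels, geom)


def simulate_field_signals(phantom: FieldPhantom, gtab: GradientTable,
                           sigma: float = 0.0, seed=0,
                           s0: float = 1.0) -> np.ndarray:
    """(grid, grid, count) signal volume for the field phantom."""
    n = phantom.grid_size
    out = np.empty((n, n, gtab.count))
    for i in range(n):
        for j in range(n):
            out[i, j] = multi_fiber_signal(phantom.configs[i][j], gtab, s0)
    return add_rician_noise(out, sigma, seed)
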