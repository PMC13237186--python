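"""Validation studies: angular sweep, group statistics, stability,
regularization and voxel classification.

Every study is reproducible from (parameters, seed): all randomness is
routed through numpy SeedSequence spawns of the given seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .finsler import ScalarMap, ffa_map, mean_metric
from .gradients import DirectionSet, GradientTable, gradient_table, uniform_directions
from .phantom import (DEFAULT_BVALUE, DEFAULT_N_DIRECTIONS, GROUP_NAMES,
                      FiberConfig, add_rician_noise, canonical_group_config,
                      group_dataset, multi_fiber_signal, rotation_ensemble)
from .quartic import (FitOptions, QuarticTensor, fit_quartic_field,
                      floor_signals)


@dataclass(frozen=True)
class GroupStats:
    group: str
    mean_ffa: float
    sd_ffa: float
    n_instances: int

    def __post_init__(self):
        if self.sd_ffa < 0:
            raise ValueError("sd_ffa must be >= 0")


@dataclass(frozen=True)
class StabilityResult:
    config: str
    n_directions: int
    sigma: float
    mean_ffa: float
    sd_ffa: float
    relative_error_percent: float
    flagged: bool = False

    def __post_init__(self):
        if self.relative_error_percent < 0:
            raise ValueError("relative_error_percent must be >= 0")


@dataclass(frozen=True)
class ClassificationRanges:
    """Half-open FFA intervals mapping values to fiber counts.

    Defaults partition [0, 1]: one [0.70, 1.00], two [0.40, 0.70),
    three [0.20, 0.40), isotropic [0.00, 0.20).
    """

    one: tuple[float, float] = (0.70, 1.00)
    two: tuple[float, float] = (0.40, 0.70)
    three: tuple[float, float] = (0.20, 0.40)
    isotropic: tuple[float, float] = (0.00, 0.20)

    def __post_init__(self):
        edges = [self.isotropic, self.three, self.two, self.one]
        if edges[0][0] != 0.0 or edges[-1][1] != 1.0:
            raise ValueError("ranges must span [0, 1]")
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo[1] != hi[0]:
                raise ValueError("ranges must partition [0, 1] without overlap")

    @property
    def boundaries(self) -> np.ndarray:
        # interior boundaries, each left-closed for the upper class
        return np.array([self.three[0], self.two[0], self.one[0]])


def _ffa_of_signals(signals: np.ndarray, gtab: GradientTable, dirs: DirectionSet,
                    tikhonov_lambda: float = 0.0, s0: float = 1.0) -> np.ndarray:
    """Floor -> fit -> FFA for signal arrays of shape (..., count)."""
    opts = FitOptions(tikhonov_lambda=tikhonov_lambda)
    coeffs = fit_quartic_field(floor_signals(signals, s0), s0, gtab, opts)
    return ffa_map(coeffs, dirs).data


def default_protocol(n_directions: int = DEFAULT_N_DIRECTIONS,
                     bvalue: float = DEFAULT_BVALUE):
    """(gtab, dirs) of the standard synthetic protocol: the same uniform
    antipodally-deduplicated directions serve as gradient scheme and as the
    metric-averaging set."""
    dirs = uniform_directions(n_directions)
    return gradient_table(dirs, bvalue), dirs


def compute_group_ffas(n_instances: int = 50, sigma: float = 0.0,
                       gtab: GradientTable | None = None,
                       dirs: DirectionSet | None = None,
                       seed=0, tikhonov_lambda: float = 0.0) -> dict[str, np.ndarray]:
    """FFA per rotation instance for the four simulation groups."""
    if gtab is None or dirs is None:
        gtab_d, dirs_d = default_protocol()
        gtab = gtab or gtab_d
        dirs = dirs or dirs_d
    seq = np.random.SeedSequence(seed)
    out = {}
    for group, child in zip(GROUP_NAMES, seq.spawn(len(GROUP_NAMES))):
        signals = np.stack(group_dataset(group, n_instances, sigma, gtab, child))
        out[group] = _ffa_of_signals(signals, gtab, dirs, tikhonov_lambda)
    return out


def group_summary(groups: dict[str, np.ndarray]) -> list[GroupStats]:
    """Sample mean and SD of FFA per group."""
    out = []
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if len(values) == 0:
            raise ValueError(f"group {name!r} is empty")
        sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
        out.append(GroupStats(name, float(values.mean()), sd, len(values)))
    return out


def group_summary_frame(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in group_summary(groups)])


def pairwise_group_tests(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Welch t-test and Wilcoxon signed-rank p-values for all group pairs.

    The signed-rank test pairs instances by rotation index, so all groups
    must have equal n.  An all-zero difference leaves the signed-rank test
    undefined; those cells report p = 1 with a flag.
    """
    names = list(groups)
    sizes = {len(np.asarray(groups[n])) for n in names}
    if len(sizes) != 1:
        raise ValueError("all groups must have equal n for paired testing")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
            t_p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
            diffs = xa - xb
            if np.all(diffs == 0):
                w_p, flagged = 1.0, True
            else:
                w_p, flagged = float(stats.wilcoxon(xa, xb).pvalue), False
            rows.append({"group_a": a, "group_b": b, "t_test_p": t_p,
                         "wilcoxon_p": w_p, "wilcoxon_degenerate": flagged})
    return pd.DataFrame(rows)


def angular_sweep(angles_deg, gtab: GradientTable | None = None,
                  dirs: DirectionSet | None = None, sigma: float = 0.0,
                  seed=0, tikhonov_lambda: float = 0.0) -> pd.DataFrame:
    """FFA of a two-fiber voxel as the crossing angle sweeps 0..90 degrees.

    At 0 degrees the two identical Gaussians collapse to a single fiber.
    """
    angles = np.asarray(angles_deg, dtype=float)
    if np.any((angles < 0) | (angles > 90)):
        raise ValueError("angles must lie in [0, 90] degrees")
    if gtab is None or dirs is None:
        gtab_d, dirs_d = default_protocol()
        gtab = gtab or gtab_d
        dirs = dirs or dirs_d
    rng = np.random.default_rng(seed)
    rows = []
    for theta in angles:
        rad = np.deg2rad(theta)
        config = FiberConfig(np.array([[1.0, 0.0, 0.0],
                                       [np.cos(rad), np.sin(rad), 0.0]]))
        sig = add_rician_noise(multi_fiber_signal(config, gtab), sigma, rng)
        rows.append({"angle_deg": float(theta),
                     "ffa": float(_ffa_of_signals(sig, gtab, dirs, tikhonov_lambda))})
    return pd.DataFrame(rows)


def stability_study(n_list=(50, 200, 500, 1000, 2000, 3000),
                    sigmas=(0.0, 0.05, 0.09), n_realizations: int = 30,
                    seed=0, configs=GROUP_NAMES, bvalue: float = DEFAULT_BVALUE,
                    tikhonov_lambda: float = 0.0) -> pd.DataFrame:
    """FFA convergence with directional sampling density.

    For each (config, sigma, N): mean +- SD of FFA over ``n_realizations``
    independent noise draws of the canonical (unrotated) configuration, and
    the relative error of the mean against the largest N as reference:
    |FFA_mean(N) - FFA_mean(N_ref)| / |FFA_mean(N_ref)| * 100.  When both
    means are below 1e-9 (noise-free isotropic) the error is defined as 0;
    a near-zero reference with a non-matching mean is flagged instead.
    """
    n_list = sorted(int(n) for n in n_list)
    n_ref = n_list[-1]
    seq = np.random.SeedSequence(seed)
    rows = []
    for config_name, config_seed in zip(configs, seq.spawn(len(configs))):
        base = canonical_group_config(config_name)
        for sigma, sigma_seed in zip(sigmas, config_seed.spawn(len(sigmas))):
            means, sds = {}, {}
            for n_dirs, n_seed in zip(n_list, sigma_seed.spawn(len(n_list))):
                gtab, dirs = default_protocol(n_dirs, bvalue)
                clean = multi_fiber_signal(base, gtab)
                noise_rng = np.random.default_rng(n_seed)
                signals = np.stack([
                    add_rician_noise(clean, sigma, noise_rng)
                    for _ in range(n_realizations)])
                vals = _ffa_of_signals(signals, gtab, dirs, tikhonov_lambda)
                means[n_dirs] = float(vals.mean())
                sds[n_dirs] = float(vals.std(ddof=1))
            ref = means[n_ref]
            for n_dirs in n_list:
                flagged = False
                if abs(ref) < 1e-9:
                    if abs(means[n_dirs]) < 1e-9:
                        rel = 0.0
                    else:
                        rel, flagged = float("nan"), True
                else:
                    rel = abs(means[n_dirs] - ref) / abs(ref) * 100.0
                rows.append({"config": config_name, "n_directions": n_dirs,
                             "sigma": sigma, "mean_ffa": means[n_dirs],
                             "sd_ffa": sds[n_dirs],
                             "relative_error_percent": rel, "flagged": flagged})
    return pd.DataFrame(rows)


def regularization_study(n_list=(50, 200, 500, 1000), sigma: float = 0.05,
                         lambdas=(0.0, 0.01), n_realizations: int = 30,
                         seed=0, configs=GROUP_NAMES,
                         bvalue: float = DEFAULT_BVALUE) -> pd.DataFrame:
    """Relative RMSE of quartic coefficients and mean Finsler metric vs a
    noise-free ground truth, with and without Tikhonov regularization.

    Ground truth per realization is the noise-free unregularized fit of the
    same rotated configuration at the same N, isolating noise error from
    quartic model error.  Relative RMSE is ||estimate - truth|| / ||truth||
    (Frobenius norm).
    """
    seq = np.random.SeedSequence(seed)
    rows = []
    for config_name, config_seed in zip(configs, seq.spawn(len(configs))):
        base = canonical_group_config(config_name)
        for n_dirs, n_seed in zip(sorted(n_list), config_seed.spawn(len(n_list))):
            gtab, dirs = default_protocol(n_dirs, bvalue)
            rot_seed, noise_seed = n_seed.spawn(2)
            ensemble = rotation_ensemble(base, n_realizations, rot_seed)
            clean = np.stack([multi_fiber_signal(c, gtab) for c in ensemble])
            noisy = add_rician_noise(clean, sigma, np.random.default_rng(noise_seed))
            truth_coeffs = fit_quartic_field(clean, 1.0, gtab, FitOptions(0.0))
            truth_metrics = np.stack([
                mean_metric(QuarticTensor(c), dirs, on_degenerate="floor")
                for c in truth_coeffs])
            for lam in lambdas:
                est = fit_quartic_field(floor_signals(noisy), 1.0, gtab,
                                        FitOptions(tikhonov_lambda=lam))
                est_metrics = np.stack([
                    mean_metric(QuarticTensor(c), dirs, on_degenerate="floor")
                    for c in est])
                coeff_rmse = (np.linalg.norm(est - truth_coeffs, axis=-1)
                              / np.linalg.norm(truth_coeffs, axis=-1))
                metric_rmse = (
                    np.linalg.norm((est_metrics - truth_metrics).reshape(len(est), -1), axis=-1)
                    / np.linalg.norm(truth_metrics.reshape(len(est), -1), axis=-1))
                rows.append({
                    "config": config_name, "n_directions": int(n_dirs),
                    "sigma": sigma, "tikhonov_lambda": lam,
                    "coeff_rmse_mean": float(coeff_rmse.mean()),
                    "coeff_rmse_sd": float(coeff_rmse.std(ddof=1)),
                    "metric_rmse_mean": float(metric_rmse.mean()),
                    "metric_rmse_sd": float(metric_rmse.std(ddof=1)),
                })
    return pd.DataFrame(rows)


def classify_ffa(scalar_map, ranges: ClassificationRanges | None = None) -> np.ndarray:
    """Label map from FFA values: 0 isotropic, 1/2/3 fiber counts.

    Boundary values follow the printed interval closures: 0.20 -> three,
    0.40 -> two, 0.70 -> one.
    """
    ranges = ranges or ClassificationRanges()
    values = scalar_map.data if isinstance(scalar_map, ScalarMap) else np.asarray(scalar_map, float)
    if np.any((values < 0) | (values > 1)) or not np.all(np.isfinite(values)):
        raise ValueError("FFA values must lie in [0, 1]")
    # boundaries are left-closed for the class above them
    labels = np.zeros(values.shape, dtype=np.uint8)
    labels[values >= ranges.three[0]] = 3
    labels[values >= ranges.two[0]] = 2
    labels[values >= ranges.one[0]] = 1
    return labels
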