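"""Model/Results interface over the quartic fit and its scalar descriptors.

`QuarticDiffusionModel` holds the data (signals + gradient table);
`fit()` performs the (optionally Tikhonov-regularized) least-squares quartic
fit and returns a `QuarticDiffusionResults` carrying the coefficients,
residual diagnostics and the anisotropy scalars (FFA, GA, GFA) that derive
from them.
"""
from __future__ import annotations

import numpy as np

from .baselines import ga_map, gfa_map
from .finsler import ScalarMap, ffa_map, mean_metric
from .gradients import DirectionSet, GradientTable, uniform_directions
from .io import DwiDataset
from .quartic import (FitOptions, QuarticTensor, fit_quartic_field,
                      floor_signals, monomial_design_matrix, signals_to_adc)


class QuarticDiffusionModel:
    """Per-voxel quartic ADC model of diffusion-weighted signals.

    Parameters
    ----------
    signals
        Array of shape (..., count): one voxel (1D) or a grid of voxels.
    gtab
        Gradient directions and b-values, one per signal frame.
    s0
        Baseline (b=0) signal, scalar or broadcastable volume.
    """

    def __init__(self, signals, gtab: GradientTable, s0=1.0):
        self.signals = np.asarray(signals, dtype=float)
        if self.signals.shape[-1] != gtab.count:
            raise ValueError(
                f"last signal axis ({self.signals.shape[-1]}) must match "
                f"gradient count ({gtab.count})"
            )
        self.gtab = gtab
        self.s0 = s0

    @classmethod
    def from_dwi(cls, dwi: DwiDataset) -> "QuarticDiffusionModel":
        s0 = dwi.s0
        if isinstance(s0, np.ndarray):
            s0 = np.maximum(s0, np.finfo(float).tiny)[..., None]
        return cls(dwi.signals, dwi.gtab, s0)

    def fit(self, tikhonov_lambda: float = 0.0,
            clamp_epsilon: float = 1e-12) -> "QuarticDiffusionResults":
        opts = FitOptions(tikhonov_lambda=tikhonov_lambda,
                          clamp_epsilon=clamp_epsilon)
        floored = floor_signals(self.signals, np.asarray(self.s0))
        coeffs = fit_quartic_field(floored, self.s0, self.gtab, opts)
        return QuarticDiffusionResults(self, coeffs, opts, floored)


class QuarticDiffusionResults:
    """Fitted quartic tensors plus derived anisotropy descriptors."""

    def __init__(self, model: QuarticDiffusionModel, params: np.ndarray,
                 opts: FitOptions, floored_signals: np.ndarray):
        self.model = model
        self.params = params          # (..., 15) quartic coefficients
        self.opts = opts
        self._adc = signals_to_adc(floored_signals, model.s0, model.gtab)

    # -- diagnostics --------------------------------------------------------

    @property
    def fitted_adc(self) -> np.ndarray:
        return self.params @ monomial_design_matrix(self.model.gtab).T

    @property
    def residuals(self) -> np.ndarray:
        return self._adc - self.fitted_adc

    @property
    def rmse(self) -> np.ndarray | float:
        val = np.sqrt(np.mean(self.residuals ** 2, axis=-1))
        return float(val) if val.ndim == 0 else val

    def tensor(self, index=None) -> QuarticTensor:
        """The fitted tensor of one voxel (index into the leading axes)."""
        coeffs = self.params if index is None else self.params[index]
        if coeffs.ndim != 1:
            raise ValueError("select a single voxel via index")
        return QuarticTensor(coeffs)

    # -- descriptors --------------------------------------------------------

    def _dirs(self, dirs: DirectionSet | None) -> DirectionSet:
        return dirs if dirs is not None else uniform_directions(81)

    def mean_metric(self, dirs: DirectionSet | None = None) -> np.ndarray:
        return mean_metric(self.tensor(), self._dirs(dirs),
                           self.opts.clamp_epsilon, on_degenerate="floor")

    def ffa(self, dirs: DirectionSet | None = None) -> ScalarMap:
        return ffa_map(self.params, self._dirs(dirs), self.opts.clamp_epsilon)

    def ga(self, dirs: DirectionSet | None = None) -> ScalarMap:
        return ga_map(self.params, self._dirs(dirs))

    def gfa(self, dirs: DirectionSet | None = None) -> ScalarMap:
        return gfa_map(self.params, self._dirs(dirs))

    # -- presentation -------------------------------------------------------

    def summary(self, dirs: DirectionSet | None = None) -> str:
        """Plain-text summary of the fit and the derived scalars."""
        dirs = self._dirs(dirs)
        n_vox = int(np.prod(self.params.shape[:-1])) if self.params.ndim > 1 else 1
        ffa_m = self.ffa(dirs)
        ga_m = self.ga(dirs)
        gfa_m = self.gfa(dirs)
        rmse = np.atleast_1d(self.rmse)
        lines = [
            "Quartic diffusion model fit",
            "=" * 42,
            f"{'voxels':<28}{n_vox}",
            f"{'gradient directions':<28}{self.model.gtab.count}",
            f"{'b-value range (s/mm^2)':<28}"
            f"{self.model.gtab.bvalues.min():g}..{self.model.gtab.bvalues.max():g}",
            f"{'tikhonov lambda':<28}{self.opts.tikhonov_lambda:g}",
            f"{'ADC fit RMSE (mm^2/s)':<28}{float(np.mean(rmse)):.3e}",
            f"{'metric directions p':<28}{dirs.p}",
            "-" * 42,
            f"{'scalar':<10}{'mean':>10}{'min':>10}{'max':>10}",
        ]
        for name, m in (("FFA", ffa_m), ("GA", ga_m), ("GFA", gfa_m)):
            d = np.atleast_1d(m.data)
            lines.append(f"{name:<10}{d.mean():>10.4f}{d.min():>10.4f}{d.max():>10.4f}")
        n_degen = int(np.atleast_1d(ffa_m.degenerate_mask).sum())
        lines.append("-" * 42)
        lines.append(f"{'degenerate voxels':<28}{n_degen}")
        return "\n".join(lines)
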