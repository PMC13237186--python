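"""Matplotlib helpers for the validation studies."""
from __future__ import annotations

import numpy as np

from .finsler import ScalarMap


def plot_angular_sweep(sweep_frame, ax=None):
    """Line plot of FFA versus two-fiber crossing angle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(sweep_frame["angle_deg"], sweep_frame["ffa"], marker="o")
    ax.set_xlabel("angular separation (deg)")
    ax.set_ylabel("FFA")
    ax.set_ylim(0, 1)
    return ax


def plot_group_boxes(groups: dict, ax=None):
    """Box-and-whisker plots of per-instance FFA for the simulation groups."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = list(groups)
    ax.boxplot([np.asarray(groups[n]) for n in names], tick_labels=names)
    ax.set_ylabel("FFA")
    ax.tick_params(axis="x", rotation=20)
    return ax


def plot_stability(stability_frame, sigma: float, ax=None):
    """Mean FFA +- SD versus directional sampling density at one noise level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = stability_frame[stability_frame["sigma"] == sigma]
    for config, grp in sub.groupby("config"):
        grp = grp.sort_values("n_directions")
        ax.errorbar(grp["n_directions"], grp["mean_ffa"], yerr=grp["sd_ffa"],
                    label=config, marker="o", capsize=2)
    ax.set_xlabel("directions per voxel N")
    ax.set_ylabel("FFA")
    ax.legend()
    return ax


def plot_scalar_map(scalar_map: ScalarMap | np.ndarray, ax=None, **imshow_kw):
    """Grayscale display of a 2D scalar map on the [0, 1] scale."""
    import matplotlib.pyplot as plt

    data = scalar_map.data if isinstance(scalar_map, ScalarMap) else np.asarray(scalar_map)
    if ax is None:
        _, ax = plt.subplots()
    imshow_kw.setdefault("cmap", "gray")
    imshow_kw.setdefault("vmin", 0.0)
    imshow_kw.setdefault("vmax", 1.0)
    im = ax.imshow(data.T, origin="lower", **imshow_kw)
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax
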