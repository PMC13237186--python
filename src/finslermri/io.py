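"""NIfTI / FSL bval-bvec readers and writers.

Conventions: FSL bvec dialect only (3 whitespace-separated rows of N
columns); volumes with b < 50 s/mm^2 count as b=0 and are averaged into the
baseline S0; scalar maps are written as float32 NIfTI-1, label maps as
uint8 with the code table in the header description.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
import yaml

from .finsler import ScalarMap
from .gradients import ANTIPODAL_TOL_RAD, GradientTable

B0_THRESHOLD = 50.0  # s/mm^2


class FormatError(ValueError):
    """Raised when an on-disk dataset violates the supported conventions."""


@dataclass
class DwiDataset:
    """4D diffusion-weighted volume with its gradient table and baseline."""

    signals: np.ndarray      # (X, Y, Z, count)
    affine: np.ndarray
    gtab: GradientTable
    s0: np.ndarray | float   # baseline volume (X, Y, Z) or scalar

    def __post_init__(self):
        if self.signals.shape[-1] != self.gtab.count:
            raise FormatError(
                f"volume has {self.signals.shape[-1]} diffusion frames but the "
                f"gradient table has {self.gtab.count} directions"
            )


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.atleast_1d(np.loadtxt(bval_path))
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    if bvecs.shape[0] != 3:
        raise FormatError(
            f"bvec file must have 3 rows (FSL dialect), found {bvecs.shape[0]}"
        )
    if bvecs.shape[1] != len(bvals):
        raise FormatError(
            f"bvec has {bvecs.shape[1]} columns but bval lists {len(bvals)} values"
        )
    return bvals, bvecs.T  # (N, 3)


def read_dwi(nifti_path, bval_path, bvec_path) -> DwiDataset:
    """Load a DWI dataset: identify/average b=0 frames, normalize directions,
    collapse antipodal duplicates (averaging their signals) with a warning."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise FormatError(f"expected a 4D volume, got shape {data.shape}")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[3] != len(bvals):
        raise FormatError(
            f"volume has {data.shape[3]} frames but gradient tables list "
            f"{len(bvals)} entries"
        )
    is_b0 = bvals < B0_THRESHOLD
    if is_b0.any():
        s0 = data[..., is_b0].mean(axis=-1)
    else:
        s0 = 1.0

    dwi = data[..., ~is_b0]
    bvals_d = bvals[~is_b0]
    vecs = bvecs[~is_b0]
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        bad = int(np.argmax(norms == 0))
        raise FormatError(
            f"gradient direction {bad} is the zero vector on a b>0 frame"
        )
    vecs = vecs / norms[:, None]

    # collapse antipodal duplicates, averaging their signals
    keep, drop_groups = [], {}
    limit = np.cos(ANTIPODAL_TOL_RAD)
    for i, v in enumerate(vecs):
        merged = False
        for k in keep:
            if abs(float(v @ vecs[k])) > limit:
                drop_groups.setdefault(k, []).append(i)
                merged = True
                break
        if not merged:
            keep.append(i)
    if drop_groups:
        warnings.warn(
            f"collapsed {sum(len(v) for v in drop_groups.values())} antipodal "
            "duplicate gradient directions (signals averaged)",
            stacklevel=2,
        )
        frames = []
        for k in keep:
            group = [k] + drop_groups.get(k, [])
            frames.append(dwi[..., group].mean(axis=-1))
        dwi = np.stack(frames, axis=-1)
        bvals_d = bvals_d[keep]
        vecs = vecs[keep]

    gtab = GradientTable(vecs, bvals_d)
    return DwiDataset(dwi, img.affine, gtab, s0)


def _check_finite(data: np.ndarray):
    if not np.all(np.isfinite(data)):
        idx = np.argwhere(~np.isfinite(data))
        head = "; ".join(str(tuple(int(i) for i in row)) for row in idx[:5])
        raise ValueError(
            f"{len(idx)} non-finite voxel(s), first at indices: {head}"
        )


def write_scalar_map(scalar_map: ScalarMap | np.ndarray, affine, path) -> None:
    """Write a scalar field as float32 NIfTI-1 with the source affine."""
    data = scalar_map.data if isinstance(scalar_map, ScalarMap) else np.asarray(scalar_map)
    _check_finite(data)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.asarray(affine))
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, affine, path) -> None:
    """Companion degenerate-voxel mask as uint8 NIfTI-1."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine))
    nib.save(img, str(path))


def write_labels(labels: np.ndarray, code_table: dict[int, str], affine, path) -> None:
    """Write an integer label map as uint8 NIfTI-1, documenting the code
    table in the header description."""
    labels = np.asarray(labels)
    _check_finite(labels)
    codes = set(np.unique(labels).tolist())
    if not codes <= set(code_table):
        raise ValueError(f"labels contain codes {codes - set(code_table)} "
                         "missing from the code table")
    img = nib.Nifti1Image(labels.astype(np.uint8), np.asarray(affine))
    descrip = ",".join(f"{k}={v}" for k, v in sorted(code_table.items()))
    img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def write_bvals_bvecs(gtab: GradientTable, bval_path, bvec_path,
                      n_b0: int = 0) -> None:
    """FSL-style tables; optional leading b=0 entries."""
    bvals = np.concatenate([np.zeros(n_b0), gtab.bvalues])
    vecs = np.vstack([np.zeros((n_b0, 3)), gtab.directions])
    np.savetxt(bval_path, bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, vecs.T, fmt="%.10f")


def export_phantom(signals: np.ndarray, gtab: GradientTable, out_prefix,
                   labels: np.ndarray | None = None,
                   spec: dict | None = None, s0: float = 1.0,
                   n_b0: int = 1) -> dict[str, str]:
    """Write a synthetic dataset as NIfTI + bval/bvec (+ labels, + config).

    ``signals`` may be (..., count); a leading b=0 frame at S0 is prepended
    so the export round-trips through :func:`read_dwi`.
    """
    signals = np.asarray(signals, dtype=float)
    vol = signals.reshape(signals.shape[:-1] + (signals.shape[-1],))
    while vol.ndim < 4:
        vol = vol[None]
    b0 = np.full(vol.shape[:-1] + (n_b0,), float(s0))
    full = np.concatenate([b0, vol], axis=-1) if n_b0 else vol
    paths = {
        "dwi": f"{out_prefix}_dwi.nii",
        "bval": f"{out_prefix}.bval",
        "bvec": f"{out_prefix}.bvec",
    }
    nib.save(nib.Nifti1Image(full.astype(np.float32), np.eye(4)), paths["dwi"])
    write_bvals_bvecs(gtab, paths["bval"], paths["bvec"], n_b0=n_b0)
    if labels is not None:
        paths["labels"] = f"{out_prefix}_labels.nii"
        lab = np.asarray(labels)
        while lab.ndim < 3:
            lab = lab[None]
        write_labels(lab, {0: "isotropic", 1: "one_fiber", 2: "two_fibers",
                           3: "three_fibers"}, np.eye(4), paths["labels"])
    if spec is not None:
        paths["config"] = f"{out_prefix}_config.yaml"
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(spec, fh)
    return paths
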