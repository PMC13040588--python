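"""Gaussian-random-field cluster-level inference on smooth z maps.

Smoothness (per-axis FWHM) is estimated from the spatial derivatives of the
standardized map inside the mask; the mask volume in FWHM units gives the
resel count R. At a height threshold u the expected Euler characteristic
density of a 3-D unit Gaussian field,

    rho3(u) = (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) exp(-u^2 / 2),

yields the expected cluster count E[m] = R rho3(u), and the expected
suprathreshold volume E[N] = R Phi(-u) resels. Cluster extents follow the
stationary-field approximation P(n >= k) = exp(-beta k^{2/3}) with
beta = (Gamma(5/2) E[m] / E[N])^{2/3} (k in resels), and the cluster-level
family-wise p of an observed extent k is 1 - exp(-E[m] P(n >= k)).

A nonparametric fallback that permutes the severity ordering and records
the null maximum cluster size is provided for masks too small or too rough
for the parametric approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import gamma as gamma_fn

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import voxel_to_mm
from .vbm import CONN26


def estimate_fwhm_voxels(zvol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-axis smoothness FWHM (in voxels) of a map within a mask.

    The map is standardized to unit variance in-mask; for a unit-variance
    Gaussian field the gradient variance lambda_i along axis i gives
    FWHM_i = sqrt(4 ln 2 / lambda_i). Gradients are forward differences
    between in-mask neighbor pairs.
    """
    vals = zvol[mask]
    finite = np.isfinite(vals)
    sd = vals[finite].std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("map has zero variance inside the mask")
    z = (zvol - vals[finite].mean()) / sd

    fwhm = np.empty(3)
    for axis in range(3):
        d = np.diff(z, axis=axis)
        pair_ok = (
            np.logical_and(
                np.take(mask, range(mask.shape[axis] - 1), axis=axis),
                np.take(mask, range(1, mask.shape[axis]), axis=axis),
            )
            & np.isfinite(d)
        )
        lam = np.var(d[pair_ok])
        fwhm[axis] = np.sqrt(4.0 * np.log(2.0) / lam) if lam > 0 else np.inf
    return fwhm


def _rho3(u: float) -> float:
    return (4 * np.log(2)) ** 1.5 / (2 * np.pi) ** 2 * (u**2 - 1) * np.exp(-u**2 / 2)


def cluster_p_grf(extent_voxels: float, u: float, resels: float,
                  voxels_per_resel: float) -> float:
    """Family-wise corrected p of a cluster of ``extent_voxels`` at height u."""
    Em = resels * _rho3(u)
    EN = resels * stats.norm.sf(u)
    if Em <= 0 or EN <= 0:
        return 1.0
    beta = (gamma_fn(2.5) * Em / EN) ** (2.0 / 3.0)
    k_resels = extent_voxels / voxels_per_resel
    p_tail = np.exp(-beta * k_resels ** (2.0 / 3.0))
    return float(1.0 - np.exp(-Em * p_tail))


@dataclass
class ClusterCorrection:
    """Result of cluster-level thresholding: table, surviving mask, diagnostics."""

    table: pd.DataFrame
    surviving_mask: np.ndarray
    fwhm_voxels: np.ndarray
    resels: float
    method: str  # "grf" or "voxel-only"


CLUSTER_COLUMNS = [
    "region", "cluster_size_voxels", "peak_x", "peak_y", "peak_z",
    "peak_stat", "cluster_p",
]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=CLUSTER_COLUMNS)


def grf_cluster_correct(
    zvol: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    voxel_z: float = 3.29,
    cluster_alpha: float = 0.05,
    fwhm_voxels: np.ndarray | None = None,
) -> ClusterCorrection:
    """Threshold a z map at ``voxel_z`` and keep GRF-significant clusters.

    Smoothness defaults to :func:`estimate_fwhm_voxels` on the map itself.
    When the mask holds less than one resel the parametric approximation is
    invalid: a warning is raised and all suprathreshold clusters are kept
    (voxel-level-only thresholding, flagged in ``method``).
    """
    if voxel_z <= 0:
        raise ValueError("voxel_z must be > 0")
    if fwhm_voxels is None:
        fwhm_voxels = estimate_fwhm_voxels(zvol, mask)
    fwhm_voxels = np.asarray(fwhm_voxels, dtype=float)
    voxels_per_resel = float(np.prod(fwhm_voxels))
    resels = mask.sum() / voxels_per_resel

    supra = mask & np.isfinite(zvol) & (zvol > voxel_z)
    labels, n_lab = ndimage.label(supra, structure=CONN26)

    voxel_only = resels < 1.0
    if voxel_only:
        warnings.warn(
            f"mask holds {resels:.2f} resels (< 1); falling back to "
            "voxel-level-only thresholding"
        )

    rows = []
    surviving = np.zeros(mask.shape, dtype=bool)
    for lab in range(1, n_lab + 1):
        cl = labels == lab
        size = int(cl.sum())
        p = (np.nan if voxel_only
             else cluster_p_grf(size, voxel_z, resels, voxels_per_resel))
        if voxel_only or p < cluster_alpha:
            zl = np.where(cl, zvol, -np.inf)
            peak = np.unravel_index(np.argmax(zl), zl.shape)
            mm = voxel_to_mm(peak, affine)
            rows.append({
                "region": "unlabeled",
                "cluster_size_voxels": size,
                "peak_x": mm[0], "peak_y": mm[1], "peak_z": mm[2],
                "peak_stat": float(zvol[peak]),
                "cluster_p": p,
            })
            surviving |= cl
    table = (pd.DataFrame(rows).sort_values("peak_stat", ascending=False)
             .reset_index(drop=True) if rows else _empty_table())
    return ClusterCorrection(
        table=table,
        surviving_mask=surviving,
        fwhm_voxels=fwhm_voxels,
        resels=float(resels),
        method="voxel-only" if voxel_only else "grf",
    )


def label_clusters(
    table: pd.DataFrame,
    affine: np.ndarray,
    atlas: np.ndarray | None = None,
    atlas_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Attach region names from a labeled atlas volume at each cluster peak.

    ``atlas`` must share the analysis grid; integer 0 is background. Without
    an atlas every row is "unlabeled".
    """
    out = table.copy()
    if atlas is None or len(out) == 0:
        return out
    inv = np.linalg.inv(affine)
    names = []
    for _, row in out.iterrows():
        mm = np.array([row["peak_x"], row["peak_y"], row["peak_z"]])
        ijk = np.round(inv[:3, :3] @ mm + inv[:3, 3]).astype(int)
        if any(i < 0 or i >= s for i, s in zip(ijk, atlas.shape)):
            raise ValueError(f"cluster peak {tuple(mm)} outside atlas grid")
        rid = int(atlas[tuple(ijk)])
        if rid == 0:
            names.append("unlabeled")
        elif atlas_labels and rid in atlas_labels:
            names.append(atlas_labels[rid])
        else:
            names.append(str(rid))
    out["region"] = names
    return out


def permutation_cluster_threshold(
    compute_zvol,
    n_perm: int,
    mask: np.ndarray,
    voxel_z: float = 3.29,
    cluster_alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> int:
    """Nonparametric cluster-extent threshold from an ordering-permutation null.

    ``compute_zvol(rng)`` must return a z volume computed under one random
    permutation of the severity ordering (destroying pseudo-time). Returns
    the extent k such that P(max null cluster size >= k) <= cluster_alpha.
    """
    rng = rng or np.random.default_rng()
    max_sizes = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        zvol = compute_zvol(rng)
        supra = mask & np.isfinite(zvol) & (zvol > voxel_z)
        labels, n_lab = ndimage.label(supra, structure=CONN26)
        if n_lab:
            max_sizes[i] = np.bincount(labels[labels > 0]).max()
    return int(np.quantile(max_sizes, 1.0 - cluster_alpha, method="higher")) + 1
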