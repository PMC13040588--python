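"""Voxel-wise causal structural covariance network construction.

Patients are sorted by hallucination severity so that subject index plays
the role of time ("pseudo-time series"). Granger causality is then computed
as a *signed path coefficient*: the target's value is regressed on its own
lags, the seed's lags, and contemporaneous nuisance covariates, and the
seed-lag coefficient (with its sign) is the causal weight. When the seed
region is atrophying, a positive coefficient means the target's GMV
reduction lags the seed's, i.e. the target sits downstream of the seed.

The resulting seed-to-voxel coefficient map is z-standardized over the
gray-matter mask (an affine, rank-preserving transform) for thresholding by
Gaussian-random-field cluster correction (see :mod:`cascn.grf`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Cohort, SeedSpec
from .errors import DegenerateInputError, DesignError

#: Nuisance covariates entering every GCA regression (patients only).
DEFAULT_GCA_COVARIATES = (
    "sex", "age", "education", "tiv", "illness_duration", "onset_age", "cpz_dose",
)


@dataclass
class PseudoTimeSeries:
    """Severity-ordered patient GMV series.

    ``series`` is (ordered subjects x in-mask voxels); rows follow ``order``,
    a permutation of the input patient rows sorted by the severity key.
    ``covariate_matrix`` rows are aligned with ``series`` rows.
    """

    order: np.ndarray
    order_key: str
    key_values: np.ndarray
    series: np.ndarray
    covariate_matrix: np.ndarray
    covariate_names: tuple[str, ...]
    subject_ids: list[str]
    mask: np.ndarray
    affine: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.series.shape[0]


def build_pseudo_series(
    patients: Cohort,
    key: str = "ahs_rank",
    tie_breakers: tuple[str, ...] = ("p3_score",),
    covariates: tuple[str, ...] = DEFAULT_GCA_COVARIATES,
) -> PseudoTimeSeries:
    """Sort patients low-to-high by severity and stack their masked GMV.

    ``key`` is ``"ahs_rank"`` or ``"p3_rank"``. Ties are broken by
    ``tie_breakers`` then ``subject_id``, making the ordering a deterministic
    function of the participant set (invariant to input row order).
    """
    key_col = {"ahs_rank": "ahs_score", "p3_rank": "p3_score"}.get(key)
    if key_col is None:
        raise ValueError(f"unknown order key {key!r}")
    part = patients.participants
    if part[key_col].nunique() == 1:
        warnings.warn(
            f"all patients share {key_col}={part[key_col].iloc[0]}; "
            "the pseudo-time ordering carries no information"
        )
    sort_cols = [key_col, *[c for c in tie_breakers if c != key_col], "subject_id"]
    order = part.sort_values(sort_cols, kind="mergesort").index.to_numpy()

    ordered = part.iloc[order]
    cov_cols = []
    for cov in covariates:
        v = ordered[cov]
        cov_cols.append((v == "M").to_numpy(float) if cov == "sex"
                        else v.to_numpy(float))
    cov_mat = np.column_stack(cov_cols) if cov_cols else np.empty((len(order), 0))
    if not np.isfinite(cov_mat).all():
        bad = [covariates[j] for j in range(cov_mat.shape[1])
               if not np.isfinite(cov_mat[:, j]).all()]
        raise DesignError(f"non-finite covariate values in columns {bad}")

    return PseudoTimeSeries(
        order=order,
        order_key=key,
        key_values=ordered[key_col].to_numpy(),
        series=patients.volumes[order][:, patients.mask],
        covariate_matrix=cov_mat,
        covariate_names=tuple(covariates),
        subject_ids=ordered["subject_id"].tolist(),
        mask=patients.mask,
        affine=patients.affine,
    )


def mask_indices_of(pts: PseudoTimeSeries, sphere: np.ndarray) -> np.ndarray:
    """Column indices into ``pts.series`` for a 3-D boolean sphere mask."""
    idx = sphere[pts.mask]
    if not idx.any():
        raise DegenerateInputError("sphere does not intersect the analysis mask")
    return np.flatnonzero(idx)


def extract_seed_series(pts: PseudoTimeSeries, sphere: np.ndarray) -> np.ndarray:
    """Per-subject mean GMV over the sphere's in-mask voxels."""
    return pts.series[:, mask_indices_of(pts, sphere)].mean(axis=1)


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError(f"{name} series is constant")
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class GCAResult:
    coef: float
    t: float
    df: int

    @property
    def p_one_sided(self) -> float:
        """P(T >= t): small when the coefficient is significantly positive."""
        return float(stats.t.sf(self.t, self.df))


def signed_path_gca(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    order: int = 1,
) -> GCAResult:
    """Signed path coefficient for x -> y on a pseudo-time series.

    Both series are z-standardized, then ``y[t]`` is regressed on
    [intercept, y[t-1..t-order], x[t-1..t-order], covariates[t]] by ordinary
    least squares over t = order..n-1. Returns the sum of the x-lag
    coefficients with its standard-error-based t statistic; the sign is
    preserved (this is a path coefficient, not a variance-ratio statistic).
    """
    x = _standardize(np.asarray(x, dtype=float), "seed")
    y = _standardize(np.asarray(y, dtype=float), "target")
    n = len(x)
    ncov = 0 if covariates is None else covariates.shape[1]
    if len(y) != n or (covariates is not None and covariates.shape[0] != n):
        raise ValueError("x, y and covariates must share their length")
    if n - order <= 1 + 2 * order + ncov + 1:
        raise DesignError(f"series of length {n} too short for order {order}")

    cols = [np.ones(n - order)]
    for lag in range(1, order + 1):
        cols.append(y[order - lag:n - lag])
    for lag in range(1, order + 1):
        cols.append(x[order - lag:n - lag])
    if covariates is not None:
        cols.append(covariates[order:])
    X = np.column_stack(cols)
    target = y[order:]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DesignError("rank-deficient GCA regression")
    beta, _, _, _ = np.linalg.lstsq(X, target, rcond=None)
    resid = target - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)

    sl = slice(1 + order, 1 + 2 * order)  # x-lag block
    coef = float(beta[sl].sum())
    var = float(sigma2 * xtx_inv[sl, sl].sum())
    return GCAResult(coef=coef, t=coef / np.sqrt(var), df=df)


@dataclass
class GCMap:
    """Seed-to-voxel signed path coefficients (NaN off-mask and at the seed)."""

    gc: np.ndarray
    seed: SeedSpec | None
    model_order: int
    n_degenerate: int = 0


@dataclass
class ZMap:
    """Globally standardized GC map; ``transform`` is the (mean, sd) used."""

    z: np.ndarray
    transform: tuple[float, float]


def gca_map(
    pts: PseudoTimeSeries,
    seed_series: np.ndarray,
    seed_sphere: np.ndarray | None = None,
    seed: SeedSpec | None = None,
    order: int = 1,
    max_degenerate_fraction: float = 0.10,
) -> GCMap:
    """Signed-path GCA from the seed series to every in-mask voxel.

    Equivalent to calling :func:`signed_path_gca` per voxel with the full
    covariate set, but solved as batched normal equations: the design shares
    [intercept, seed lags, covariates] across voxels and differs only in the
    target's own lag columns. Voxels inside ``seed_sphere`` and degenerate
    (constant) voxels are NaN; more than ``max_degenerate_fraction`` of
    degenerate voxels raises (the mask is likely wrong).
    """
    x = _standardize(np.asarray(seed_series, dtype=float), "seed")
    n, nvox = pts.series.shape
    cov = pts.covariate_matrix
    rows = n - order

    # per-voxel standardization; constant voxels flagged degenerate and
    # replaced by white noise placeholders so the stacked solve stays
    # non-singular (their coefficients are discarded below)
    sd = pts.series.std(axis=0)
    good = sd > 0
    Y = np.zeros_like(pts.series)
    Y[:, good] = (pts.series[:, good] - pts.series.mean(axis=0)[good]) / sd[good]
    if not good.all():
        filler = np.random.default_rng(0).standard_normal((n, (~good).sum()))
        Y[:, ~good] = (filler - filler.mean(0)) / filler.std(0)

    shared = [np.ones(rows)]
    for lag in range(1, order + 1):
        shared.append(x[order - lag:n - lag])
    if cov.shape[1]:
        shared.append(cov[order:])
    S = np.column_stack(shared)          # rows x ps
    ps = S.shape[1]
    p = ps + order
    xsl = slice(1, 1 + order)            # seed-lag columns within S

    L = np.stack([Y[order - lag:n - lag] for lag in range(1, order + 1)], axis=2)
    T = Y[order:]                        # rows x nvox targets

    StS = S.T @ S                                        # ps x ps
    StL = np.einsum("rp,rvl->vpl", S, L)                 # nvox x ps x order
    LtL = np.einsum("rvl,rvm->vlm", L, L)                # nvox x order x order
    Sty = S.T @ T                                        # ps x nvox
    Lty = np.einsum("rvl,rv->vl", L, T)                  # nvox x order

    G = np.empty((nvox, p, p))
    G[:, :ps, :ps] = StS
    G[:, :ps, ps:] = StL
    G[:, ps:, :ps] = StL.transpose(0, 2, 1)
    G[:, ps:, ps:] = LtL
    rhs = np.concatenate([Sty.T, Lty], axis=1)           # nvox x p

    yty = np.einsum("rv,rv->v", T, T)
    coefs = np.full(nvox, np.nan)
    df = rows - p
    with np.errstate(all="ignore"):
        try:
            beta = np.linalg.solve(G, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.full((nvox, p), np.nan)
            ok = np.abs(np.linalg.det(G)) > 1e-300
            beta[ok] = np.linalg.solve(G[ok], rhs[ok, :, None])[..., 0]
        rss = yty - np.einsum("vp,vp->v", beta, rhs)
        sigma2 = rss / df
        Ginv = np.linalg.inv(G)
        var = sigma2 * Ginv[:, xsl, xsl].sum(axis=(1, 2))
        coefs = beta[:, xsl].sum(axis=1)
        bad = ~good | ~np.isfinite(coefs) | ~np.isfinite(var) | (var <= 0)
    coefs[bad] = np.nan

    gc = np.full(pts.mask.shape, np.nan)
    gc[pts.mask] = coefs
    if seed_sphere is not None:
        gc[seed_sphere] = np.nan

    n_deg = int(bad.sum())
    if n_deg > max_degenerate_fraction * nvox:
        raise DegenerateInputError(
            f"{n_deg}/{nvox} voxels degenerate; check mask and input volumes"
        )
    if n_deg:
        warnings.warn(f"{n_deg} degenerate voxels set to missing in GC map")
    return GCMap(gc=gc, seed=seed, model_order=order, n_degenerate=n_deg)


def z_transform_map(gcmap: GCMap, mask: np.ndarray, robust: bool = True) -> ZMap:
    """Standardize the GC map over in-mask finite voxels: z = (gc - m)/s.

    With ``robust`` (default) the location/scale are the median and the
    normal-consistent MAD, so voxels carrying real causal signal do not
    inflate the scale and the z values of null voxels stay calibrated —
    required for the Gaussian-field cluster inference downstream. With
    ``robust=False`` the plain mean/SD are used (in-mask mean 0, sd 1
    exactly). Either way the transform is affine and rank-preserving.
    """
    vals = gcmap.gc[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise DegenerateInputError("fewer than 2 finite in-mask GC values")
    if robust:
        m = float(np.median(vals))
        sd = float(1.4826 * np.median(np.abs(vals - m)))
    else:
        m, sd = float(vals.mean()), float(vals.std())
    if sd == 0:
        raise DegenerateInputError("GC map has zero scale")
    return ZMap(z=(gcmap.gc - m) / sd, transform=(m, sd))
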