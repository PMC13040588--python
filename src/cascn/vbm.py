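"""Stage-specific voxel-based morphometry and atrophy-origin localization.

Patients are staged by hallucination severity (quartiles of the PSYRATS AHS
total, or fixed PANSS P3 bins). Each stage is compared against all controls
with a per-voxel ordinary-least-squares GLM whose contrast is the group
indicator — the standard reading of a "covaried two-sample t-test" — and
voxel p-values are controlled by Benjamini–Hochberg FDR. The atrophy origin
is the peak (maximal |t|) among significant GMV *reductions* at the
earliest significant stage, together with its 26-connected cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .io import Cohort, voxel_to_mm
from .errors import DesignError, StagingError

DEFAULT_VBM_COVARIATES = ("age", "sex", "education", "tiv")

#: 26-neighborhood structuring element for cluster formation.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class StageDefinition:
    """Closed integer score intervals mapping severity scores to stages 1..K."""

    strategy: str  # "quartiles_ahs" or "p3_bins"
    boundaries: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_hi = None
        for lo, hi in self.boundaries:
            if lo > hi:
                raise StagingError(f"interval [{lo}, {hi}] is empty")
            if prev_hi is not None and lo <= prev_hi:
                raise StagingError("stage intervals overlap or are unordered")
            prev_hi = hi

    @property
    def n_stages(self) -> int:
        return len(self.boundaries)

    def assign(self, score: int) -> int:
        """1-based stage of a score; raises if the score is uncovered."""
        for k, (lo, hi) in enumerate(self.boundaries, start=1):
            if lo <= score <= hi:
                return k
        raise StagingError(f"score {score} not covered by {self.boundaries}")


#: The fixed three-bin staging on the PANSS P3 hallucination item.
P3_STAGES = StageDefinition("p3_bins", ((4, 4), (5, 5), (6, 7)))


def quartile_stages(scores) -> StageDefinition:
    """Four closed integer intervals at the empirical quartiles of ``scores``.

    Cut points are the floored 25/50/75th percentiles; a score tied with a
    cut point goes to the lower stage, keeping intervals disjoint.
    """
    scores = np.asarray(scores, dtype=int)
    if len(np.unique(scores)) < 4:
        raise StagingError("need >= 4 distinct severity scores for quartiles")
    cuts = [int(np.floor(np.percentile(scores, q))) for q in (25, 50, 75)]
    lo, hi = int(scores.min()), int(scores.max())
    bounds = []
    prev = lo
    for c in cuts:
        if c < prev:  # heavily tied sample; keep intervals valid
            c = prev
        bounds.append((prev, c))
        prev = c + 1
    if prev > hi:
        raise StagingError("degenerate quartiles: top stage is empty")
    bounds.append((prev, hi))
    return StageDefinition("quartiles_ahs", tuple(bounds))


def assign_stages(
    participants: pd.DataFrame,
    strategy: str | StageDefinition = "quartiles_ahs",
) -> tuple[StageDefinition, np.ndarray]:
    """Stage every patient row; returns the definition and 1-based labels.

    ``strategy`` may be a :class:`StageDefinition` (e.g. published interval
    boundaries) or one of ``"quartiles_ahs"`` / ``"p3_bins"``. Raises
    :class:`StagingError` if any stage holds fewer than 2 patients.
    """
    if isinstance(strategy, StageDefinition):
        stagedef = strategy
        key = "ahs_score" if strategy.strategy == "quartiles_ahs" else "p3_score"
    elif strategy == "quartiles_ahs":
        stagedef = quartile_stages(participants["ahs_score"])
        key = "ahs_score"
    elif strategy == "p3_bins":
        stagedef = P3_STAGES
        key = "p3_score"
    else:
        raise StagingError(f"unknown staging strategy {strategy!r}")

    labels = np.array([stagedef.assign(int(s)) for s in participants[key]])
    for k in range(1, stagedef.n_stages + 1):
        if (labels == k).sum() < 2:
            raise StagingError(
                f"stage {k} has {(labels == k).sum()} patients; "
                "a group comparison needs >= 2"
            )
    return stagedef, labels


@dataclass
class TMap:
    """Voxel-wise t statistics for the group contrast (patients - controls)."""

    t: np.ndarray
    df: int
    covariates: tuple[str, ...]
    stage: int
    n_patients: int
    n_controls: int

    def p(self, mask: np.ndarray) -> np.ndarray:
        """Two-sided p-values (Student t, ``df``) on the mask, NaN elsewhere."""
        p = np.full(self.t.shape, np.nan)
        p[mask] = 2.0 * stats.t.sf(np.abs(self.t[mask]), self.df)
        return p


def _design_matrix(
    stage_patients: Cohort, controls: Cohort, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    part = pd.concat(
        [stage_patients.participants, controls.participants], ignore_index=True
    )
    cols = [np.ones(len(part)), (part["group"] == "patient").to_numpy(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        v = part[cov]
        cols.append((v == "M").to_numpy(float) if cov == "sex"
                    else v.to_numpy(float))
        names.append(cov)
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # name columns whose removal restores full column count - rank parity
    collinear = [
        names[j]
        for j in range(X.shape[1])
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
    ]
    raise DesignError(f"rank-deficient design; collinear columns: {collinear}")


def glm_group_ttest(
    stage_patients: Cohort,
    controls: Cohort,
    covariates: tuple[str, ...] = DEFAULT_VBM_COVARIATES,
    stage: int = 0,
) -> TMap:
    """Per-voxel OLS of GMV on [intercept, group, covariates]; t of ``group``.

    Equivalent to the classic pooled two-sample t-test when ``covariates``
    is empty. All in-mask voxels are fit in one vectorized least-squares
    solve; df = n - rank(design).
    """
    X, names = _design_matrix(stage_patients, controls, covariates)
    _check_rank(X, names)
    n, p = X.shape
    if n <= p:
        raise DesignError(f"n={n} subjects but {p} design columns")

    mask = stage_patients.mask
    Y = np.concatenate(
        [stage_patients.volumes[:, mask], controls.volumes[:, mask]], axis=0
    )
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta[1] / se, 0.0)

    t3 = np.zeros(mask.shape)
    t3[mask] = tvals
    return TMap(
        t=t3,
        df=df,
        covariates=tuple(covariates),
        stage=stage,
        n_patients=stage_patients.n_subjects,
        n_controls=controls.n_subjects,
    )


def fdr_threshold(
    pmap: np.ndarray, mask: np.ndarray, q: float = 1e-5
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg over in-mask voxels.

    Returns (significance mask, adjusted-p volume with NaN off-mask).
    """
    if not np.any(mask):
        raise ValueError("empty mask")
    p = np.asarray(pmap)[mask]
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = reject
    adj = np.full(mask.shape, np.nan)
    adj[mask] = p_adj
    return sig, adj


@dataclass(frozen=True)
class PeakRegion:
    """Peak of the origin cluster: mm coordinate, t value, cluster extent."""

    peak_mm: tuple[float, float, float]
    peak_t: float
    cluster_voxels: int
    stage: int


def find_origin(
    tmaps: list[TMap],
    sig_masks: list[np.ndarray],
    affine: np.ndarray,
) -> PeakRegion | None:
    """Atrophy origin: max-|t| significant reduction at the earliest stage.

    Only negative-t (patient < control) voxels are eligible. Returns ``None``
    when no stage shows a significant reduction, which halts the pipeline
    with an explanatory message rather than an arbitrary seed.
    """
    for tmap, sig in zip(tmaps, sig_masks):
        eligible = sig & (tmap.t < 0)
        if not eligible.any():
            continue
        tv = np.where(eligible, tmap.t, 0.0)
        peak_idx = np.unravel_index(np.argmax(np.abs(tv)), tv.shape)
        labels, _ = ndimage.label(eligible, structure=CONN26)
        cluster = labels == labels[peak_idx]
        return PeakRegion(
            peak_mm=tuple(voxel_to_mm(peak_idx, affine)),
            peak_t=float(tmap.t[peak_idx]),
            cluster_voxels=int(cluster.sum()),
            stage=tmap.stage,
        )
    return None
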