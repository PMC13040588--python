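"""Replicate studies quantifying what the pipeline recovers on synthetic data.

These routines are the package's self-validation harness: they run the full
analysis on freshly generated cascade cohorts and measure origin recovery,
planted-edge recovery, degree-sign recovery, negative-control behaviour,
family-wise error of the cluster correction, and the calibration of the
underlying estimators. Both the test suite and ``scripts/acceptance.py``
call them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from . import grf, io as cio, network, vbm, voxelwise
from .simulate import CascadeSpec, default_fixture, generate_cohort
from .voxelwise import GCMap, build_pseudo_series, extract_seed_series, gca_map


@dataclass
class ReplicateResult:
    origin_ok: bool
    n_clusters: int
    recovered_edges: int
    n_planted_edges: int
    trans_net: float            # mean net degree over recovered first-layer ROIs
    term_net: float             # mean net degree over recovered terminal ROIs
    shuffled_recovered: int | None = None
    shuffled_clusters: int | None = None


def _roi_to_region(rois: network.ROISet, spec: CascadeSpec,
                   max_dist_mm: float = 12.0) -> dict[str, str]:
    """Map each planted region to its nearest ROI center (seed -> origin)."""
    mapping: dict[str, str] = {}
    for name, center in zip(rois.names, rois.centers_mm):
        if name == network.SEED_NODE:
            mapping.setdefault(spec.origin_region().name, name)
            continue
        dists = [np.linalg.norm(np.asarray(center) - np.asarray(r.center_mm))
                 for r in spec.regions]
        i = int(np.argmin(dists))
        if dists[i] <= max_dist_mm:
            mapping.setdefault(spec.regions[i].name, name)
    return mapping


def _roi_network(cohort, pts, seed, clusters, roi_alpha=0.05):
    rois = network.extract_rois(
        clusters, seed, cohort.shape, cohort.affine, cohort.mask
    )
    coef, tstat, df = network.pairwise_gca(pts, rois)
    net = network.threshold_network(coef, tstat, df, rois.names, alpha=roi_alpha)
    return rois, net


def _edge_and_degree_metrics(spec, rois, net):
    reg2roi = _roi_to_region(rois, spec)
    recovered = 0
    for parent, child in spec.edges:
        p, c = reg2roi.get(parent), reg2roi.get(child)
        if p is not None and c is not None:
            i, j = net.nodes.index(p), net.nodes.index(c)
            recovered += int(np.isfinite(net.weights[i, j]))
    degrees = network.compute_degrees(net).set_index("node")
    first_layer = {c for p, c in spec.edges if p == spec.origin_region().name}
    terminals = set(spec.terminal_regions())

    def tier_mean(names):
        vals = [degrees.loc[reg2roi[n], "net_degree"]
                for n in names if n in reg2roi]
        return float(np.mean(vals)) if vals else np.nan

    return recovered, tier_mean(first_layer), tier_mean(terminals)


def run_cascade_replicate(
    rng_seed: int,
    spec: CascadeSpec | None = None,
    include_shuffle: bool = False,
    q: float = 1e-5,
    voxel_z: float = 3.29,
    cluster_alpha: float = 0.05,
    roi_alpha: float = 0.05,
) -> ReplicateResult:
    """Generate one cohort, run the full analysis, score it against the truth.

    With ``include_shuffle`` the voxel- and ROI-wise stages are additionally
    re-run with the severity ordering randomly permuted (the negative
    control: pseudo-time destroyed, planted-edge recovery should fall to the
    nominal false-positive rate).
    """
    spec = spec if spec is not None else default_fixture(rng_seed=rng_seed)
    if spec.rng_seed != rng_seed:
        spec = dataclasses.replace(spec, rng_seed=rng_seed)
    cohort = generate_cohort(spec)
    pats, ctrls = cohort.patients(), cohort.controls()

    _, labels = vbm.assign_stages(pats.participants, "quartiles_ahs")
    tmaps, sigs = [], []
    for k in range(1, 5):
        tm = vbm.glm_group_ttest(pats.subset(labels == k), ctrls, stage=k)
        sg, _ = vbm.fdr_threshold(tm.p(cohort.mask), cohort.mask, q)
        tmaps.append(tm)
        sigs.append(sg)
    origin = vbm.find_origin(tmaps, sigs, cohort.affine)
    planted = spec.origin_region()
    origin_ok = origin is not None and (
        np.linalg.norm(np.asarray(origin.peak_mm)
                       - np.asarray(planted.center_mm)) <= planted.radius_mm
    )
    if origin is None:
        return ReplicateResult(False, 0, 0, len(spec.edges), np.nan, np.nan)

    seed = cio.SeedSpec(tuple(origin.peak_mm), 6.0)
    sphere = cio.sphere_mask(seed, cohort.shape, cohort.affine,
                             gm_mask=cohort.mask)

    def run_network_stage(pts):
        seed_series = extract_seed_series(pts, sphere)
        gcm = gca_map(pts, seed_series, seed_sphere=sphere, seed=seed)
        zm = voxelwise.z_transform_map(gcm, cohort.mask)
        corr = grf.grf_cluster_correct(
            zm.z, cohort.mask & ~sphere, cohort.affine,
            voxel_z=voxel_z, cluster_alpha=cluster_alpha,
        )
        if len(corr.table) == 0:
            return 0, 0, np.nan, np.nan
        rois, net = _roi_network(cohort, pts, seed, corr.table, roi_alpha)
        rec, trans_net, term_net = _edge_and_degree_metrics(spec, rois, net)
        return len(corr.table), rec, trans_net, term_net

    pts = build_pseudo_series(pats)
    n_clusters, recovered, trans_net, term_net = run_network_stage(pts)

    shuffled_rec = shuffled_clusters = None
    if include_shuffle:
        rng = np.random.default_rng(100_000 + rng_seed)
        shuffled = pats.participants.copy()
        shuffled["ahs_score"] = rng.permutation(
            shuffled["ahs_score"].to_numpy()
        )
        pats_shuffled = cio.Cohort(pats.volumes, pats.affine, pats.mask,
                                   shuffled, ground_truth=spec)
        pts_s = build_pseudo_series(pats_shuffled)
        shuffled_clusters, shuffled_rec, _, _ = run_network_stage(pts_s)

    return ReplicateResult(
        origin_ok=bool(origin_ok),
        n_clusters=n_clusters,
        recovered_edges=recovered,
        n_planted_edges=len(spec.edges),
        trans_net=trans_net,
        term_net=term_net,
        shuffled_recovered=shuffled_rec,
        shuffled_clusters=shuffled_clusters,
    )


def cascade_recovery_study(
    seeds, include_shuffle: bool = True
) -> dict:
    """Run :func:`run_cascade_replicate` over many seeds and aggregate."""
    results = [
        run_cascade_replicate(s, include_shuffle=include_shuffle) for s in seeds
    ]
    n = len(results)
    total_edges = sum(r.n_planted_edges for r in results)
    out = {
        "n_replicates": n,
        "origin_hits": sum(r.origin_ok for r in results),
        "edge_recovery_rate": sum(r.recovered_edges for r in results)
        / total_edges,
        "trans_mean_net_degree": float(np.nanmean([r.trans_net for r in results])),
        "term_mean_net_degree": float(np.nanmean([r.term_net for r in results])),
        "results": results,
    }
    if include_shuffle:
        out["shuffled_edge_recovery_rate"] = (
            sum(r.shuffled_recovered or 0 for r in results) / total_edges
        )
    return out


def grf_calibration_study(
    n_fields: int = 200,
    rng_seed: int = 0,
    shape=(48, 48, 48),
    fwhm_mm: float = 6.0,
    voxel_mm: float = 1.5,
    voxel_z: float = 3.29,
    cluster_alpha: float = 0.05,
) -> float:
    """Family-wise rate of any surviving cluster on smooth Gaussian null fields."""
    rng = np.random.default_rng(rng_seed)
    mask = np.ones(shape, dtype=bool)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    sigma = fwhm_mm / 2.3548 / voxel_mm
    hits = 0
    for _ in range(n_fields):
        f = gaussian_filter(rng.standard_normal(shape), sigma)
        zm = voxelwise.z_transform_map(GCMap(gc=f, seed=None, model_order=1), mask)
        corr = grf.grf_cluster_correct(
            zm.z, mask, affine, voxel_z=voxel_z, cluster_alpha=cluster_alpha
        )
        hits += len(corr.table) > 0
    return hits / n_fields


def coupling_recovery_study(
    n: int = 87, n_rep: int = 500, c: float = 0.5, rng_seed: int = 0
) -> dict:
    """Recovery of y_t = c x_{t-1} + 0.5 y_{t-1} + e and the c = 0 null rate.

    Under standardization the population coefficient is c * sd_x / sd_y with
    sd_y^2 = (c^2 + 1) / (1 - 0.25).
    """
    rng = np.random.default_rng(rng_seed)
    analytic = c / np.sqrt((c**2 + 1.0) / 0.75)

    def one(c_true):
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        y = np.zeros(n)
        for t in range(1, n):
            y[t] = c_true * x[t - 1] + 0.5 * y[t - 1] + e[t]
        return voxelwise.signed_path_gca(x, y)

    coefs = [one(c).coef for _ in range(n_rep)]
    null_t = [one(0.0).t for _ in range(n_rep)]
    return {
        "mean_coef": float(np.mean(coefs)),
        "analytic_coef": float(analytic),
        "null_exceedance_rate": float(np.mean(np.abs(null_t) > 1.96)),
    }


def fdr_mixture_study(
    n_rep: int = 200, m_null: int = 1000, m_alt: int = 100,
    q: float = 0.05, rng_seed: int = 0
) -> float:
    """Mean realized false-discovery proportion on a null/alternative mixture."""
    rng = np.random.default_rng(rng_seed)
    fdps = []
    for _ in range(n_rep):
        p = np.concatenate([
            rng.uniform(size=m_null),
            rng.uniform(size=m_alt) * 1e-6,
        ])
        mask = np.ones((p.size, 1, 1), bool)
        sig, _ = vbm.fdr_threshold(p.reshape(-1, 1, 1), mask, q=q)
        rejected = sig.ravel()
        if rejected.any():
            fdps.append(rejected[:m_null].sum() / rejected.sum())
        else:
            fdps.append(0.0)
    return float(np.mean(fdps))
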