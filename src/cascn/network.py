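"""ROI-level directed causal network and weighted degree analysis.

Spherical ROIs are placed at the surviving cluster peaks of the voxel-wise
map (plus the seed itself). Pairwise signed-path Granger coefficients among
ROI mean series are computed with the same regression as the voxel stage;
positive coefficients whose own one-sided t-test passes alpha become
directed edge weights (standardized by the off-diagonal dispersion so
weights are comparable across cohorts). Each node is summarized
by weighted out-, in- and net-degree (out - in): a positive net degree
marks a causal source, a negative one a causal target, and a positive-net
node that receives an edge from the seed is a *transitional* node relaying
the seed's influence onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import SeedSpec, sphere_mask, mni_to_voxel
from .voxelwise import PseudoTimeSeries, extract_seed_series, signed_path_gca
from .errors import ConfigurationError

SEED_NODE = "seed"


@dataclass
class ROISet:
    """Named, pairwise-disjoint ROI masks on the analysis grid."""

    names: list[str]
    centers_mm: np.ndarray          # n x 3
    masks: np.ndarray               # n x grid, boolean

    def __post_init__(self) -> None:
        overlap = self.masks.sum(axis=0) > 1
        if overlap.any():
            raise ConfigurationError("ROI masks overlap")
        if any(not m.any() for m in self.masks):
            raise ConfigurationError("empty ROI mask")

    @property
    def n_rois(self) -> int:
        return len(self.names)


def extract_rois(
    clusters: pd.DataFrame,
    seed: SeedSpec,
    grid_shape: tuple[int, int, int],
    affine: np.ndarray,
    gm_mask: np.ndarray,
    radius_mm: float = 6.0,
) -> ROISet:
    """Spheres of ``radius_mm`` at each cluster peak, plus the seed ROI.

    Contested voxels (inside several spheres) go to the nearest peak. Peaks
    closer than one voxel are merged with a warning. ROI names come from the
    cluster table's ``region`` column, disambiguated by peak order.
    """
    if len(clusters) == 0:
        raise ConfigurationError("no clusters to extract ROIs from")
    centers = [np.asarray(seed.center_mm, dtype=float)]
    names = [SEED_NODE]
    voxel_mm = np.min(np.linalg.norm(affine[:3, :3], axis=0))
    for i, row in clusters.iterrows():
        c = np.array([row["peak_x"], row["peak_y"], row["peak_z"]], dtype=float)
        dists = [np.linalg.norm(c - prev) for prev in centers]
        if min(dists) < voxel_mm:
            near = names[int(np.argmin(dists))]
            warnings.warn(
                f"cluster peak {tuple(c)} within one voxel of ROI {near!r}; merged"
            )
            continue
        label = str(row.get("region", "unlabeled"))
        name = label if label not in ("unlabeled", "nan") else f"cluster_{i + 1}"
        while name in names:
            name += "_b"
        names.append(name)
        centers.append(c)

    centers = np.asarray(centers)
    spheres = np.stack([
        sphere_mask(SeedSpec(tuple(c), radius_mm), grid_shape, affine, gm_mask=gm_mask)
        for c in centers
    ])
    contested = spheres.sum(axis=0) > 1
    if contested.any():
        idx = np.argwhere(contested)
        mm = idx @ affine[:3, :3].T + affine[:3, 3]
        nearest = np.argmin(
            np.linalg.norm(mm[:, None, :] - centers[None, :, :], axis=2), axis=1
        )
        for vox, owner in zip(idx, nearest):
            v = tuple(vox)
            for r in range(len(names)):
                spheres[(r,) + v] = r == owner
    return ROISet(names=names, centers_mm=centers, masks=spheres)


def pairwise_gca(
    pts: PseudoTimeSeries,
    rois: ROISet,
    order: int = 1,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Directed signed-path coefficients among ROI mean series.

    Entry (i, j) is the i -> j coefficient with the same covariates,
    model order and standardization as the voxel-wise analysis; the diagonal
    is NaN. Returns (coefficient matrix, t-statistic matrix, residual df).
    """
    series = [extract_seed_series(pts, m) for m in rois.masks]
    k = rois.n_rois
    coef = np.full((k, k), np.nan)
    tstat = np.full((k, k), np.nan)
    df = 0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            res = signed_path_gca(
                series[i], series[j], covariates=pts.covariate_matrix, order=order
            )
            coef[i, j] = res.coef
            tstat[i, j] = res.t
            df = res.df
    return coef, tstat, df


@dataclass
class DirectedNetwork:
    """Positive, significant causal weights (z-standardized coefficients)."""

    nodes: list[str]
    weights: np.ndarray             # k x k, NaN where no edge
    seed_node: str = SEED_NODE

    def __post_init__(self) -> None:
        stored = self.weights[np.isfinite(self.weights)]
        if stored.size and not (stored > 0).all():
            raise ConfigurationError("stored edge weights must be positive")
        if np.isfinite(np.diagonal(self.weights)).any():
            raise ConfigurationError("self-edges are not allowed")

    @property
    def n_edges(self) -> int:
        return int(np.isfinite(self.weights).sum())

    def edges(self) -> list[tuple[str, str, float]]:
        ii, jj = np.where(np.isfinite(self.weights))
        return [
            (self.nodes[i], self.nodes[j], float(self.weights[i, j]))
            for i, j in zip(ii, jj)
        ]


def threshold_network(
    coef: np.ndarray,
    tstat: np.ndarray,
    df: int,
    nodes: list[str],
    alpha: float = 0.05,
    seed_node: str = SEED_NODE,
) -> DirectedNetwork:
    """Keep positive, individually significant coefficients as edge weights.

    An entry is retained when its coefficient is positive and its regression
    t statistic passes the one-sided test P(T_df >= t) < alpha (positive GC
    preserved; one-sided because only the positive direction is retained).
    Retained weights are the coefficients standardized by the dispersion of
    all off-diagonal entries — a scale-only z transform, so weights stay
    positive and remain comparable across cohorts.
    """
    k = coef.shape[0]
    off = ~np.eye(k, dtype=bool)
    vals = coef[off]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2 or vals.std() == 0:
        raise ConfigurationError("too few finite coefficients to standardize")
    with np.errstate(invalid="ignore"):
        pvals = stats.t.sf(tstat, df)
        keep = off & np.isfinite(coef) & (coef > 0) & (pvals < alpha)
    weights = np.where(keep, coef / vals.std(), np.nan)
    if not keep.any():
        warnings.warn("no edge survived thresholding; returning empty network")
    return DirectedNetwork(nodes=list(nodes), weights=weights, seed_node=seed_node)


def compute_degrees(net: DirectedNetwork) -> pd.DataFrame:
    """Weighted out/in/net degree and node class for every node.

    net = out - in; sums to zero exactly over nodes. Classes: positive net
    with an incoming edge from the seed -> "transitional"; positive net
    otherwise -> "source"; negative -> "target"; zero -> "neutral".
    """
    import math

    w = np.where(np.isfinite(net.weights), net.weights, 0.0)
    # exactly-rounded sums: conservation (sum of net degrees = 0) then holds
    # to 1 ulp, since every edge contributes +w to one node and -w to another
    out_deg = np.array([math.fsum(row) for row in w])
    in_deg = np.array([math.fsum(col) for col in w.T])
    net_deg = np.array([
        math.fsum(list(w[i]) + [-v for v in w[:, i]]) for i in range(len(w))
    ])
    seed_idx = net.nodes.index(net.seed_node) if net.seed_node in net.nodes else None
    classes = []
    for i, nd in enumerate(net_deg):
        if nd > 0:
            from_seed = (
                seed_idx is not None
                and i != seed_idx
                and np.isfinite(net.weights[seed_idx, i])
            )
            classes.append("transitional" if from_seed else "source")
        elif nd < 0:
            classes.append("target")
        else:
            classes.append("neutral")
    return pd.DataFrame({
        "node": net.nodes,
        "out_degree": out_deg,
        "in_degree": in_deg,
        "net_degree": net_deg,
        "class": classes,
    })


def to_networkx(net: DirectedNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for u, v, w in net.edges():
        g.add_edge(u, v, weight=w)
    return g


def export_network(net: DirectedNetwork, degrees: pd.DataFrame, outdir) -> None:
    """Write edges.tsv, degrees.tsv (descending net degree) and network.graphml."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(net.edges(), columns=["source", "target", "weight_z"])
    edges.to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.6g")
    degrees.sort_values("net_degree", ascending=False, kind="mergesort").to_csv(
        outdir / "degrees.tsv", sep="\t", index=False, float_format="%.6g"
    )
    nx.write_graphml(to_networkx(net), outdir / "network.graphml")


def read_graphml(path) -> DirectedNetwork:
    g = nx.read_graphml(path)
    nodes = list(g.nodes())
    k = len(nodes)
    weights = np.full((k, k), np.nan)
    for u, v, data in g.edges(data=True):
        weights[nodes.index(u), nodes.index(v)] = data["weight"]
    return DirectedNetwork(nodes=nodes, weights=weights)


def plot_degrees(degrees: pd.DataFrame, path) -> None:
    """Horizontal bar chart of out/in/net degree, ranked by net degree."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = degrees.sort_values("net_degree", ascending=True)
    y = np.arange(len(d))
    fig, ax = plt.subplots(figsize=(7, max(3, 0.4 * len(d))))
    ax.barh(y + 0.25, d["out_degree"], height=0.25, label="out-degree")
    ax.barh(y, d["in_degree"], height=0.25, label="in-degree")
    ax.barh(y - 0.25, d["net_degree"], height=0.25, label="net-degree")
    ax.set_yticks(y, d["node"])
    ax.axvline(0, color="k", lw=0.8)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
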