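"""Synthetic atrophy-cascade cohorts with known ground truth.

The generator emulates the statistical structure a causal structural
covariance network (CaSCN) analysis assumes: a patient group whose
gray-matter volume (GMV) loss starts in an origin region at low symptom
severity and propagates along a directed cascade, so that downstream
regions' loss lags the origin's along the severity ordering; plus a control
group, covariate effects on global GMV, voxel noise, and Gaussian spatial
smoothing.

Each region follows a logistic atrophy trajectory in severity:

    lost_fraction(s) = amplitude * logistic((s - onset) / slope)

``onset`` is the severity at which loss reaches half its asymptote, so an
edge parent -> child with onset(child) > onset(parent) plants the lead-lag
structure the Granger analysis is meant to detect. Subjects are mutually
independent draws; the only "causal" signal available to the downstream
analysis is the shape of these trajectories, which is exactly the situation
of a cross-sectional pseudo-time series.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from . import io as cio
from .errors import ConfigurationError

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class RegionSpec:
    """A spherical cascade region and its logistic atrophy trajectory.

    amplitude: fraction of baseline GMV lost at full severity (0 <= a < 1);
    onset: severity score at which loss accelerates (logistic midpoint);
    slope: severity units controlling sigmoid steepness.
    """

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude: float
    onset: float
    slope: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude < 1.0):
            raise ConfigurationError(f"{self.name}: amplitude must be in [0, 1)")
        if self.slope <= 0:
            raise ConfigurationError(f"{self.name}: slope must be > 0")


def atrophy_fraction(severity, region: RegionSpec):
    """Fraction of baseline GMV lost at ``severity`` (logistic trajectory).

    Strictly increasing in severity, -> 0 as severity -> -inf and ->
    ``region.amplitude`` as severity -> +inf; total on all real inputs.
    """
    return region.amplitude * expit(
        (np.asarray(severity, dtype=float) - region.onset) / region.slope
    )


@dataclass
class CascadeSpec:
    """Full recipe for one synthetic cohort.

    ``edges`` are (parent_name, child_name) pairs; every edge must satisfy
    onset(child) > onset(parent), which makes onsets strictly increasing
    along every directed path. ``covariate_effects`` are additive GMV shifts
    (same units as ``baseline_gmv``) per unit of the centered covariate.
    """

    regions: list[RegionSpec]
    edges: list[tuple[str, str]]
    severity_range: tuple[int, int] = (14, 42)
    noise_sd: float = 0.35
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": -0.0015, "sex": 0.012, "tiv": 8e-5}
    )
    n_patients: int = 87
    n_controls: int = 83
    smoothing_fwhm_mm: float = 6.0
    rng_seed: int = 0
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.5
    baseline_gmv: float = 0.6
    mask_radius_mm: float = 33.0
    mask_exponent: float = 4.0
    mask_center_mm: tuple[float, float, float] = (0.0, -23.0, 2.0)
    max_overlap_fraction: float = 0.05

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ConfigurationError("region names must be unique")
        by_name = {r.name: r for r in self.regions}
        for parent, child in self.edges:
            if parent not in by_name or child not in by_name:
                raise ConfigurationError(f"edge ({parent}, {child}) names unknown region")
            if not by_name[child].onset > by_name[parent].onset:
                raise ConfigurationError(
                    f"edge ({parent}, {child}) violates onset monotonicity: "
                    f"{by_name[child].onset} <= {by_name[parent].onset}"
                )
        lo, hi = self.severity_range
        if not lo < hi:
            raise ConfigurationError("severity_range must be increasing")
        if self.n_patients < 8 or self.n_controls < 2:
            raise ConfigurationError("need >= 8 patients and >= 2 controls")

    @property
    def affine(self) -> np.ndarray:
        """Isotropic affine placing the mask center mid-grid."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        center_vox = (np.asarray(self.grid_shape) - 1) / 2.0
        aff[:3, 3] = np.asarray(self.mask_center_mm) - self.voxel_size_mm * center_vox
        return aff

    def region_by_name(self, name: str) -> RegionSpec:
        return next(r for r in self.regions if r.name == name)

    def parents(self) -> set[str]:
        return {p for p, _ in self.edges}

    def children(self) -> set[str]:
        return {c for _, c in self.edges}

    def terminal_regions(self) -> list[str]:
        return [r.name for r in self.regions if r.name not in self.parents()
                and r.name in self.children()]

    def origin_region(self) -> RegionSpec:
        roots = [r for r in self.regions if r.name not in self.children()]
        return min(roots, key=lambda r: r.onset)


def default_fixture(rng_seed: int = 0, **overrides) -> CascadeSpec:
    """The reference 8-region cascade on a 48-cubed 1.5 mm grid.

    One origin ("thalamus", centered at MNI (0, -23, 2)), three transitional
    regions fed by the origin, and four terminal regions fed by the
    transitional layer. Amplitude and onset decrease/increase with cascade
    depth: downstream regions atrophy later and, over the observed severity
    window, less -- the configuration in which an order-1 signed-path
    Granger analysis can recover direction from cross-sectional data.
    """
    c = np.asarray([0.0, -23.0, 2.0])
    off = lambda d: tuple(c + d)  # noqa: E731
    regions = [
        RegionSpec("thalamus", off((0, 0, 0)), 8.0, 0.55, 18.0, 8.0),
        RegionSpec("trans_a", off((24, 0, 0)), 8.0, 0.52, 25.0, 9.0),
        RegionSpec("trans_b", off((-24, 0, 0)), 8.0, 0.52, 25.0, 9.0),
        RegionSpec("trans_c", off((0, 24, 0)), 8.0, 0.52, 25.0, 9.0),
        RegionSpec("term_d", off((0, -24, 0)), 7.0, 0.38, 31.0, 9.0),
        RegionSpec("term_e", off((0, 0, 24)), 7.0, 0.38, 31.0, 9.0),
        RegionSpec("term_f", off((0, 0, -24)), 7.0, 0.38, 31.0, 9.0),
        RegionSpec("term_g", off((14, 14, 14)), 7.0, 0.38, 31.0, 9.0),
    ]
    edges = [
        ("thalamus", "trans_a"),
        ("thalamus", "trans_b"),
        ("thalamus", "trans_c"),
        ("trans_a", "term_d"),
        ("trans_b", "term_e"),
        ("trans_c", "term_f"),
        ("trans_a", "term_g"),
    ]
    return CascadeSpec(regions=regions, edges=edges, rng_seed=rng_seed, **overrides)


def _gm_mask(spec: CascadeSpec) -> np.ndarray:
    """Superellipsoid "brain": |x/a|^p + |y/a|^p + |z/a|^p <= 1 in mm.

    Exponent 2 gives a ball; the default 4 gives a rounded box that fills
    more of the grid, keeping the planted regions a small fraction of the
    analysis mask (as real atrophy clusters are of a whole-brain mask).
    """
    shape = spec.grid_shape
    aff = spec.affine
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ijk = np.stack([g.ravel() for g in grids], axis=-1)
    mm = ijk @ aff[:3, :3].T + aff[:3, 3]
    d = np.abs(mm - np.asarray(spec.mask_center_mm)) / spec.mask_radius_mm
    return (np.sum(d ** spec.mask_exponent, axis=1) <= 1.0).reshape(shape)


def _check_overlaps(region_masks: dict[str, np.ndarray], max_frac: float) -> None:
    names = list(region_masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            ma, mb = region_masks[a], region_masks[b]
            inter = np.logical_and(ma, mb).sum()
            if inter > max_frac * min(ma.sum(), mb.sum()):
                raise ConfigurationError(
                    f"regions {a!r} and {b!r} overlap by {inter} voxels; "
                    "ground truth would be confounded"
                )


def _draw_severities(spec: CascadeSpec, rng: np.random.Generator) -> np.ndarray:
    """Integer severities, uniform over the range, with occupied quartile stages."""
    from .vbm import quartile_stages  # local import: vbm has no dependency back

    lo, hi = spec.severity_range
    for _ in range(100):
        sev = rng.integers(lo, hi + 1, size=spec.n_patients)
        try:
            stagedef = quartile_stages(sev)
        except Exception:
            continue
        labels = np.array([stagedef.assign(s) for s in sev])
        if all((labels == k).sum() >= 2 for k in range(1, len(stagedef.boundaries) + 1)):
            return sev
    raise ConfigurationError(
        "could not draw a severity sample with >= 2 patients per quartile stage"
    )


def _participants_table(spec: CascadeSpec, rng: np.random.Generator) -> pd.DataFrame:
    sev = _draw_severities(spec, rng)
    n_p, n_c = spec.n_patients, spec.n_controls
    n = n_p + n_c

    age = np.clip(np.round(rng.normal(26.0, 5.5, n), 1), 16.0, 45.0)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    education = np.clip(np.round(rng.normal(12.0, 2.5, n), 1), 6.0, 20.0)
    tiv = np.round(rng.normal(1450.0, 120.0, n), 1)

    duration = np.round(np.exp(rng.normal(np.log(36.0), 0.6, n_p)), 1)  # months
    onset_age = np.round(np.maximum(age[:n_p] - duration / 12.0, 14.0), 1)
    cpz = np.round(np.clip(rng.normal(420.0, 160.0, n_p), 50.0, 1500.0), 1)

    p3 = np.clip(4 + np.round((sev - 14) / 9.0).astype(int)
                 + rng.integers(-1, 2, n_p), 4, 7)

    rows = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "group": ["patient"] * n_p + ["control"] * n_c,
        "age": age,
        "sex": sex,
        "education": education,
        "tiv": tiv,
        "ahs_score": np.concatenate([sev, np.zeros(n_c, dtype=int)]),
        "p3_score": np.concatenate([p3, np.ones(n_c, dtype=int)]),
        "illness_duration": np.concatenate([duration, np.full(n_c, np.nan)]),
        "onset_age": np.concatenate([onset_age, np.full(n_c, np.nan)]),
        "cpz_dose": np.concatenate([cpz, np.full(n_c, np.nan)]),
    })
    return rows


def generate_cohort(spec: CascadeSpec) -> cio.Cohort:
    """Simulate one cohort; bit-identical across runs for the same spec.

    Each patient volume is baseline + covariate shifts - per-region logistic
    atrophy of the baseline + white Gaussian noise, then smoothed at
    ``smoothing_fwhm_mm``. Controls are identical with the atrophy term
    zero. The returned cohort carries ``ground_truth = spec``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    table = _participants_table(spec, rng)
    mask = _gm_mask(spec)
    aff = spec.affine
    shape = spec.grid_shape

    region_masks = {
        r.name: cio.sphere_mask(
            cio.SeedSpec(tuple(r.center_mm), r.radius_mm), shape, aff, gm_mask=mask
        )
        for r in spec.regions
    }
    _check_overlaps(region_masks, spec.max_overlap_fraction)

    sigma_vox = spec.smoothing_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
    base = spec.baseline_gmv
    eff = spec.covariate_effects
    age0, tiv0 = table["age"].mean(), table["tiv"].mean()

    n = len(table)
    volumes = np.empty((n,) + shape, dtype=np.float64)
    for i, row in table.iterrows():
        shift = (
            eff.get("age", 0.0) * (row["age"] - age0)
            + eff.get("sex", 0.0) * (1.0 if row["sex"] == "M" else 0.0)
            + eff.get("tiv", 0.0) * (row["tiv"] - tiv0)
        )
        vol = np.where(mask, base + shift, 0.0)
        if row["group"] == "patient":
            for r in spec.regions:
                frac = float(atrophy_fraction(row["ahs_score"], r))
                vol[region_masks[r.name]] -= frac * base
        vol += rng.normal(0.0, spec.noise_sd, size=shape)
        volumes[i] = gaussian_filter(vol, sigma=sigma_vox)

    return cio.Cohort(volumes, aff, mask, table, ground_truth=spec)


# ---------------------------------------------------------------------------
# on-disk cohort directories
# ---------------------------------------------------------------------------

def ground_truth_dict(spec: CascadeSpec) -> dict:
    return {
        "regions": [
            {
                "name": r.name,
                "center_mm": list(r.center_mm),
                "radius_mm": r.radius_mm,
                "amplitude": r.amplitude,
                "onset": r.onset,
                "slope": r.slope,
            }
            for r in spec.regions
        ],
        "edges": [list(e) for e in spec.edges],
        "severity_range": list(spec.severity_range),
        "rng_seed": spec.rng_seed,
    }


def write_cohort(cohort: cio.Cohort, outdir: str | os.PathLike) -> Path:
    """Write a cohort directory: per-subject NIfTIs, mask, participants.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(cohort.participants["subject_id"]):
        cio.write_nifti(cohort.volumes[i], cohort.affine, outdir / f"{sid}.nii.gz")
    cio.write_nifti(cohort.mask, cohort.affine, outdir / "mask.nii.gz")
    cio.write_participants(cohort.participants, outdir / "participants.tsv")
    if cohort.ground_truth is not None:
        (outdir / "ground_truth.json").write_text(
            json.dumps(ground_truth_dict(cohort.ground_truth), indent=2)
        )
    return outdir


def read_cohort_dir(path: str | os.PathLike) -> cio.Cohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    table = cio.read_participants(path / "participants.tsv")
    images = [path / f"{sid}.nii.gz" for sid in table["subject_id"]]
    return cio.read_cohort(images, path / "participants.tsv", path / "mask.nii.gz")
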