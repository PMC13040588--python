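import dataclasses

import numpy as np
import pytest

from cascn.simulate import CascadeSpec, RegionSpec, default_fixture, generate_cohort


def small_spec(rng_seed: int = 0, **overrides) -> CascadeSpec:
    """A two-region cascade on a 24^3 grid: fast enough for unit tests."""
    base = dict(
        regions=[
            RegionSpec("origin", (0.0, -23.0, 2.0), 5.0, 0.50, 18.0, 8.0),
            RegionSpec("child", (0.0, -13.0, 2.0), 4.0, 0.40, 27.0, 9.0),
        ],
        edges=[("origin", "child")],
        n_patients=24,
        n_controls=16,
        grid_shape=(24, 24, 24),
        mask_radius_mm=15.0,
        mask_exponent=2.0,
        rng_seed=rng_seed,
    )
    base.update(overrides)
    return CascadeSpec(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_spec(rng_seed=3))


@pytest.fixture(scope="session")
def fixture_spec():
    return default_fixture(rng_seed=1)


@pytest.fixture(scope="session")
def fixture_cohort(fixture_spec):
    """One full-size reference cohort (87 patients / 83 controls, 48^3)."""
    return generate_cohort(fixture_spec)


@pytest.fixture(scope="session")
def fixture_cohort_dir(fixture_cohort, tmp_path_factory):
    from cascn.simulate import write_cohort

    out = tmp_path_factory.mktemp("cohort")
    write_cohort(fixture_cohort, out)
    return out


def make_pts(series: np.ndarray, covariates: np.ndarray | None = None):
    """Wrap a raw (subjects x voxels) matrix as a PseudoTimeSeries."""
    from cascn.voxelwise import PseudoTimeSeries

    n, v = series.shape
    mask = np.ones((v, 1, 1), dtype=bool)
    return PseudoTimeSeries(
        order=np.arange(n),
        order_key="ahs_rank",
        key_values=np.arange(n),
        series=series,
        covariate_matrix=covariates if covariates is not None else np.empty((n, 0)),
        covariate_names=(),
        subject_ids=[f"s{i}" for i in range(n)],
        mask=mask,
        affine=np.eye(4),
    )
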