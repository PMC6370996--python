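"""Shared fixtures: synthetic cohorts at the sizes each study needs.

The 20-case cohort mirrors the study conditions (default grid, noise and
volume ranges); smaller cohorts back unit tests.  All fixtures are
session-scoped because cohort generation dominates suite runtime.
"""

import numpy as np
import pytest

import geodvh as gd


@pytest.fixture(scope="session")
def small_cohort():
    """Six cases on a reduced grid, two plan types: fast unit-test cohort."""
    params = gd.CohortParams(
        n_cases=6,
        grid_dims=(64, 64, 48),
        gtv_volume_range_mL=(4.0, 40.0),
        master_seed=7,
    )
    return params, gd.make_cohort(params, ("InitPlan", "Boost1"))


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    _, cohort = small_cohort
    return gd.prepare_cohort([sc.case for sc in cohort], ("InitPlan", "Boost1"))


@pytest.fixture(scope="session")
def cohort20():
    """The default 20-case study cohort with all four plan types."""
    return gd.make_cohort(gd.CohortParams(master_seed=0))


@pytest.fixture(scope="session")
def prepared20(cohort20):
    return gd.prepare_cohort([sc.case for sc in cohort20])


@pytest.fixture(scope="session")
def deterministic_cohort():
    """Noise-free cohort: dose is an exact function of distance and field."""
    params = gd.CohortParams(
        n_cases=10,
        grid_dims=(80, 80, 56),
        falloff=gd.FalloffParams(noise_sd=0.0, case_jitter_sd=0.0),
        master_seed=11,
    )
    return gd.make_cohort(params, ("InitPlan",))


@pytest.fixture(scope="session")
def deterministic_prepared(deterministic_cohort):
    return gd.prepare_cohort([sc.case for sc in deterministic_cohort], ("InitPlan",))


def random_mask(grid: gd.VoxelGrid, rng: np.random.Generator, p: float = 0.2):
    return gd.StructureMask(grid, rng.random(grid.dims) < p, "random")


def brute_force_signed_distance(oar: gd.StructureMask, target: gd.StructureMask):
    """O(N*M) all-pairs oracle for the signed distance map."""
    sp = np.asarray(target.grid.spacing)
    tgt = np.argwhere(target.inside) * sp
    non = np.argwhere(~target.inside) * sp
    out = []
    for vox in np.argwhere(oar.inside):
        p = vox * sp
        if target.inside[tuple(vox)]:
            d = -np.sqrt(((non - p) ** 2).sum(axis=1)).min()
        else:
            d = np.sqrt(((tgt - p) ** 2).sum(axis=1)).min()
        out.append(d)
    return np.asarray(out)
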