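"""Shared fixtures: phantom specs at several scales and the one full-size
end-to-end study used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from mntrace.phantom import GroupPlan, InjectionPlan, PhantomSpec, make_phantom_atlas, simulate_cohorts
from mntrace.pipeline import analyze_study, preprocess_cohorts


def clean_spec(**overrides) -> PhantomSpec:
    """Default-geometry spec with all nuisances switched off."""
    base = dict(
        rigid_jitter_mm=0.0,
        rigid_jitter_deg=0.0,
        warp_jitter_mm=0.0,
        bias_amplitude=0.0,
        scale_range=(1.0, 1.0),
        noise_sigma=0.0,
        seed=0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


def small_null_spec(seed: int = 0, n: int = 8, noise_sigma: float = 0.04) -> PhantomSpec:
    """Reduced 32^3 cohort with no injection and no planted enhancement."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        brain_semi_mm=(1.25, 1.25, 1.1),
        n_subjects_per_group=n,
        group_defs={"A": GroupPlan(), "B": GroupPlan()},
        rigid_jitter_mm=0.0,
        rigid_jitter_deg=0.0,
        warp_jitter_mm=0.0,
        bias_amplitude=0.0,
        scale_range=(1.0, 1.0),
        noise_sigma=noise_sigma,
        seed=seed,
    )


@pytest.fixture(scope="session")
def default_atlas():
    return make_phantom_atlas(PhantomSpec())


@pytest.fixture(scope="session")
def clean_atlas():
    return make_phantom_atlas(clean_spec())


@pytest.fixture(scope="session")
def full_study():
    """The complete default two-cohort study (n = 10/group), simulated,
    preprocessed (MDT + two-step warp propagation) and analyzed once.

    Seeds are fixed constants of the suite, independent of any CLI seed.
    """
    spec = PhantomSpec(n_subjects_per_group=10, seed=1)
    cohorts, truth = simulate_cohorts(spec)
    pre = preprocess_cohorts(cohorts, seed=101)
    study = analyze_study(pre, truth.atlas, roi_segments=["DS", "RTN", "SNr", "BLA"])
    return {"spec": spec, "cohorts": cohorts, "truth": truth, "pre": pre, "study": study}


PLANTED_24H = {
    "ACA": {"ACA", "DS", "RTN", "SNr", "PAG", "LC", "DMH", "MBO"},
    "ILPL": {"ILPL", "BLA", "AHN", "LHA"},
}


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
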