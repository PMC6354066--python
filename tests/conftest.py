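import numpy as np
import pytest

from murivol.cohort import CohortSpec, ModalityParams, default_cohort_spec, make_cohort


def coarse_modalities():
    """Coarsened acquisition grids (same field of view) for fast tests."""
    intensity = {"GM": 100.0, "WM": 70.0, "CSF": 130.0, "background": 10.0}
    iv = ModalityParams(0.30, (39, 39, 39), intensity, noise_sd=30.0)
    ex = ModalityParams(0.15, (78, 78, 78), intensity, noise_sd=12.0)
    return iv, ex


@pytest.fixture(scope="session")
def fast_spec() -> CohortSpec:
    iv, ex = coarse_modalities()
    return default_cohort_spec().replace(invivo=iv, exvivo=ex)


@pytest.fixture(scope="session")
def fast_cohort(fast_spec):
    return make_cohort(fast_spec, 7)


@pytest.fixture(scope="session")
def rendered_subject(fast_spec, fast_cohort):
    """One rendered in vivo phantom (image + truth labels) at the coarse grid."""
    from murivol.phantom import render_phantom
    traj = fast_cohort[0]
    img, lab = render_phantom(traj.invivo_volumes[0], fast_spec.structures,
                              fast_spec.invivo, seed=3)
    return traj, img, lab


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
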