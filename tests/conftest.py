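import numpy as np
import pytest
from hypothesis import settings

from fibsafe.geometry import CrossSection, LandmarkSet
from fibsafe.synthetic import CohortParams, generate_cohort, generate_cross_section

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_section(contour, anchor1, anchor4, apex7, apex8, apex9, subject_id="T", **kw):
    lm = LandmarkSet(
        anterior_anchor=anchor1,
        posterior_anchor=anchor4,
        anterior_apex=apex7,
        posterior_apex=apex8,
        lateral_apex=apex9,
    )
    return CrossSection(
        subject_id=subject_id, side="right", fibula_contour=np.asarray(contour, float),
        landmarks=lm, **kw,
    )


@pytest.fixture
def equilateral_section():
    """Equilateral triangle, apexes at its vertices, anchors far medial."""
    h = 5.0 * np.sqrt(3.0)
    contour = [[5.0, 0.0], [0.0, h], [-5.0, 0.0]]
    return make_section(
        contour, [3.0, -15.0], [-3.0, -15.0], [5.0, 0.0], [-5.0, 0.0], [0.0, h]
    )


@pytest.fixture
def asym_triangle_section():
    """Anterolateral edge exactly 15 mm, posterolateral exactly 10 mm."""
    apex9 = np.array([0.0, 8.0])
    apex7 = np.array([np.sqrt(15.0**2 - 64.0), 0.0])
    apex8 = np.array([-np.sqrt(10.0**2 - 64.0), 0.0])
    contour = [apex7, apex9, apex8, [0.0, -1.5]]
    return make_section(contour, [8.0, -20.0], [-8.0, -20.0], apex7, apex8, apex9)


@pytest.fixture
def symmetric_section():
    """Isosceles section with both anchors on the symmetry axis."""
    contour = [[12.0, 0.0], [0.0, 15.0], [-12.0, 0.0], [0.0, -2.0]]
    return make_section(
        contour, [0.0, -20.0], [0.0, -28.0], [12.0, 0.0], [-12.0, 0.0], [0.0, 15.0]
    )


@pytest.fixture
def wedge_section():
    """Convex section with medial-wedge anchors: through-apex axes exit at the apexes."""
    contour = [[12.0, 0.0], [0.0, 15.0], [-12.0, 0.0], [0.0, -2.0]]
    return make_section(
        contour, [10.0, -30.0], [-10.0, -30.0], [12.0, 0.0], [-12.0, 0.0], [0.0, 15.0]
    )


@pytest.fixture
def noiseless_params():
    return CohortParams(landmark_noise_sd_mm=0.0, seed=123)


def random_convex_section(rng, params=None, subject_id="R"):
    """A random convex synthetic section (triangular or triangular-convex)."""
    params = params or CohortParams(landmark_noise_sd_mm=0.0, seed=0)
    cls = "triangular_convex" if rng.random() < 0.7 else "triangular"
    cs, truth = generate_cross_section(params, cls, rng, subject_id=subject_id)
    return cs, truth


@pytest.fixture(scope="session")
def noiseless_cohort_200():
    params = CohortParams(n_subjects=200, landmark_noise_sd_mm=0.0, seed=2024)
    return generate_cohort(params)


@pytest.fixture(scope="session")
def default_cohort_96():
    return generate_cohort(CohortParams(n_subjects=96, seed=96))
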