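import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from gallerytrack.datamodel import (Gallery, ImageAnnotation, Point,
                                    ProjectState, Status)
from gallerytrack.synthgen import GrowthParams, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def straight_pair():
    """A horizontal primary with a child branching from its midpoint."""
    a = Gallery("A", [Point(0, 0), Point(10, 0)])
    b = Gallery("B", [Point(5, 0.5), Point(5.5, 8)])
    return a, b


@pytest.fixture
def small_project():
    """Two images, three galleries, all optional fields populated."""
    state = ProjectState(threshold_px=5.0, scale_mm=30.0)
    state.entrance_points["arena"] = [Point(0.0, 0.0)]
    state.add(ImageAnnotation(
        group_id="arena", serial=0, status=Status.ANALYZED,
        ref_point=Point(2.0, 3.0), scale_line=(Point(0, 0), Point(60, 0)),
        galleries=[Gallery("g00", [Point(2, 3), Point(42, 3)])]))
    state.add(ImageAnnotation(
        group_id="arena", serial=1, status=Status.ANALYZED,
        ref_point=Point(2.5, 3.5), scale_line=(Point(0, 0), Point(60, 0)),
        galleries=[
            Gallery("g00", [Point(2.5, 3.5), Point(42.5, 3.5), Point(82.5, 3.5)]),
            Gallery("g01", [Point(42.5, 4.0), Point(43.0, 33.5)]),
        ]))
    return state


@pytest.fixture(scope="session")
def grown_structure():
    """One deterministic synthetic growth sequence with ground truth."""
    return generate(GrowthParams(seed=7, n_steps=20))
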