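"""Shared synthetic movies; session-scoped because generation is the
expensive part of most tests."""

import numpy as np
import pytest

import bordercell as bc
from bordercell import synthetic


@pytest.fixture(scope="session")
def fixture_specs():
    return synthetic.fixture_specs(seed=0)


@pytest.fixture(scope="session")
def category_movies(fixture_specs):
    """Rendered tight/loose/balanced movies with their ground truth."""
    out = {}
    for name in ("tight", "loose", "balanced"):
        out[name] = bc.generate(fixture_specs[name])
    return out


@pytest.fixture(scope="session")
def sink_movie(fixture_specs):
    return bc.generate(fixture_specs["sink_flow"])


@pytest.fixture(scope="session")
def translation_movie(fixture_specs):
    return bc.generate(fixture_specs["translation_pair"])


@pytest.fixture(scope="session")
def bleach_movie(fixture_specs):
    return bc.generate(fixture_specs["bleaching"])


@pytest.fixture(scope="session")
def category_regions(category_movies):
    """Recovered region sets for the three category movies."""
    out = {}
    for name, (stack, truth) in category_movies.items():
        frame = bc.subtract_background(stack.frames[0, 0])
        out[name] = (
            frame,
            bc.build_region_set(frame, truth.landmarks, stack.pixel_size_um),
        )
    return out


@pytest.fixture()
def speckle_pair():
    """48x48 noise-free speckle frame and its integer-shifted copy."""
    rng = np.random.default_rng(7)
    frame = np.exp(rng.normal(0, 0.3, size=(48, 48))) * 100
    shifted = np.roll(frame, shift=(0, 3), axis=(0, 1))  # (dx, dy) = (3, 0)
    return frame, shifted
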