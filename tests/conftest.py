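"""Shared fixtures.

Expensive artifacts (rendered phantoms, full scenario runs) are built once
per session and shared between the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from octeye import (analyze_bscan, analyze_stack, load_scenario,
                    mouse_geometry, model_eye_geometry, render_bscan,
                    render_timeseries)
from octeye.phantom import TissueOptics, default_imaging


@pytest.fixture(scope="session")
def mouse_geom():
    return mouse_geometry()


@pytest.fixture(scope="session")
def optics():
    return TissueOptics()


@pytest.fixture(scope="session")
def baseline_image(mouse_geom, optics):
    """Noiseless B-scan of the mouse baseline eye."""
    return render_bscan(mouse_geom, optics)


@pytest.fixture(scope="session")
def baseline_analysis(baseline_image, optics):
    """(record, raw surfaces, corrected surfaces) of the baseline frame."""
    return analyze_bscan(baseline_image, optics=optics)


@pytest.fixture(scope="session")
def model_eye_analysis():
    geom = model_eye_geometry()
    optics = TissueOptics()
    img = render_bscan(geom, optics, default_imaging("model_eye"))
    return analyze_bscan(img, optics=optics)


@pytest.fixture(scope="session")
def group1_run():
    """Noiseless Group-I time series measured end to end."""
    scenario = load_scenario("group1")
    frames, truth = render_timeseries(scenario, seed=1, noise=False)
    measured = analyze_stack(frames)
    return scenario, frames, truth, measured


@pytest.fixture(scope="session")
def group4_run():
    scenario = load_scenario("group4")
    frames, truth = render_timeseries(scenario, seed=2, noise=False)
    measured = analyze_stack(frames)
    return scenario, frames, truth, measured


@pytest.fixture(scope="session")
def control_noisy_run():
    """60-min control arm with the default speckle model, fixed seed."""
    scenario = load_scenario("control")
    frames, truth = render_timeseries(scenario, seed=7, noise=True)
    measured = analyze_stack(frames)
    return scenario, frames, truth, measured


@pytest.fixture(scope="session")
def noisy_image(mouse_geom, optics):
    return render_bscan(mouse_geom, optics, noise_seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
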