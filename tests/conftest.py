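"""Shared fixtures: calibrated reduced-order heart models.

The calibrated baseline is computed once per session (it is deterministic)
and shared across ventricle, circulation, valve and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiosim.circulation import HeartModel, run_cycle
from cardiosim.materials import ActiveLaw
from cardiosim.ventricle import VentricleGeometry, calibrate_baseline, size_infarct


@pytest.fixture(scope="session")
def baseline_calibration():
    return calibrate_baseline(HeartModel())


@pytest.fixture(scope="session")
def healthy_model(baseline_calibration):
    cal = baseline_calibration
    return HeartModel(
        geom=VentricleGeometry(aspect=cal.aspect),
        active=ActiveLaw(T_max=cal.T_max),
    )


@pytest.fixture(scope="session")
def healthy_cycle(healthy_model):
    return run_cycle(healthy_model)


@pytest.fixture(scope="session")
def sized_infarct(healthy_model):
    return size_infarct(healthy_model, ef_target=0.45)


@pytest.fixture(scope="session")
def infarcted_cycle(healthy_model, sized_infarct):
    return run_cycle(healthy_model.with_infarct(sized_infarct))


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def study_result(tmp_path_factory):
    """Full three-arm study with default configuration (expensive; shared
    by the study-level and acceptance tests)."""
    from cardiosim.config import StudyConfig
    from cardiosim.study import run_study

    out = tmp_path_factory.mktemp("study")
    return run_study(StudyConfig(), out_dir=out), out
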