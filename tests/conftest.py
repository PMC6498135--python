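import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqsecrete import presets
from seqsecrete.chip_sim import simulate_chip
from seqsecrete.tracking import CellTimeCourse

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_chip():
    """One default chip (18,000 wells, retention 0.56) with ground truth."""
    config = presets.default_config(seed=303)
    wells, truth = simulate_chip(config)
    return config, wells, truth


@pytest.fixture(scope="session")
def pattern_cohort():
    """1752 complete courses generated with the study's printed
    stable-pattern probabilities for CCL2 / TNF / IL-6."""
    config = presets.pattern_validation_config(seed=101)
    courses, truth, panel = presets.build_cohort(config)
    return config, courses, truth, panel


@pytest.fixture(scope="session")
def coupling_cohort():
    """1752 complete courses under generator defaults (basal coupling 0.5,
    two latent states) at full retention."""
    config = presets.coupling_validation_config(seed=202)
    courses, truth, panel = presets.build_cohort(config)
    return config, courses, truth, panel


def make_course(calls, log2=None, cell_id="c0", present=None, row=0, col=0):
    """Small helper to build a course from a (T, K) call matrix."""
    calls = np.asarray(calls, dtype=int)
    if log2 is None:
        log2 = calls * 10.0
    if present is None:
        present = np.ones(calls.shape[0], dtype=bool)
    return CellTimeCourse(cell_id=cell_id, chip_id="chip01", row=row, col=col,
                          log2=np.asarray(log2, float), calls=calls,
                          present=np.asarray(present, bool))


@pytest.fixture
def course_factory():
    return make_course
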