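"""Shared fixtures: reference subjects and cohorts, all generated at test time."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ivgttml import synth_cohort as sc
from ivgttml.feature_table import extract_feature_matrix
from ivgttml.secretion_model import (
    cpeptide_kinetics_from_anthropometrics,
    deconvolve_isr,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


NOISE_FREE = {"glucose": 0.0, "insulin": 0.0, "cpeptide": 0.0}


@pytest.fixture(scope="session")
def noise_free_config():
    return sc.SimulationConfig(noise_cv=dict(NOISE_FREE), seed=1)


@pytest.fixture(scope="session")
def reference_truth():
    """One subject at typical non-progressor medians, with known physiology."""
    kin = cpeptide_kinetics_from_anthropometrics(33.0, "F", 65.8, 164.0)
    return sc.SubjectTruth(
        id="REF", group="NON-PROG", age=33.0, body_weight=65.8, height=164.0,
        S_I_true=4.7e-4, S_G_true=0.022, V_true=13.4, p2_true=0.03,
        G_b=4.66, Cp_b=545.0, first_phase_amp=4000.0, second_phase_gain=10.0,
        FE_L_true=0.50, CL_P_true=0.40, cpep_kinetics=kin,
    )


@pytest.fixture(scope="session")
def reference_record(reference_truth, noise_free_config):
    """Noise-free simulated IM-IVGTT of the reference subject."""
    return sc.simulate_ivgtt(reference_truth, noise_free_config)


@pytest.fixture(scope="session")
def reference_dense(reference_truth, noise_free_config):
    """Exact internal states/flows of the reference simulation."""
    return sc.simulate_dense(reference_truth, noise_free_config)


@pytest.fixture(scope="session")
def reference_profile(reference_record, reference_truth):
    return deconvolve_isr(reference_record, reference_truth.cpep_kinetics)


@pytest.fixture(scope="session")
def cohort_features():
    """Extracted 34-feature matrix of a default 78-subject noisy cohort."""
    config = sc.SimulationConfig(seed=20)
    truths = sc.sample_cohort(config)
    records = sc.simulate_cohort(truths, config)
    return extract_feature_matrix(records)


def constant_record(n_extra: int = 0, **overrides) -> sc.IVGTTRecord:
    """A record whose three curves sit at basal throughout (steady state)."""
    times = np.array(sc.SAMPLE_SCHEDULE_MIN if not n_extra else
                     np.linspace(0, 180, 19 + n_extra))
    defaults = dict(
        id="CONST", group="NON-PROG", age=33.0, body_weight=65.8, height=164.0,
        times=times,
        glucose=np.full(times.size, 4.66),
        insulin=np.full(times.size, 156.0),
        cpeptide=np.full(times.size, 545.0),
        glucose_dose=0.0, exo_insulin=0.0,
    )
    defaults.update(overrides)
    return sc.IVGTTRecord(**defaults)
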