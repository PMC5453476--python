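import numpy as np
import pytest

from cpgait.core import Dataset, Domain, GaitTrial, PHASE_TRACKS, Track, compute_normative_band
from cpgait.synthetic import GeneratorConfig, generate_cp_dataset, generate_reference_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    return generate_reference_cohort(56, seed=7)


@pytest.fixture(scope="session")
def band(reference_cohort):
    return compute_normative_band(reference_cohort)


@pytest.fixture(scope="session")
def small_dataset():
    """Small noisy CP dataset shared by feature/evaluation tests."""
    return generate_cp_dataset(GeneratorConfig(n_patients=15, seed=11))


def make_trial(curve_fn, trial_id="t1", patient_id="p1", toe_off=60.0, labels=None):
    """Build a valid trial whose every curve is ``curve_fn(track, domain)``."""
    curves = {}
    for t in Track:
        curves[(t, Domain.FULL_CYCLE)] = curve_fn(t, Domain.FULL_CYCLE)
    for t in PHASE_TRACKS:
        for d in (Domain.STANCE, Domain.SWING):
            curves[(t, d)] = curve_fn(t, d)
    return GaitTrial(
        trial_id=trial_id, session_id=f"{trial_id}-s", patient_id=patient_id,
        toe_off_pct=toe_off, curves=curves, labels=labels or {},
    )


@pytest.fixture
def constant_trial():
    return make_trial(lambda t, d: np.full(51, 5.0))
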