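import pytest
from hypothesis import settings

import hepanet as hp

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def michels1():
    return hp.build_template(hp.Variant.MICHELS_I)


@pytest.fixture(scope="session")
def cohort200():
    """200 Michels-I synthetic patients at the study conditions (noise 0.12,
    buffer-response gain drawn), each run through the default pipeline:
    calibrate on baseline, then the three scenarios with physics-only
    predictions and 15% intervals."""
    patients = hp.generate_cohort(200, seed=11)
    results = []
    for patient in patients:
        baseline_ms = hp.reconcile_baseline(list(patient.measurements))
        calibrated, report = hp.calibrate_outlets(
            hp.observed_network(patient), baseline_ms
        )
        solutions, predictions = hp.predict_scenarios(calibrated)
        results.append(
            {
                "patient": patient,
                "calibrated": calibrated,
                "report": report,
                "solutions": solutions,
                "predictions": predictions,
            }
        )
    return results


@pytest.fixture(scope="session")
def clean_cohort50():
    """50 noise-free, buffer-response-free patients for recovery checks."""
    return hp.generate_cohort(50, seed=7, noise_variability=0.0, habr_gain_true=0.0)
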