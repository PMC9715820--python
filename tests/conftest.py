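import datetime as dt

import pytest

from hfmarkov.cohort import PatientTimeline
from hfmarkov.engine import assign_cohort_states
from hfmarkov.reference import reference_model
from hfmarkov.simulate import GeneratorConfig, generate_cohort_with_paths


@pytest.fixture(scope="session")
def reference_chain():
    model, report = reference_model()
    return model


@pytest.fixture(scope="session")
def medium_synthetic():
    """Shared 20k-patient cohort from the reference ground truth, with
    latent paths and assigned state sequences.

    The 18-cycle (6-year) horizon keeps end-of-study disengagement
    misclassification (a NoEvent run surviving to the horizon reads as Left)
    far below sampling error for the early-transition estimates.
    """
    truth, _ = reference_model()
    config = GeneratorConfig(ground_truth=truth, seed=20240, n_patients=20_000, horizon_cycles=18)
    cohort, paths = generate_cohort_with_paths(config)
    sequences = assign_cohort_states(cohort)
    return config, cohort, paths, sequences


@pytest.fixture
def three_patient_cohort():
    base = dt.date(2012, 3, 1)
    end = dt.date(2014, 3, 1)
    return [
        PatientTimeline(
            patient_id="A",
            baseline_date=base,
            study_end_date=end,
            events=(
                (dt.date(2012, 4, 10), "clinic_visit"),
                (dt.date(2012, 9, 2), "hf_hospitalization"),
                (dt.date(2013, 1, 15), "death"),
            ),
            age_years=71.0,
            sex="male",
            lvef_percent=35.0,
            ntprobnp_ng_per_l=1500.0,
        ),
        PatientTimeline(
            patient_id="B",
            baseline_date=base,
            study_end_date=end,
            events=((dt.date(2012, 5, 20), "clinic_visit"),),
            age_years=59.5,
            sex="female",
            lvef_percent=55.0,
            ntprobnp_ng_per_l=None,
        ),
        PatientTimeline(
            patient_id="C",
            baseline_date=base,
            study_end_date=end,
            events=(),
            age_years=80.2,
            sex="female",
            lvef_percent=48.0,
            ntprobnp_ng_per_l=230.0,
        ),
    ]
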