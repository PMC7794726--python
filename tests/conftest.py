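import numpy as np
import pytest

import resttremor as rt


@pytest.fixture(scope="session")
def oracle_cohort():
    """8-subject cohort with 6-min visits for ground-truth-driven checks."""
    return rt.simulate_cohort(n_subjects=8, visits_per_subject=1,
                              class_mix={0: 2, 1: 3, 2: 3}, seed=0)


@pytest.fixture(scope="session")
def oracle_assessments(oracle_cohort):
    """Per-visit oracle-prediction assessments paired with ground truth."""
    rows = []
    for profile, visit_id, rec, truth in oracle_cohort.visits:
        ws = rt.build_window_set([rec])
        va = rt.assess_windowset(ws, ws.rest_label == 1, ws.tremor_label == 1)
        rows.append((profile, truth, va))
    return rows


@pytest.fixture(scope="session")
def small_windowset():
    """6-subject, 2-min-visit cohort: compact but learnable for CNN tests."""
    script = rt.default_visit_script(n_cycles=2, activity_s=30.0, rest_s=30.0)
    cohort = rt.simulate_cohort(n_subjects=6, visits_per_subject=1,
                                class_mix={0: 1, 1: 3, 2: 2}, seed=0,
                                script=script)
    return rt.build_window_set([rec for _, _, rec, _ in cohort.visits])


@pytest.fixture(scope="session")
def tremor_visit():
    """One mild-tremor visit with ground truth."""
    profile = rt.SubjectProfile(subject_id="s1", has_tremor=True,
                                tremor_frequency_hz=5.0, severity_class=1,
                                target_band_rms_ms2=0.5, constancy_fraction=0.6)
    return (profile,) + rt.simulate_visit(profile, seed=0)


def time_vector(n, fs=50.0):
    return np.arange(n) / fs
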