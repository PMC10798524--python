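import numpy as np
import pandas as pd
import pytest

import riskcontext as rc
from riskcontext.cohort import ScrGenParams
from dataclasses import replace


@pytest.fixture(scope="session")
def choice_set():
    return rc.generate_choice_set(seed=1)


@pytest.fixture(scope="session")
def norm(choice_set):
    return rc.NormalizationScheme.from_choice_set(choice_set)


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects x 240 trials simulated at the default coefficients."""
    sets, recs, params, norm = rc.simulate_cohort(n_subjects=12, seed=7)
    feats = rc.build_cohort_features(sets, recs, norm)
    return {"sets": sets, "recs": recs, "params": params, "norm": norm,
            "features": feats}


@pytest.fixture(scope="session")
def clean_subject(choice_set, norm):
    """One subject with noise-free, never-missing responses and SCR."""
    g = ScrGenParams(amp_noise_sd=0.0, trace_noise_sd=0.0,
                     nonresponse_prob_outcome=0.0, nonresponse_prob_decision=0.0)
    params = replace(rc.sample_subject_params(seed=2), scr=g)
    records = rc.simulate_choices(choice_set, params, norm, seed=3, miss_rate=0.0)
    return {"params": params, "records": records}
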