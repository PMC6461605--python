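import numpy as np
import pandas as pd
import pytest

import longimorph as lm
from longimorph.cohort import CohortDesign


@pytest.fixture(scope="session")
def default_cohort():
    return lm.generate_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 8+8 cohort, three annual visits each."""
    design = CohortDesign(
        n_wolfram=8,
        n_control=8,
        visit_count_probs={"wolfram": [0, 0, 1.0, 0, 0, 0, 0], "control": [0, 0, 1.0]},
        seed=7,
    )
    return lm.generate_cohort(design)


@pytest.fixture(scope="session")
def thalamus_data(default_cohort):
    """Corrected thalamus volume table merged with participant covariates."""
    vols = lm.simulate_roi_volumes(default_cohort, seed=11, regions=("thalamus",))
    corrected = lm.correct_for_etiv(vols.data)
    merged = corrected.merge(default_cohort.participants, on="participant_id")
    return merged, vols
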