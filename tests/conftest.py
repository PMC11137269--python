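import numpy as np
import pytest

import multipattern as mp
from multipattern.synthetic_data import MortalityCoefs


def quiet_overrides(**extra):
    """Turn off utilisation draws for tests that do not need them."""
    base = dict(acute_rate_per_period=0.0, dispensation_rate=0.0)
    base.update(extra)
    return base


@pytest.fixture(scope="session")
def planted_cohort():
    """Three well-separated planted patterns, with attrition and utilisation."""
    cfg = mp.block_config(
        600,
        seed=11,
        mortality_coefs=MortalityCoefs(
            intercept=-6.5, age=0.07, female=-0.3, cluster=(0.0, 0.3, -0.2)
        ),
        lost_rate=0.03,
        acute_rate_per_period=4.0,
        dispensation_rate=6.0,
    )
    return mp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_wave(planted_cohort):
    patients = mp.apply_multimorbidity_filter(planted_cohort.patients)
    return mp.build_wave(patients, "2011"), patients


@pytest.fixture(scope="session")
def planted_clustering(planted_wave):
    wave, _ = planted_wave
    return mp.kmeans_jaccard(
        wave.matrix, 3, seed=5, wave_label="2011", included_ids=wave.included_ids
    )


def truth_for(cohort, ids):
    truth = {
        p.patient_id: int(t) for p, t in zip(cohort.patients, cohort.truth_labels)
    }
    return np.array([truth[i] for i in ids])
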