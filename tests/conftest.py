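import numpy as np
import pytest

from pkdiss import synthetic as syn
from pkdiss.datatypes import ConcentrationTimeProfile, DissolutionProfile


@pytest.fixture(scope="session")
def noise_free_truth() -> syn.PKTruth:
    return syn.rabbit_cipro_pk_truth(between_subject_cv=0.0, residual_cv=0.0)


@pytest.fixture(scope="session")
def noise_free_profile(noise_free_truth) -> ConcentrationTimeProfile:
    """One subject on the standard sampling grid, no noise, no censoring."""
    design = syn.rabbit_cipro_design(seed=0, n_subjects=1)
    return syn.simulate_study(noise_free_truth, design, product_id="F")[0]


@pytest.fixture()
def simple_dissolution_pair() -> tuple[DissolutionProfile, DissolutionProfile]:
    times = [5.0, 10.0, 15.0, 30.0, 45.0]
    ref = DissolutionProfile("ref", times, [40.0, 60.0, 75.0, 85.0, 92.0])
    test = DissolutionProfile("test", times, [31.0, 51.0, 66.0, 76.0, 83.0])
    return ref, test


def profile_from_arrays(times, concs, dose=500.0, subject="s1", **kw):
    return ConcentrationTimeProfile(
        subject_id=subject,
        times=np.asarray(times, dtype=float),
        concentrations=np.asarray(concs, dtype=float),
        dose=dose,
        **kw,
    )
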