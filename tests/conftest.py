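import numpy as np
import pytest

import roidecode as rd


@pytest.fixture(scope="session")
def atlas3():
    return rd.Atlas(np.array([1, 2, 3]), ["a", "b", "c"],
                    ["FPN", "DMN", "VIS"])


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects x 60 trials x 3 ROIs with strong couplings."""
    cfg = rd.SyntheticConfig(n_subjects=2, n_trials=60, n_rois=3,
                             coupling_sparsity=1.0, coupling_magnitude=0.6,
                             seed=42)
    return rd.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def decoded_small(small_cohort, atlas3):
    """Decoded 2x3 cohort, both targets, small permutation count."""
    cohort, truth = small_cohort
    spec = rd.SplitSpec(n_train=25, n_test=25, n_repeats=10)
    results = rd.decode_all(cohort, atlas3, spec, n_perm=60, master_seed=7)
    return cohort, truth, results
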