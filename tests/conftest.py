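import numpy as np
import pandas as pd
import pytest

import passclock as pc

# A deliberately small study design used by most unit tests: same
# structure as the full default (train + test cohorts, drifting CpGs on
# a bimodal background) at a fraction of the probe count.
SMALL = dict(n_probes=400, n_hypo=6, n_hyper=5, n_extra_drifters=5, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """(beta, sheet, truth) for the scaled-down default design."""
    return pc.generate_cohort(pc.default_config(**SMALL))


@pytest.fixture(scope="session")
def small_clock(small_cohort):
    """A clock trained on the small cohort's training samples, plus the
    screened probe list used to fit it."""
    beta, sheet, truth = small_cohort
    train = [s for s in beta.sample_ids if s.startswith("train")]
    beta_tr = beta.select_samples(train)
    dmps = pc.screen_dmps(beta_tr, sheet, pc.ScreenConfig(threshold=1e-11))
    probes = [r.probe_id for r in dmps]
    model = pc.fit_clock(beta_tr.select_probes(probes), sheet,
                         cv=pc.CvSpec(seed=3))
    return model, probes


@pytest.fixture
def toy_beta():
    """Hand-written 3-probe x 2-sample matrix."""
    return pc.BetaMatrix(("cgA", "cgB", "cgC"), ("S1", "S2"),
                         np.array([[0.1, 0.2], [0.5, 0.6], [0.9, 1.0]]))


@pytest.fixture
def toy_sheet():
    return pc.SampleSheet(pd.DataFrame({
        "sample_id": ["S1", "S2"],
        "passage": [10, 12],
        "treatment": ["vehicle", "vehicle"],
    }))
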