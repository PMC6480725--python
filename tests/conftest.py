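import numpy as np
import pytest

from ansig.qmatrix import build_qmatrix, expand_item_properties
from ansig.rasch import ResponseMatrix

STUDY_MODELS = tuple(range(3, 14))

#: Published operator easiness coefficients used as generating truth in
#: study-like simulations.
TRUE_INTERCEPT = 4.77
TRUE_ETA = {"AOS": 0.35, "PS": -1.53, "CF": -2.13, "NPCP": -2.65, "PCP": -3.76}


@pytest.fixture(scope="session")
def study_qmatrix():
    return build_qmatrix("ansig", STUDY_MODELS)


@pytest.fixture(scope="session")
def study_properties(study_qmatrix):
    """49-item layout: five items per model except 4, 12 (three) and 8 (four)."""
    counts = {m: 5 for m in STUDY_MODELS}
    counts[4], counts[12], counts[8] = 3, 3, 4
    assignments = [(f"m{m:02d}_{j+1}", m) for m in STUDY_MODELS
                   for j in range(counts[m])]
    return expand_item_properties(study_qmatrix, assignments)


def simulate_lltm_responses(properties, n_persons, seed, person_sd=1.09,
                            item_resid_sd=0.0, intercept=TRUE_INTERCEPT,
                            eta=None):
    """Complete-design Bernoulli responses under the operator decomposition."""
    eta_vec = np.array(list((eta or TRUE_ETA).values()))
    rng = np.random.default_rng(seed)
    easi = intercept + properties.covariates @ eta_vec
    if item_resid_sd > 0:
        easi = easi + rng.normal(0.0, item_resid_sd, len(easi))
    theta = rng.normal(0.0, person_sd, n_persons)
    p = 1.0 / (1.0 + np.exp(-(theta[:, None] + easi[None, :])))
    scores = (rng.random(p.shape) < p).astype(float)
    return ResponseMatrix.from_array(scores, item_ids=list(properties.item_ids))


@pytest.fixture(scope="session")
def study_responses(study_properties):
    return simulate_lltm_responses(study_properties, n_persons=600, seed=20260922)
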