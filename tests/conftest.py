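import numpy as np
import pytest
from hypothesis import settings

from annualcoex import CompetitionParams, make_design, simulate_seed_production
from annualcoex.reference import REFERENCE_ESTIMATES, REFERENCE_SE

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

PAIR_ORDER = ["lambda_i", "alpha_ii", "alpha_ij", "lambda_j", "alpha_jj", "alpha_ji"]


@pytest.fixture(scope="session")
def dry_estimates():
    return REFERENCE_ESTIMATES["dry"]


@pytest.fixture(scope="session")
def wet_estimates():
    return REFERENCE_ESTIMATES["wet"]


@pytest.fixture(scope="session")
def dry_params():
    return CompetitionParams(**REFERENCE_ESTIMATES["dry"])


@pytest.fixture(scope="session")
def pair_point_and_cov():
    """(x, diagonal cov) per treatment, in PAIR_ORDER, from reference SEs."""
    out = {}
    for trt in ("dry", "wet"):
        e, s = REFERENCE_ESTIMATES[trt], REFERENCE_SE[trt]
        out[trt] = (
            np.array([e[k] for k in PAIR_ORDER]),
            np.diag(np.array([s[k] for k in PAIR_ORDER]) ** 2),
        )
    return out


@pytest.fixture(scope="session")
def dry_table(dry_params):
    """One simulated experiment (dry treatment only) at the default design."""
    design = make_design(treatments=("dry",))
    return simulate_seed_production(design, dry_params, rng_seed=20_260_922)


@pytest.fixture(scope="session")
def small_table(dry_params):
    """A small (~32-pot) single-treatment dataset for oracle comparisons."""
    design = make_design({0: 4, 4: 2, 10: 2, 20: 2}, treatments=("dry",))
    return simulate_seed_production(design, dry_params, rng_seed=11)
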