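"""Shared fixtures: a small synthetic cohort grid and a trained toy model.

The fixture grid uses reduced geometry (72x72 slices, 8 per patient, 3
patients per cell) so the whole suite stays fast; tests of full-scale
conventions (144x144 defaults, manifest arithmetic) build their own inputs.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from segaudit.calibration import fit_platt, validation_logit_sample
from segaudit.synth import SynthConfig, ToyPredictorParams, generate_cohorts, train_toy_predictor

from segaudit.synth import DEFAULT_GBM_SITES, DEFAULT_LGG_SITES

# one site per grade so site groups hold >1 patient in the site tests
SMALL_CONFIG = SynthConfig(
    patients={
        "train": {"GBM": 3, "LGG": 3},
        "validation": {"GBM": 3, "LGG": 3},
        "test": {"GBM": 3, "LGG": 3},
    },
    n_slices=8,
    shape=(72, 72),
    gbm_sites=(DEFAULT_GBM_SITES[0],),
    lgg_sites=(DEFAULT_LGG_SITES[0],),
)


@pytest.fixture(scope="session")
def cohorts():
    return generate_cohorts(SMALL_CONFIG, seed=11)


@pytest.fixture(scope="session")
def predictor(cohorts):
    return train_toy_predictor(cohorts["train"]["ALL"], ToyPredictorParams(seed=0))


@pytest.fixture(scope="session")
def platt(cohorts, predictor):
    z, y = validation_logit_sample(cohorts["validation"]["ALL"], predictor, seed=0)
    return fit_platt(z, y, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_audit(tmp_path_factory):
    """One full nine-condition audit at fixture scale, shared across tests."""
    from segaudit.report import AuditConfig, run_audit

    out = tmp_path_factory.mktemp("audit")
    config = AuditConfig(synth=SMALL_CONFIG, seed=11, out_dir=str(out), make_plots=False)
    return config, run_audit(config)
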