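"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mitokit.gene_order import SignedGeneOrder
from mitokit.synthetic_data import (
    build_ground_record,
    default_config,
    make_study_fixture,
)

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def study_fixture():
    """The default study-like synthetic fixture (45 records + manifest + tree)."""
    return make_study_fixture(default_config(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def defect_fixture():
    """Same design with annotation defects planted in four records."""
    return make_study_fixture(default_config(seed=FIXTURE_SEED, with_defects=True))


@pytest.fixture()
def ground_record():
    cfg = default_config(seed=11)
    return build_ground_record(cfg, "Testa synthetica", group="Caridea",
                               record_id="SYNGR01.1",
                               rng=np.random.default_rng(11))
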