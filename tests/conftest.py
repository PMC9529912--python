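from __future__ import annotations

import numpy as np
import pytest

from phenoclust.data import read_dataset
from phenoclust.simulate import default_config, generate, make_fixtures


@pytest.fixture(scope="session")
def fixture_files(tmp_path_factory):
    """Fixed-seed fixture cohorts written once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(out)


@pytest.fixture(scope="session")
def dataset1_like(fixture_files):
    """286 animals, 10 cohorts, 4 cohorts missing weight/open-field/nesting."""
    return read_dataset(fixture_files["dataset1_like"], fixture_files["battery"])


@pytest.fixture(scope="session")
def dataset2_like(fixture_files):
    return read_dataset(fixture_files["dataset2_like"], fixture_files["battery"])


@pytest.fixture(scope="session")
def dataset3_like(fixture_files):
    """Three-arm treatment cohort (34/25/32, 50% rescue)."""
    return read_dataset(fixture_files["dataset3_like"], fixture_files["battery"])


@pytest.fixture(scope="session")
def null_females(fixture_files):
    return read_dataset(fixture_files["null_females"], fixture_files["battery"])


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort (85 per genotype, single cohort)."""
    ds, truth = generate(default_config(), seed=11)
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
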