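"""Shared fixtures: the planted six-family dataset and its pipeline run.

Both are session-scoped because the all-vs-all alignment step dominates
runtime; every test that needs the planted conditions reuses the same
deterministic dataset (master seed 7).
"""

import pytest

from lhr.pipeline import run_pipeline
from lhr.synthetic import (ArchitectureSpec, SynthParams,
                           generate_family_dataset)


@pytest.fixture(scope="session")
def planted_params():
    return SynthParams()   # six families, sizes 20/12/8/4/3/2, seed 7


@pytest.fixture(scope="session")
def planted_dataset(planted_params):
    return generate_family_dataset(planted_params)


@pytest.fixture(scope="session")
def pipeline_result(planted_dataset):
    return run_pipeline(planted_dataset)


@pytest.fixture(scope="session")
def two_family_dataset():
    """Small two-family dataset for fast graph-level tests."""
    params = SynthParams(
        n_families=2, family_sizes=(4, 4),
        within_identity=0.85, between_identity=0.25,
        architectures=(
            ArchitectureSpec("aLhr2", "intact", taxon="Archaea"),
            ArchitectureSpec("bLhr", "intact", taxon="Bacteria"),
        ),
        n_species=4, seed=11)
    return generate_family_dataset(params)
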