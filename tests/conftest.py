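"""Shared fixtures: synthetic bundles at two scales.

``small_bundle`` is a quick two-chromosome dataset for unit-level
cross-module checks; ``default_run`` is the full default-scale
simulate-and-validate round trip shared by the end-to-end tests.
"""

import pytest

from hspscan.pipeline import simulate_and_validate
from hspscan.synthetic_data import SyntheticConfig, generate_dataset


SMALL_CONFIG = dict(n_chromosomes=2, chromosome_length=300_000,
                    n_family_genes=20, n_decoy_genes=46,
                    tandem_array_sizes=[2, 5], seed=1)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_bundle")
    return generate_dataset(SyntheticConfig(**SMALL_CONFIG), outdir)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full-scale simulate -> pipeline -> truth comparison (default
    study conditions: 6 chromosomes x 1 Mb, 60 family genes, 140 decoys,
    domain divergence 0.2)."""
    workdir = tmp_path_factory.mktemp("default_run")
    summary, pipe = simulate_and_validate(SyntheticConfig(seed=1), workdir)
    return summary, pipe, workdir
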