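import numpy as np
import pytest

from neo3d import mapping, synthetic


@pytest.fixture(scope="session")
def world():
    """A small but complete synthetic study world shared across tests."""
    return synthetic.build_world(n_peptides=200, n_genes=120, seed=7)


@pytest.fixture(scope="session")
def bundle_dir(world, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = synthetic.write_bundle(world, outdir)
    return paths


@pytest.fixture(scope="session")
def annotation(bundle_dir):
    return mapping.load_annotation(bundle_dir["proteins_fasta"], bundle_dir["genes_bed"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
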