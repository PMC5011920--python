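import pytest

from histokit import classify
from histokit.synthetic_data import SimulationConfig, generate_genome


@pytest.fixture(scope="session")
def refs():
    return classify.load_references()


@pytest.fixture(scope="session")
def dataset19():
    """Synthetic 19-gene complement mirroring the tabulated feature flags."""
    return generate_genome(SimulationConfig(seed=11, cluster_copies=2))


@pytest.fixture(scope="session")
def dataset19_dir(dataset19, tmp_path_factory):
    from histokit.synthetic_data import write_dataset

    out = tmp_path_factory.mktemp("dataset19")
    return write_dataset(dataset19, out, reads=False)
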