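import pytest

from smallrna_crstress.synthetic_data import SimulationSpec, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic study shared by read-level and pipeline tests."""
    spec = SimulationSpec(
        seed=7,
        library_depths={"CK": 30_000, "Cr200": 32_400},
        n_known_mirnas=30,
        n_novel_hairpins=4,
        background_loci=60,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def small_dataset_dir(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    paths = small_dataset.write(out)
    return paths
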