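import pytest

from hybridase.sim import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def mixed_bundle():
    """A small simulated experiment with all four gene classes planted."""
    config = SimConfig(
        seed=11,
        n_genes=40,
        class_proportions={
            "null": 0.55,
            "cis": 0.15,
            "paternal_imprint": 0.15,
            "maternal_imprint": 0.15,
        },
    )
    return simulate_experiment(config)


@pytest.fixture(scope="session")
def disk_bundle(tmp_path_factory):
    """The same kind of experiment written to disk for IO / CLI tests."""
    out = tmp_path_factory.mktemp("bundle")
    config = SimConfig(
        seed=5,
        n_genes=12,
        marker_blocks=[("chr1", 10_000, 15_000)],
    )
    return simulate_experiment(config, out)
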