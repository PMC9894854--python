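import pytest

from salpflux.synthetic import CycleScenario, NoiseConfig, generate_cycle


@pytest.fixture(scope="session")
def noiseless_cycle():
    """Default scenario with all noise off: estimators must recover truth."""
    return generate_cycle(CycleScenario(noise=NoiseConfig.off()), seed=1)


@pytest.fixture(scope="session")
def noisy_cycle():
    """Default scenario with default noise."""
    return generate_cycle(CycleScenario(), seed=1)


@pytest.fixture(scope="session")
def noiseless_tables(noiseless_cycle, tmp_path_factory):
    """Noiseless bundle written to disk as the CSV/YAML/JSON contract."""
    outdir = tmp_path_factory.mktemp("noiseless")
    return noiseless_cycle.write(outdir)
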