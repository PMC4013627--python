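import pytest
from hypothesis import HealthCheck, settings

from nitroquant import NoiseModel, Peptide, SimulatedSpecies, generate_run, table1_fixture

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


def make_pair_species(light_abundance: float) -> list[SimulatedSpecies]:
    """A co-eluting light/heavy Y*LYEIAR pair at the given light:heavy ratio."""
    return [
        SimulatedSpecies(
            "YLYEIAR[light]", Peptide.parse("YLYEIAR 1:nitro_light"),
            2, light_abundance, 1.0, 0.12,
        ),
        SimulatedSpecies(
            "YLYEIAR[heavy]", Peptide.parse("YLYEIAR 1:nitro_heavy"),
            2, 1.0, 1.0, 0.12,
        ),
    ]


@pytest.fixture(scope="session")
def noise_free_quarter_run():
    """0.25:1 light:heavy pair, all noise disabled: ratios are exact."""
    return generate_run(make_pair_species(0.25), noise=NoiseModel.none(), seed=1)


@pytest.fixture(scope="session")
def noisy_quarter_run():
    """0.25:1 pair under the default noise model."""
    return generate_run(make_pair_species(0.25), seed=7)


@pytest.fixture(scope="session")
def adversarial_run():
    """0.25:1 pair with near-reporter decoy peaks 0.01-0.05 Da off-target."""
    noise = NoiseModel(adversarial_decoys=True)
    return generate_run(make_pair_species(0.25), noise=noise, seed=5)


@pytest.fixture(scope="session")
def table1_runs():
    """The five-run mixing-design fixture (1:1 ref, 3x 0.25:1, 1x 0.10:1)."""
    return table1_fixture(seed=7)
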