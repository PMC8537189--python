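import warnings

import pytest
from hypothesis import HealthCheck, settings

from leafdepo import GeneratorConfig, simulate_study
from leafdepo.reference import (
    efficiency_wide,
    load_species,
    load_wettability,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_wettability():
    return load_wettability().set_index("species_id")


@pytest.fixture(scope="session")
def ref_species():
    return load_species().set_index("species_id")


@pytest.fixture(scope="session")
def ref_efficiency():
    """Reference efficiency per scale: dict scale -> species x fraction table."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # known PhSu/PhVi code mismatch
        return {scale: efficiency_wide(scale) for scale in ("leaf", "plant", "land")}


@pytest.fixture(scope="session")
def noisefree_config():
    return GeneratorConfig(weighing_sd_mg=0.0, ca_sd_deg=0.0, tds_rel_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_study(noisefree_config):
    return simulate_study(noisefree_config, seed=7)


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(GeneratorConfig(), seed=7)


@pytest.fixture()
def study_dir(tmp_path, noisefree_study):
    """A small noise-free study written to disk."""
    from leafdepo import write_study

    _, bundle = noisefree_study
    d = tmp_path / "study"
    write_study(bundle, d)
    return d
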