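import pytest
from hypothesis import HealthCheck, settings

from affinikit import reference as ref
from affinikit.kinetics import SensorgramKineticFitter
from affinikit.models import OneToOneParams
from affinikit.synth import GeneratorConfig, gen_sensorgrams

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol():
    return ref.DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def global_params():
    """Published global bivalent-analyte parameter set."""
    return ref.GLOBAL_FIT_PARAMS


@pytest.fixture(scope="session")
def local_params():
    """Published local (7.1 uM) bivalent-analyte parameter set."""
    return ref.LOCAL_FIT_PARAMS


@pytest.fixture(scope="session")
def kinetic_concs():
    return ref.KINETIC_CONCENTRATIONS_M


@pytest.fixture(scope="session")
def noise_free_sensorgrams(global_params, kinetic_concs, protocol):
    """Noise-free bivalent injection series over the twofold design."""
    return gen_sensorgrams(global_params, kinetic_concs, protocol,
                           GeneratorConfig(seed=0, noise_sd_ru=0.0))


@pytest.fixture(scope="session")
def noise_free_global_fit(noise_free_sensorgrams, global_params):
    fitter = SensorgramKineticFitter(model="bivalent", scope="global",
                                     analyte_mw=global_params.analyte_mw)
    fitter.fit(noise_free_sensorgrams)
    return fitter.result_


@pytest.fixture(scope="session")
def one_to_one_params(global_params):
    """1:1 model with the published first-site rates."""
    return OneToOneParams(k_on=global_params.k_on1,
                          k_off=global_params.k_off1,
                          R_max=global_params.R_max, RI=5.0)


@pytest.fixture(scope="session")
def one_to_one_sensorgrams(one_to_one_params, kinetic_concs, protocol):
    return gen_sensorgrams(one_to_one_params, kinetic_concs, protocol,
                           GeneratorConfig(seed=0, noise_sd_ru=0.0))
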