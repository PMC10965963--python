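import numpy as np
import pytest

from xylflux import load_packaged_measurement_spec
from xylflux.core_network import (load_packaged_fluxes, load_packaged_network,
                                  parse_network)
from xylflux.flux_fit import (FreeFluxParam, biomass_drain_fluxes,
                              project_to_steady_state)
from xylflux.isotope_forward import TracerSpec
from xylflux.synthetic_data import DEFAULT_TRACER

MEASURED_RATES = {"uptake": 1.45, "growth": 0.08}


@pytest.fixture(scope="session")
def net():
    return load_packaged_network()


@pytest.fixture(scope="session")
def fixture_flux():
    return load_packaged_fluxes()


@pytest.fixture(scope="session")
def spec():
    return load_packaged_measurement_spec()


@pytest.fixture(scope="session")
def tracer():
    """The study's tracer: 100% [1,2-13C]xylose, 99% purity."""
    return DEFAULT_TRACER


@pytest.fixture(scope="session")
def tracer_pure():
    return TracerSpec("XYL.ext", (((1, 2), 1.0),), purity=1.0)


@pytest.fixture(scope="session")
def measured_rates():
    return dict(MEASURED_RATES)


@pytest.fixture(scope="session")
def pfp(net):
    fixed = biomass_drain_fluxes(MEASURED_RATES["growth"],
                                 MEASURED_RATES["uptake"])
    fixed["upt"] = 100.0
    return FreeFluxParam(net, fixed, ["pgi", "ppc", "maeB", "pyc", "fbp"])


@pytest.fixture(scope="session")
def truth(pfp, fixture_flux):
    """The packaged flux fixture, re-balanced to exact steady state."""
    return project_to_steady_state(pfp, fixture_flux)


@pytest.fixture(scope="session")
def toy_nets():
    return {name: load_packaged_network(f"toy_{name}.net")
            for name in ("linear", "condense", "ppp")}


@pytest.fixture(scope="session")
def noise_free_dataset(net, truth, tracer, spec):
    from xylflux.synthetic_data import MidNoiseModel, generate_mid_dataset

    ds, _ = generate_mid_dataset(net, truth, tracer, spec, MidNoiseModel(sd=0.0))
    return ds


@pytest.fixture(scope="session")
def recovery_fit(net, noise_free_dataset, tracer, spec, measured_rates):
    """The 50-start noise-free recovery fit (shared across tests)."""
    from xylflux.flux_fit import fit_fluxes

    return fit_fluxes(net, noise_free_dataset, tracer, spec,
                      measured_rates=measured_rates, n_starts=50, seed=1)


EDEMP_CENTER = (89.0, 12.0, 10.0, 1.0, 2.0)  # pgi, ppc, maeB, pyc, fbp


def sample_edemp_fluxes(pfp, rng, min_flux=0.1, exchange_box=(0.5, 8.0)):
    """Strictly positive steady-state draw near the reference flux state
    (the box acceptance region of this network is too thin for naive
    rejection sampling)."""
    from xylflux.flux_fit import sample_steady_state_fluxes

    return sample_steady_state_fluxes(
        pfp, rng, min_flux=min_flux, center=EDEMP_CENTER, spread=0.3,
        exchange_box=exchange_box)


def sample_toy_fluxes(toy_net, rng, with_exchange=True):
    """Random strictly-positive steady-state flux draw for a toy network."""
    fixed = {toy_net.uptake_reaction_id: 100.0}
    p = FreeFluxParam(toy_net, fixed)
    from xylflux.flux_fit import sample_steady_state_fluxes

    return sample_steady_state_fluxes(
        p, rng, box=(1.0, 80.0), min_flux=1.0,
        exchange_box=(0.0, 10.0) if with_exchange else None)
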