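"""xylflux: 13C metabolic flux analysis, genome-scale FBA, and growth
kinetics for engineered *Pseudomonas putida* assimilating D-xylose through
the exogenous isomerase pathway and the EDEMP cycle."""

from . import (core_network, flux_fit, gem_fba, growth_kinetics,
               isotope_forward, mid_processing, synthetic_data)
from .core_network import (AtomMappedNetwork, FluxDistribution,
                           load_packaged_fluxes, load_packaged_network,
                           parse_network, validate_steady_state)
from .isotope_forward import (MeasurementSpec, MidDataset, TracerSpec,
                              brute_force_mids, simulate_mids)

__version__ = "0.1.0"


def load_packaged_measurement_spec() -> MeasurementSpec:
    """The packaged fragment list: TBDMS amino-acid fragments plus intact
    IC-MS sugar phosphates."""
    from importlib.resources import files

    return MeasurementSpec.from_json(
        files("xylflux.data").joinpath("measurement_spec.json").read_text())
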