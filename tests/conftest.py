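import numpy as np
import pytest

from lipofrac.analytes import VolumetricConstants
from lipofrac.simulate import (
    NoiseModel,
    allocate_species,
    build_species,
    default_species_library,
    draw_serum_totals,
    simulate_sample_profile,
)

LDL_LIPIDS = {"FC": 0.19, "CE": 0.50, "TG": 0.05, "PC": 0.17, "SM": 0.06,
              "PE": 0.01, "PI": 0.005, "LPC": 0.005}
HDL_LIPIDS = {"FC": 0.09, "CE": 0.25, "TG": 0.03, "PC": 0.41, "SM": 0.08,
              "PE": 0.03, "PI": 0.01, "LPC": 0.10}


@pytest.fixture(scope="session")
def constants():
    return VolumetricConstants()


@pytest.fixture(scope="session")
def ldl_species(constants):
    """A single LDL species carrying exactly one apoB-100."""
    return build_species(
        "ldl_test", 22.0, {"B-100": 1}, LDL_LIPIDS, constants,
        broadening_sigma_nm=0.0,
    )


@pytest.fixture(scope="session")
def hdl_species(constants):
    return build_species(
        "hdl_test", 10.0, {"A-I": 3, "A-II": 2}, HDL_LIPIDS, constants,
        broadening_sigma_nm=0.0,
    )


@pytest.fixture(scope="session")
def nl_sample_noiseless(constants):
    """One noise-free (but lossy) NL-like sample from the default library."""
    rng = np.random.default_rng(11)
    totals = draw_serum_totals("NL", rng, constants)
    library = default_species_library(constants, serum_totals=totals)
    species = allocate_species(totals, library)
    return simulate_sample_profile(
        species, noise=NoiseModel.noiseless(), rng=rng, sample_id="NL-noiseless"
    )
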