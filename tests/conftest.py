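import pytest

from snarefusion import (
    EncounterParams,
    Medium,
    VesicleGeometry,
    VesiclePopulation,
    vesicle_number_density,
)


@pytest.fixture
def medium() -> Medium:
    return Medium()


@pytest.fixture
def suv_geometry() -> VesicleGeometry:
    return VesicleGeometry()


@pytest.fixture
def encounter_params() -> EncounterParams:
    return EncounterParams()


@pytest.fixture
def standard_populations(suv_geometry):
    """tSUV / vSUV populations of the standard 1 mM, 9:1 lipid-mixing assay.

    SNARE densities are the standard one v-SNARE per 100 lipids and one
    t-SNARE per 200 lipids.
    """
    from snarefusion import lipids_per_vesicle

    n_lipids = lipids_per_vesicle(suv_geometry)
    rho_t = vesicle_number_density(1e-3, 0.9, suv_geometry)
    rho_v = vesicle_number_density(1e-3, 0.1, suv_geometry)
    tpop = VesiclePopulation(
        geometry=suv_geometry,
        number_density=rho_t,
        snare_copies_per_vesicle=n_lipids / 200,
    )
    vpop = VesiclePopulation(
        geometry=suv_geometry,
        number_density=rho_v,
        snare_copies_per_vesicle=n_lipids / 100,
    )
    return vpop, tpop
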