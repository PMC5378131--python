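import pytest

from afca import ModelParams
from afca.geometry import (build_icosphere, build_neighbour_map,
                           build_substrate, mark_functional_regions)


@pytest.fixture(scope="session")
def baseline_params():
    return ModelParams()


@pytest.fixture(scope="session")
def mesh5(baseline_params):
    """Carved, mapped and marked level-5 substrate (no fibrosis).

    Tests that sample fibrosis on it must resample (sample_fibrosis clears
    previous labels), so sharing the mesh across tests is safe.
    """
    return build_substrate(baseline_params, level=5)


@pytest.fixture(scope="session")
def small_params():
    """Level-3 analogue: the internode spacing is 4x the level-5 one, so all
    interaction radii are scaled by 4 to preserve the ~36-node neighbourhood
    and the 8-neighbour excitation rule."""
    return ModelParams(fc=30, interaction_radius_mm=2.544 * 4,
                       sn_radius_mm=1.696 * 4, burst_group_radius_mm=2.12 * 4,
                       annulus_width_mm=8.0)


@pytest.fixture(scope="session")
def small_mesh(small_params):
    return build_substrate(small_params, level=3)


@pytest.fixture(scope="session")
def sphere5(baseline_params):
    """Uncarved (defect-free) level-5 sphere with neighbour map and regions."""
    mesh = build_icosphere(5)
    build_neighbour_map(mesh, baseline_params.interaction_radius_mm)
    mark_functional_regions(mesh, baseline_params)
    return mesh
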