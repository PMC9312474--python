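import numpy as np
import pandas as pd
import pytest

from transect_varpart.core import StudyDesign, build_community_matrix
from transect_varpart.simulate import SimulationConfig, simulate_study


SMALL_DESIGN = StudyDesign(
    n_islands=2, locations_per_island=2, transects_per_location=2,
    n_observers=3, repeats_per_observer=3,
)


@pytest.fixture(scope="session")
def small_design():
    return SMALL_DESIGN


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated study (72 observations, 8 species)."""
    config = SimulationConfig(design=SMALL_DESIGN, n_species=8, seed=42)
    return simulate_study(config)


@pytest.fixture(scope="session")
def small_matrix(small_study):
    records, _ = small_study
    return build_community_matrix(records, "MaxCount", window=(0.0, 50.0))


@pytest.fixture(scope="session")
def full_study():
    """A full-size study under the default design (540 observations)."""
    config = SimulationConfig(seed=7, n_species=20)
    return simulate_study(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def full_design_labels(design: StudyDesign) -> pd.DataFrame:
    """Balanced factor-label frame for a design, without simulating counts."""
    rows = []
    for isl in range(design.n_islands):
        for loc in range(design.locations_per_island):
            for tr in range(design.transects_per_location):
                for ob in range(design.n_observers):
                    for rep in range(design.repeats_per_observer):
                        rows.append((f"i{isl}", f"l{isl}.{loc}", f"t{isl}.{loc}.{tr}",
                                     f"o{ob}"))
    return pd.DataFrame(rows, columns=["island", "location", "transect", "observer"])
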