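import numpy as np
import pytest

from paleoniche.grids import HINDCAST_LAYERS
from paleoniche.points import build_background_region, simulate_background, simulate_occurrences
from paleoniche.prep import fit_pca
from paleoniche.synthio import (
    ClimateConfig,
    generate_climate_series,
    generate_morpho_table,
    generate_regions,
)


@pytest.fixture(scope="session")
def small_climate_config():
    """Desk-scale grid for fast pipeline tests (the full default is
    exercised in the acceptance tests)."""
    return ClimateConfig(fine_shape=(80, 80), coarse_factor=8, n_bins=60)


@pytest.fixture(scope="session")
def climate_series(small_climate_config):
    return generate_climate_series(small_climate_config, seed=11)


@pytest.fixture(scope="session")
def regions(small_climate_config):
    from paleoniche.synthio import RegionConfig

    return generate_regions(
        RegionConfig(n_species_polygons=6, min_peak_separation=18),
        small_climate_config,
        seed=11,
    )


@pytest.fixture(scope="session")
def occurrences(regions, climate_series):
    return simulate_occurrences(regions, climate_series.present_fine.grid, n=120, seed=5)


@pytest.fixture(scope="session")
def background(regions, occurrences, climate_series):
    region = build_background_region(regions)
    return simulate_background(
        region, occurrences, climate_series.present_fine.grid, n=800, seed=6
    )


@pytest.fixture(scope="session")
def calibration_scores(climate_series, occurrences, background):
    """(presence PC scores, background PC scores, PCA transform)."""
    hind = climate_series.present_fine.subset(list(HINDCAST_LAYERS))
    pca = fit_pca(hind)

    def at(idx):
        X = np.column_stack(
            [hind[n].values[idx[:, 0], idx[:, 1]] for n in HINDCAST_LAYERS]
        )
        return pca.transform_matrix(X)

    return at(occurrences.cell_index), at(background.cell_index), pca


@pytest.fixture(scope="session")
def morpho_table():
    return generate_morpho_table(seed=5)
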