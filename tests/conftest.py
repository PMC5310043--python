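"""Shared fixtures: hand-checkable rate tables and a reusable synthetic panel."""

import numpy as np
import pandas as pd
import pytest

from reefcarb.census import EndolithicRates, RateTables, load_default_rates
from reefcarb.simulate import GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def default_rates():
    return load_default_rates()


@pytest.fixture(scope="session")
def oracle_rates():
    """Minimal rate tables whose outputs are single hand-computable products."""
    coral = pd.DataFrame([
        {"genus": "Acropora", "morphology": "branching",
         "growth_mean_cm_yr": 1.0, "growth_lo95_cm_yr": 0.8,
         "growth_hi95_cm_yr": 1.2, "density_g_cm3": 1.5,
         "geometry_multiplier": 1.0},
        {"genus": "OtherCoral", "morphology": "other",
         "growth_mean_cm_yr": 0.5, "growth_lo95_cm_yr": 0.4,
         "growth_hi95_cm_yr": 0.6, "density_g_cm3": 1.6,
         "geometry_multiplier": 1.0},
    ])
    parrotfish = pd.DataFrame([
        {"species_or_group": "excavator", "size_min_cm": 10.0,
         "size_max_cm": 60.0, "bite_rate_h": 120.0, "feeding_hours": 8.0,
         "scar_fraction": 0.1, "scar_volume_cm3": 0.5,
         "substrate_density_g_cm3": 1.5},
        {"species_or_group": "scraper", "size_min_cm": 10.0,
         "size_max_cm": 60.0, "bite_rate_h": 100.0, "feeding_hours": 8.0,
         "scar_fraction": 0.05, "scar_volume_cm3": 0.1,
         "substrate_density_g_cm3": 1.5},
    ])
    length_weight = pd.DataFrame([
        {"species": "Chlorurus sordidus", "a": 0.015, "b": 3.04,
         "group": "excavator"},
        {"species": "Scarus ghobban", "a": 0.014, "b": 3.02,
         "group": "scraper"},
        {"species": "Leptoscarus vaigiensis", "a": 0.012, "b": 3.05,
         "group": "browser"},
    ])
    urchin = pd.DataFrame([
        {"species": "Echinometra mathaei", "test_min_cm": 0.0,
         "test_max_cm": 20.0, "erosion_kg_ind_yr": 0.5},
    ])
    return RateTables(coral=coral, parrotfish=parrotfish,
                      length_weight=length_weight, urchin=urchin,
                      endolithic=EndolithicRates())


@pytest.fixture(scope="session")
def panel_bundle():
    """One default-condition synthetic panel shared across read-only tests."""
    return generate_panel(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
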