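"""Shared fixtures: small synthetic landscapes, populations and genotypes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from raydisp import synthetic as syn


@pytest.fixture(scope="session")
def grid_boxes() -> pd.DataFrame:
    cfg = syn.LandscapeConfig("continuous_grid", 100, 30.0, site="Grid", seed=7)
    return syn.generate_landscape(cfg)


@pytest.fixture(scope="session")
def small_population(grid_boxes):
    params = syn.PopulationParams(
        years=6,
        occupancy_rate=0.25,
        adult_survival=0.6,
        recapture_prob=1.0,
        natal_kernel_by_sex={"F": syn.Kernel("exponential", 120.0),
                             "M": syn.Kernel("exponential", 120.0)},
        breeding_kernel_by_sex={"F": syn.Kernel("exponential", 20.0),
                                "M": syn.Kernel("exponential", 20.0)},
        clutch_mean=4.0,
        first_year_survival=0.3,
        seed=11,
    )
    pedigree, captures = syn.simulate_population(grid_boxes, params)
    return {"boxes": grid_boxes, "pedigree": pedigree, "captures": captures,
            "params": params}


@pytest.fixture(scope="session")
def allele_freqs():
    return syn.random_allele_frequencies(n_loci=13, seed=3)


@pytest.fixture(scope="session")
def unrelated_genotypes(allele_freqs):
    """50 unrelated (founder) individuals at random coordinates."""
    n = 50
    ped = pd.DataFrame({
        "individual_id": [f"u{k:03d}" for k in range(n)],
        "sex": ["F", "M"] * (n // 2),
        "birth_year": [None] * n,
        "natal_box": [None] * n,
        "mother_id": [None] * n,
        "father_id": [None] * n,
    })
    table = syn.simulate_genotypes(ped, allele_freqs, seed=21)
    rng = np.random.default_rng(22)
    coords = pd.DataFrame({
        "individual_id": table["individual_id"],
        "sex": ped["sex"],
        "x_m": rng.uniform(0, 600, n),
        "y_m": rng.uniform(0, 600, n),
    })
    return table, coords
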