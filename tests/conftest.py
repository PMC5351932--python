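import numpy as np
import pandas as pd
import pytest

from brainmeth.simulate import (
    EffectSpec,
    make_design,
    make_manifest,
    simulate_beta,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_manifest():
    return make_manifest(200, n_chroms=2, mean_gap_bp=300, seed=11)


@pytest.fixture(scope="session")
def small_design():
    return make_design(n_donors=30, seed=11)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact full study bundle shared across read-only tests."""
    return simulate_dataset(n_probes=1500, n_donors=40, n_snps=60, seed=17)


@pytest.fixture(scope="session")
def single_region_null():
    """Null (no effects) one-region dataset: 500 probes x 60 samples."""
    manifest = make_manifest(500, n_chroms=2, mean_gap_bp=400, seed=23)
    sheet = make_design(
        n_donors=60,
        case_fraction=0.5,
        regions=("PFC",),
        region_availability={"PFC": 1.0},
        restricted_regions={},
        seed=23,
    )
    beta, truth = simulate_beta(manifest, sheet, EffectSpec(), seed=24)
    return manifest, sheet, beta, truth
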