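"""Shared fixtures: synthetic datasets are generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import leafsrc as ls


@pytest.fixture(scope="session")
def benchmark():
    """The standard desk-scale benchmark: 4 families x 3 species x 20
    samples, 5% noise, seed 7 (generation takes ~10 s, shared)."""
    return ls.sample_dataset(ls.default_benchmark())


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny 2-family, 2-species, 5-sample dataset plus 25 extra test points
    per species for reduction/identity checks."""
    spec = ls.SynthSpec(
        n_families=2, species_per_family=2, samples_per_species=5, seed=11
    )
    return ls.sample_dataset(spec, test_per_species=25)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
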