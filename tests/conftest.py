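"""Shared fixtures: the published-count dataset and small synthetic bundles."""

from __future__ import annotations

import numpy as np
import pytest

from symassem.io import CloneLibrary, SequenceVariant
from symassem.screening import screen_variants
from symassem.simulate import SimConfig, simulate_bundle, published_dataset


@pytest.fixture(scope="session")
def published_bundle():
    return published_dataset()


@pytest.fixture(scope="session")
def published_screen(published_bundle):
    return screen_variants(published_bundle.libraries, published_bundle.variants)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact 2-site simulation with genotypes and environment attached."""
    config = SimConfig(seed=7, n_colonies=3, with_genotypes=True, with_env=True)
    bundle, truth = simulate_bundle(config)
    return bundle, truth


def make_library(sample_id: str, counts: dict[str, int], **kw) -> CloneLibrary:
    defaults = dict(
        colony_id=kw.pop("colony_id", sample_id.split("-")[0]),
        site=kw.pop("site", "BTN"),
        year=kw.pop("year", 2007),
        life_stage=kw.pop("life_stage", "adult"),
        morphology=kw.pop("morphology", "branching"),
    )
    return CloneLibrary(sample_id=sample_id, counts=counts, **defaults, **kw)


def make_variant(label: str, sequence: str, **kw) -> SequenceVariant:
    return SequenceVariant(label=label, clade=label[0], sequence=sequence, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
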