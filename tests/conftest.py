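"""Shared fixtures: small simulated studies and a toy classification dataset."""

from __future__ import annotations

import numpy as np
import pytest

from floralecho import synthdata
from floralecho.config import SimConfig
from floralecho.echonet import EchoRenderer, build_chunks, split_by_flower


@pytest.fixture(scope="session")
def truth():
    return synthdata.GroundTruthAcoustics()


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced angle grid for fast scan simulation in tests."""
    return SimConfig(seed=42, n_angles=15)


def make_separable_species(scales=(0.5, 1.2, 2.8), cv=0.03, syndromes=None):
    """Species templates with very different sizes (hence notch spacings)."""
    templates = []
    for i, scale in enumerate(scales):
        means = {k: v * scale for k, v in synthdata._BASE_MEANS.items()}
        syn = syndromes[i] if syndromes else "bat"
        templates.append(
            synthdata.SpeciesTemplate(f"Sp{chr(65 + i)}", f"Fam{i}", syn, means,
                                      cv if np.isscalar(cv) else cv[i])
        )
    return templates


@pytest.fixture(scope="session")
def toy_dataset(small_cfg, truth):
    """3 well-separated species, 6 flowers each, two-plane scans + renderer."""
    templates = make_separable_species()
    flowers = synthdata.sample_flowers(templates, 6, 7)
    scans = {
        f.flower_id: synthdata.simulate_flower_scans(f, truth, small_cfg)
        for f in flowers
    }
    species_by_flower = {f.flower_id: f.species_id for f in flowers}
    by_species: dict = {}
    for f in flowers:
        by_species.setdefault(f.species_id, []).append(f.flower_id)
    split = split_by_flower(by_species, counts=(4, 1, 1), seed=3)
    call = synthdata.synthesize_call()
    renderer = EchoRenderer(scans, call, small_cfg.sample_rate, echo_len=1280)
    return {
        "flowers": flowers,
        "scans": scans,
        "species_by_flower": species_by_flower,
        "by_species": by_species,
        "split": split,
        "renderer": renderer,
        "class_order": sorted(by_species),
        "cfg": small_cfg,
    }


def chunks_for(ds, part: str, k: int, scheme: str, seed_offset: int = 0):
    seeds = {"train": 10, "val": 11, "test": 12}
    return build_chunks(
        ds["scans"], ds["species_by_flower"], ds["split"].ids(part), k, scheme,
        seeds[part] + seed_offset,
    )
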