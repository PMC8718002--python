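"""Replicated simulation experiments behind the headline quantities.

These drivers re-run the full generator + measurement chain many times and
reduce the results to the study's summary numbers: the TS-vs-area regression
coefficients recovered from simulated scans, and the per-syndrome group means
of the morphological coefficient of variation.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from . import morpho, pipeline, sonar, stats, synthdata


def _spawn_seeds(base_seed: int, n: int) -> np.ndarray:
    """Independent 31-bit child seeds derived from one base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def replicated_regression(
    base_seed: int,
    n_replicates: int = 200,
    n_per_species: int = 14,
) -> Dict[str, np.ndarray]:
    """Fit the broadband TS ~ ln(area) regression on replicate studies.

    Each replicate generates a fresh 12-species catalog, samples
    ``n_per_species`` flowers per species, simulates their two-plane scans,
    runs the echo-processing chain to broadband overall TS and fits the OLS
    regression on the resulting 168 flowers.
    """
    seeds = _spawn_seeds(base_seed, n_replicates)
    slopes = np.empty(n_replicates)
    intercepts = np.empty(n_replicates)
    r2 = np.empty(n_replicates)
    for i, seed in enumerate(seeds):
        table = pipeline.simulated_band_ts_table(
            seed=int(seed), n_per_species=n_per_species, bands=(sonar.BROADBAND,)
        )
        fit = stats.fit_ts_regression(table)
        slopes[i], intercepts[i], r2[i] = fit.slope, fit.intercept, fit.r_squared
    return {"slopes": slopes, "intercepts": intercepts, "r_squared": r2}


def replicated_cv_group_means(
    base_seed: int,
    n_seeds: int = 50,
    n_per_species: int = 14,
) -> Dict[str, float]:
    """Syndrome-group means of morphological cV, averaged over seeds.

    For each seed: generate the default catalog, sample flowers, compute the
    per-species per-feature cV table, average across features within species
    and across species within syndrome.
    """
    seeds = _spawn_seeds(base_seed, n_seeds)
    bat = np.empty(n_seeds)
    other = np.empty(n_seeds)
    for i, seed in enumerate(seeds):
        catalog = synthdata.make_catalog(int(seed))
        flowers = synthdata.sample_flowers(catalog, n_per_species, int(seed) + 1)
        cv_tbl = morpho.species_cv_table(synthdata.flowers_to_frame(flowers))
        means = cv_tbl.groupby("syndrome")["cv"].mean()
        bat[i], other[i] = means["bat"], means["other"]
    return {
        "bat_mean_cv": float(bat.mean()),
        "other_mean_cv": float(other.mean()),
        "n_seeds": n_seeds,
        "n_flowers_per_species": n_per_species,
    }
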