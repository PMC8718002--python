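"""Flower morphometrics: bell surface area and relative-variability statistics.

The reflective surface of a bell-shaped corolla is modelled as a circular
disc (the corolla opening, radius ``r_c`` from the outer diameter) plus the
lateral surface of a paraboloid (the corolla chalice, radius ``r_p`` from the
inner diameter and height ``h`` equal to the corolla length):

    F_sur = pi*r_p/(6*h**2) * [ (r_p**2 + 4*h**2)**1.5 - r_p**3 ] + pi*r_c**2

Interspecific variability is compared with the coefficient of variation
cV = sigma/mu, which is dimensionless and therefore comparable across flowers
of very different absolute size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical morphological features, all in mm
FEATURES = (
    "corolla_length",
    "calyx_length",
    "inner_depth",
    "inner_diam_h",
    "inner_diam_v",
    "outer_diam_h",
    "outer_diam_v",
)


@dataclass(frozen=True)
class MorphFeatures:
    """Morphological measurements of a single flower, in mm.

    Radially symmetric species may carry a single diameter per position; pass
    the same value for the horizontal and vertical fields.
    """

    corolla_length: float
    calyx_length: float
    inner_depth: float
    inner_diam_h: float
    inner_diam_v: float
    outer_diam_h: float
    outer_diam_v: float

    @property
    def r_p(self) -> float:
        """Paraboloid radius: half the mean inner corolla diameter."""
        return 0.5 * 0.5 * (self.inner_diam_h + self.inner_diam_v)

    @property
    def r_c(self) -> float:
        """Opening radius: half the mean outer corolla diameter."""
        return 0.5 * 0.5 * (self.outer_diam_h + self.outer_diam_v)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURES}


def paraboloid_area(r_p: float, h: float) -> float:
    """Lateral surface area of a paraboloid of radius ``r_p`` and height ``h``.

    Evaluated in a numerically stable form so that the analytic limit
    ``h -> 0`` (a flat disc of area pi*r_p**2) is reached without
    catastrophic cancellation.
    """
    if r_p < 0 or h < 0:
        raise ValueError("paraboloid radius and height must be non-negative")
    if r_p == 0.0:
        return 0.0
    if h == 0.0:
        return math.pi * r_p**2
    # bracket = r_p**3 * ((1 + x)**1.5 - 1), x = 4 h^2 / r_p^2
    x = 4.0 * h * h / (r_p * r_p)
    bracket = r_p**3 * math.expm1(1.5 * math.log1p(x))
    return math.pi * r_p / (6.0 * h * h) * bracket


def surface_area(m: MorphFeatures) -> float:
    """Reflective flower surface area in mm**2 (paraboloid chalice + opening disc)."""
    r_p, r_c, h = m.r_p, m.r_c, m.corolla_length
    if r_p <= 0 or r_c <= 0 or h < 0:
        raise ValueError(
            f"non-positive morphology: r_p={r_p}, r_c={r_c}, h={h}"
        )
    return paraboloid_area(r_p, h) + math.pi * r_c**2


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation: SD (n-1 denominator) over mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("cV needs at least two values")
    mu = arr.mean()
    if mu == 0:
        raise ValueError("cV undefined for zero mean")
    return float(arr.std(ddof=1) / mu)


def species_cv_table(
    flowers: pd.DataFrame,
    features: Optional[Iterable[str]] = None,
    species_col: str = "species_id",
) -> pd.DataFrame:
    """Per-species, per-feature coefficients of variation in long format.

    Parameters
    ----------
    flowers:
        One row per flower with a species column and one column per
        morphological feature. Features that are absent (all-NaN) for a
        species are skipped, not zero-filled; species with fewer than two
        flowers are dropped with a warning.

    Returns
    -------
    DataFrame with columns ``species_id``, ``syndrome`` (if present in the
    input), ``feature``, ``cv``.
    """
    feats = list(features) if features is not None else list(FEATURES)
    rows = []
    for species, grp in flowers.groupby(species_col, sort=True):
        if len(grp) < 2:
            logger.warning("species %s has <2 flowers; dropped from cV table", species)
            continue
        syndrome = grp["syndrome"].iloc[0] if "syndrome" in grp else None
        for feat in feats:
            if feat not in grp:
                continue
            vals = grp[feat].dropna().to_numpy()
            if vals.size < 2:
                continue
            row = {species_col: species, "feature": feat,
                   "cv": coefficient_of_variation(vals)}
            if syndrome is not None:
                row["syndrome"] = syndrome
            rows.append(row)
    return pd.DataFrame(rows)


def species_mean_cv(cv_table: pd.DataFrame, species_col: str = "species_id") -> pd.DataFrame:
    """Mean cV across features for each species (keeps syndrome if present)."""
    keys = [species_col] + (["syndrome"] if "syndrome" in cv_table else [])
    return cv_table.groupby(keys, as_index=False)["cv"].mean()
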