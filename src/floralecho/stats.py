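"""Statistical comparisons: TS~area regression, syndrome contrasts, cV summaries.

The core analyses are (i) an ordinary least-squares regression of flower-level
band target strength on the natural log of flower surface area, (ii) a Welch
two-sample t-test on the regression residuals grouped by pollination syndrome
(Welch because the groups need not share a variance; the degrees of freedom
are fractional), (iii) per-syndrome summaries of morphological and acoustic
coefficients of variation, and (iv) a likelihood-ratio comparison of nested
linear mixed models with a random plant-family intercept, refit by maximum
likelihood (not REML) as required for fixed-effect LR tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "RegressionFit",
    "GroupComparison",
    "fit_ts_regression",
    "residual_syndrome_test",
    "cv_syndrome_summary",
    "lmm_compare",
]


@dataclass
class RegressionFit:
    """OLS fit of band TS (dB) on ln(surface area in mm^2)."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df: Tuple[int, int]
    residuals: np.ndarray
    n: int

    def predict(self, surface_area: np.ndarray) -> np.ndarray:
        return self.slope * np.log(np.asarray(surface_area, dtype=float)) + self.intercept


@dataclass
class GroupComparison:
    """Welch two-sample comparison of {bat, other} groups."""

    mean_bat: float
    mean_other: float
    t_statistic: float
    welch_df: float
    p_value: float
    labels: Tuple[str, str] = ("bat", "other")

    @property
    def difference(self) -> float:
        return self.mean_bat - self.mean_other


def fit_ts_regression(
    ts_table: pd.DataFrame,
    ts_col: str = "ts_broad",
    area_col: str = "surface_area",
) -> RegressionFit:
    """OLS of band TS on ln(surface area): TS = slope*ln(area) + intercept."""
    df = ts_table[[ts_col, area_col]].dropna()
    if len(df) < 3:
        raise ValueError("regression needs at least 3 flowers")
    area = df[area_col].to_numpy(dtype=float)
    if np.any(area <= 0):
        raise ValueError("surface areas must be positive")
    x = np.log(area)
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) predictor")
    y = df[ts_col].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        f_statistic=float(model.fvalue),
        df=(int(model.df_model), int(model.df_resid)),
        residuals=np.asarray(model.resid),
        n=len(df),
    )


def residual_syndrome_test(
    fit: RegressionFit, syndromes: Sequence[str]
) -> GroupComparison:
    """Welch t-test on regression residuals grouped by pollination syndrome."""
    syndromes = np.asarray(list(syndromes))
    if syndromes.size != fit.n:
        raise ValueError("syndrome labels must match the regression rows")
    bat = fit.residuals[syndromes == "bat"]
    other = fit.residuals[syndromes == "other"]
    if bat.size < 2 or other.size < 2:
        raise ValueError("each syndrome group needs at least 2 flowers")
    res = sps.ttest_ind(bat, other, equal_var=False)
    return GroupComparison(
        mean_bat=float(bat.mean()),
        mean_other=float(other.mean()),
        t_statistic=float(res.statistic),
        welch_df=float(res.df),
        p_value=float(res.pvalue),
    )


def acoustic_cv_table(
    ts_band_table: pd.DataFrame,
    band_cols: Sequence[str] = ("ts_45kHz", "ts_68kHz", "ts_102kHz", "ts_153kHz"),
    species_col: str = "species_id",
) -> pd.DataFrame:
    """Per-species cV of flower-level band TS, one row per (species, band).

    TS values are delogged to linear power before the cV is taken: dB values
    here are negative, which would flip the sign of sigma/mu, so relative
    acoustic variability is defined on the linear-power scale.
    """
    rows = []
    for species, grp in ts_band_table.groupby(species_col, sort=True):
        if len(grp) < 2:
            continue
        syndrome = grp["syndrome"].iloc[0] if "syndrome" in grp else None
        for col in band_cols:
            lin = 10.0 ** (grp[col].to_numpy(dtype=float) / 10.0)
            mu = lin.mean()
            row = {
                species_col: species,
                "band": col,
                "cv": float(lin.std(ddof=1) / mu),
            }
            if syndrome is not None:
                row["syndrome"] = syndrome
            rows.append(row)
    return pd.DataFrame(rows)


def cv_syndrome_summary(
    cv_table: pd.DataFrame,
    ts_band_table: Optional[pd.DataFrame] = None,
    band_cols: Sequence[str] = ("ts_45kHz", "ts_68kHz", "ts_102kHz", "ts_153kHz"),
) -> Dict[str, Dict[str, float]]:
    """Per-syndrome mean cV of morphology and (optionally) of band TS.

    ``cv_table`` is the long-format morphological cV table (must carry a
    ``syndrome`` column); ``ts_band_table`` holds one row per flower with
    per-band overall TS values and is reduced to per-species acoustic cVs
    before the syndrome means are taken.
    """
    out: Dict[str, Dict[str, float]] = {
        "morphological": cv_table.groupby("syndrome")["cv"].mean().to_dict()
    }
    if ts_band_table is not None:
        ac = acoustic_cv_table(ts_band_table, band_cols=band_cols)
        out["acoustic"] = ac.groupby("syndrome")["cv"].mean().to_dict()
    return out


def lmm_compare(
    data: pd.DataFrame,
    response: str,
    full_fixed: str,
    reduced_fixed: str = "1",
    group: str = "family",
) -> Dict[str, float]:
    """Likelihood-ratio comparison of nested mixed models (random intercept).

    Both models carry a random intercept per ``group`` and are fit by maximum
    likelihood (REML likelihoods are not comparable across fixed-effect
    structures). Returns chi2, the fixed-effect df difference, the p-value,
    and a convergence flag; non-convergence is reported, never silently
    ignored.

    Example: ``lmm_compare(df, "ts_broad", "np.log(surface_area) * syndrome",
    "np.log(surface_area)")`` tests the syndrome main effect plus interaction
    (2 df).
    """
    fits = {}
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, fixed in (("full", full_fixed), ("reduced", reduced_fixed)):
            model = smf.mixedlm(
                f"{response} ~ {fixed}", data=data, groups=data[group]
            )
            fit = model.fit(reml=False)
            if not (getattr(fit, "converged", True) and np.isfinite(fit.llf)):
                fit = model.fit(reml=False, method="powell")
            converged = converged and bool(
                getattr(fit, "converged", True) and np.isfinite(fit.llf)
            )
            fits[name] = fit
    df_diff = int(len(fits["full"].fe_params) - len(fits["reduced"].fe_params))
    chi2 = 2.0 * (fits["full"].llf - fits["reduced"].llf)
    chi2 = max(float(chi2), 0.0)
    p = float(sps.chi2.sf(chi2, df_diff)) if df_diff > 0 else float("nan")
    return {
        "chi2": chi2,
        "df": df_diff,
        "p_value": p,
        "converged": converged,
    }
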