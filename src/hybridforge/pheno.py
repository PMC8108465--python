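"""Phenotype processing: multi-environment BLUP, field check-row
adjustment, within-population z-scoring, and mid-parent heterosis.

Phenotypes arrive as long-format multi-environment records (sample,
trait, location, year, value). Each line's value across environments is
condensed to a best linear unbiased prediction (BLUP) under a mixed
model with location and year as fixed effects and line as a random
intercept; the BLUP shrinks noisy line means toward the population mean
in proportion to the variance-component ratio.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TraitTable

logger = logging.getLogger("hybridforge")


@dataclass(frozen=True)
class ZScoreTransform:
    """Per-population standardization parameters (exactly invertible)."""

    population: str
    trait: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")


def fit_line_blup(tt: TraitTable, trait: str) -> pd.Series:
    """Per-line BLUPs of one trait across environments.

    Model: value = mu + location + year (fixed) + line (random) + error,
    fitted by REML. Returns a Series indexed by sample id, on the trait's
    original scale: the grand fixed-effect mean plus the shrunken random
    line effect. Deterministic given the data.

    In the no-residual limit of a balanced design this reduces to the
    per-line mean.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = tt.for_trait(trait).copy()
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    if df["sample"].nunique() < 2:
        raise ValueError("BLUP needs at least 2 lines")
    df["location"] = df["location"].astype(str)
    df["year"] = df["year"].astype(str)

    terms = []
    if df["location"].nunique() > 1:
        terms.append("C(location)")
    if df["year"].nunique() > 1:
        terms.append("C(year)")
    rhs = " + ".join(terms) if terms else "1"

    n_fixed = 1 + (df["location"].nunique() - 1) + (df["year"].nunique() - 1)
    if len(df) - n_fixed - df["sample"].nunique() <= 0:
        raise ValueError("zero residual degrees of freedom for BLUP model")

    values = df["value"].to_numpy()
    if np.ptp(values) == 0.0:
        # degenerate: every record identical; line variance is 0
        return pd.Series(values[0], index=sorted(df["sample"].unique()))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"value ~ {rhs}", df, groups=df["sample"])
        fit = model.fit(reml=True, method=["lbfgs", "powell"])

    # grand mean of the fixed part, averaged over the observed design
    fixed_mean = float(np.mean(fit.fittedvalues - _ranef_per_obs(fit, df)))
    re = pd.Series(
        {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}
    )
    blup = (fixed_mean + re).sort_index()
    blup.name = trait
    return blup


def _ranef_per_obs(fit, df: pd.DataFrame) -> np.ndarray:
    re = {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}
    return df["sample"].map(re).to_numpy()


def check_row_adjust(
    tt: TraitTable, check_id: str, window: int = 10
) -> TraitTable:
    """Remove field spatial trend using repeated check rows.

    Within each (trait, location, year) block, every plot value is
    adjusted by the deviation of the local check mean (check rows whose
    ``row`` index lies within ``window`` of the plot) from the global
    check mean. Requires a ``row`` column; blocks without checks pass
    through unchanged with a warning.
    """
    if "row" not in tt.df.columns:
        raise ValueError("check-row adjustment needs a 'row' column")
    df = tt.df.copy()
    for (trait, loc, year), block_idx in df.groupby(
        ["trait", "location", "year"]
    ).groups.items():
        block = df.loc[block_idx]
        checks = block[block["sample"] == check_id]
        if checks.empty:
            logger.warning(
                "no check rows for %s/%s/%s; values unadjusted", trait, loc, year
            )
            continue
        check_rows = checks["row"].to_numpy(dtype=float)
        check_vals = checks["value"].to_numpy(dtype=float)
        global_mean = check_vals.mean()
        rows = block["row"].to_numpy(dtype=float)
        local = np.empty(len(rows))
        for i, r in enumerate(rows):
            near = np.abs(check_rows - r) <= window
            if not near.any():  # fall back to the nearest single check
                near = np.abs(check_rows - r) == np.abs(check_rows - r).min()
            local[i] = check_vals[near].mean()
        df.loc[block_idx, "value"] = block["value"].to_numpy() - (local - global_mean)
    return TraitTable(df)


def fit_zscore(values, population: str = "", trait: str = "") -> ZScoreTransform:
    """Estimate z-score parameters (mean, sd with ddof=1) on a population."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("z-score needs at least 2 values")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise ValueError("constant values: z-score undefined (sd = 0)")
    return ZScoreTransform(population, trait, float(np.mean(v)), sd)


def zscore(values, transform: ZScoreTransform) -> np.ndarray:
    """z_i = (y_i - mean) / sd."""
    return (np.asarray(values, dtype=float) - transform.mean) / transform.sd


def inverse_zscore(z, transform: ZScoreTransform) -> np.ndarray:
    """Back-conversion y_i = z_i * sd + mean (exact inverse of zscore)."""
    return np.asarray(z, dtype=float) * transform.sd + transform.mean


def compute_mph(y_h, y_m, y_p):
    """Mid-parent heterosis: (y_h - midparent) / midparent.

    Symmetric in the parents and invariant to positive rescaling of all
    three inputs. Undefined (NaN, with a warning) where the mid-parent
    value is zero.
    """
    y_h = np.asarray(y_h, dtype=float)
    mid = (np.asarray(y_m, dtype=float) + np.asarray(y_p, dtype=float)) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        mph = np.where(mid != 0.0, (y_h - mid) / mid, np.nan)
    n_bad = int(np.isnan(mph).sum()) if mph.ndim else int(np.isnan(mph))
    if n_bad:
        logger.warning("%d crosses have zero mid-parent value; MPH undefined", n_bad)
    return mph if mph.ndim else float(mph)
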