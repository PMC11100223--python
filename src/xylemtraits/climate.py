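"""Trait vs climate-of-origin correlation screen.

Species-mean traits (optionally with the first two PCA scores appended as
pseudo-traits) are correlated with the climate covariates of each species'
origin: elevation (Ele, m), latitude/longitude (Lat/Lon, degrees), annual
mean temperature (AMT, C), mean temperature of the warmest/driest quarter
(MTWQ/MTDQ, C), annual precipitation (APRE, mm), precipitation of the
wettest/driest quarter (PREWQ/PREDQ, mm), and an aridity index (AI).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .varstats import _pearson_pair

logger = logging.getLogger(__name__)

CLIMATE_VARS = ["Ele", "Lat", "Lon", "AMT", "MTWQ", "MTDQ",
                "APRE", "PREWQ", "PREDQ", "AI"]

#: raw two-sided p-value tiers used for star annotations
STAR_TIERS = [(0.001, "***"), (0.05, "**"), (0.1, "*")]


def stars(p: float) -> str:
    for cut, mark in STAR_TIERS:
        if p < cut:
            return mark
    return ""


def climate_correlation_table(
    traits: pd.DataFrame,
    climate: pd.DataFrame,
    bh_adjust: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pearson r, p and star matrices (traits x climate variables).

    Rows are matched on species index; at least 4 matched species are
    required.  No multiple-testing correction by default (raw tiers);
    ``bh_adjust=True`` applies Benjamini-Hochberg across all pairs before
    starring.
    """
    traits = traits.select_dtypes(include=[np.number])
    climate = climate.select_dtypes(include=[np.number])
    common = traits.index.intersection(climate.index)
    unmatched = sorted(set(traits.index).symmetric_difference(climate.index))
    if unmatched:
        logger.warning("species without both trait and climate rows: %s",
                       unmatched)
    if len(common) < 4:
        raise ValueError(
            f"need >= 4 matched species, got {len(common)}")
    t = traits.loc[common]
    c = climate.loc[common]
    r = pd.DataFrame(np.nan, index=t.columns, columns=c.columns)
    p = pd.DataFrame(np.nan, index=t.columns, columns=c.columns)
    for trait in t.columns:
        for var in c.columns:
            pair = pd.concat([t[trait], c[var]], axis=1).dropna()
            r.loc[trait, var], p.loc[trait, var] = _pearson_pair(
                pair.iloc[:, 0].to_numpy(float), pair.iloc[:, 1].to_numpy(float))
    p_for_stars = p
    if bh_adjust:
        flat = p.to_numpy().ravel()
        ok = np.isfinite(flat)
        adj = flat.copy()
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
        p_for_stars = pd.DataFrame(adj.reshape(p.shape), index=p.index,
                                   columns=p.columns)
    star = p_for_stars.map(lambda v: stars(v) if np.isfinite(v) else "")
    return r, p, star


def read_climate_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "species" in df.columns:
        df = df.set_index("species")
    if df.index.duplicated().any():
        raise ValueError("climate table has duplicate species rows")
    return df
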