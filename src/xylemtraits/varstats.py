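"""Interspecific-variation statistics: log transform, coefficients of
variation, one-way ANOVA with Tukey HSD and compact letter display, Pearson
correlation matrices, and |r|-based hierarchical clustering of traits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def log_transform(df: pd.DataFrame) -> pd.DataFrame:
    """Natural log of every numeric cell; errors (naming the cell) on any
    non-positive value rather than applying an offset."""
    out = df.copy()
    num = out.select_dtypes(include=[np.number]).columns
    for col in num:
        vals = out[col].astype(float)
        bad = vals.index[~(vals > 0)]
        if len(bad):
            raise ValueError(
                f"log_transform: non-positive value at row {bad[0]!r}, "
                f"column {col!r} ({vals.loc[bad[0]]})"
            )
        out[col] = np.log(vals)
    return out


def interspecific_cv(species_means: pd.DataFrame) -> pd.Series:
    """Percent coefficient of variation of species means, per trait:
    100 * sd(means) / mean(means), with the sample (ddof=1) SD."""
    if len(species_means) < 2:
        raise ValueError("interspecific_cv: need at least 2 species")
    num = species_means.select_dtypes(include=[np.number])
    return 100.0 * num.std(ddof=1) / num.mean()


def within_species_cv(derived: pd.DataFrame, species_col: str = "species",
                      traits=None) -> pd.DataFrame:
    """Per-species percent CV across individuals, one row per species."""
    if traits is None:
        traits = [c for c in derived.columns
                  if c != species_col and pd.api.types.is_numeric_dtype(derived[c])]
    grouped = derived.groupby(species_col)[list(traits)]
    return 100.0 * grouped.std(ddof=1) / grouped.mean()


@dataclass
class AnovaResult:
    trait: str
    F: float
    p: float
    tukey_p: pd.DataFrame        # symmetric pairwise HSD p-values
    letters: dict[str, str]      # compact letter display per group
    alpha: float


def compact_letter_display(labels, pairwise_p: np.ndarray,
                           alpha: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups that differ (pairwise p < alpha) share no letter; letters are
    assigned in a deterministic (alphabetical-label) order.
    """
    labels = list(labels)
    order = sorted(range(len(labels)), key=lambda i: str(labels[i]))
    letter_sets: list[set[int]] = [set(range(len(labels)))]
    for a_pos, b_pos in combinations(range(len(order)), 2):
        i, j = order[a_pos], order[b_pos]
        if pairwise_p[i, j] < alpha:
            for s in [s for s in letter_sets if i in s and j in s]:
                letter_sets.remove(s)
                for repl in (s - {i}, s - {j}):
                    if repl and not any(repl <= other for other in letter_sets):
                        letter_sets.append(repl)
    letter_sets.sort(key=lambda s: sorted(str(labels[i]) for i in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {str(lab): "" for lab in labels}
    for k, s in enumerate(letter_sets):
        ch = alphabet[k % len(alphabet)] * (1 + k // len(alphabet))
        for i in sorted(s):
            out[str(labels[i])] += ch
    return out


def anova_tukey(df: pd.DataFrame, trait: str, group: str = "species",
                alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA plus Tukey HSD post-hoc letters for one trait."""
    groups = {str(g): sub[trait].dropna().to_numpy(float)
              for g, sub in df.groupby(group)}
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("anova_tukey: need at least 2 groups")
    small = [g for g in labels if groups[g].size < 2]
    if small:
        raise ValueError(f"anova_tukey: groups with < 2 observations: {small}")
    arrays = [groups[g] for g in labels]
    F, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pmat = np.asarray(hsd.pvalue)
    letters = compact_letter_display(labels, pmat, alpha=alpha)
    tukey_p = pd.DataFrame(pmat, index=labels, columns=labels)
    return AnovaResult(trait, float(F), float(p), tukey_p, letters, alpha)


def _pearson_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform with n-2 df."""
    n = x.size
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if n < 3 or sx == 0 or sy == 0:
        return np.nan, np.nan
    r = float(np.cov(x, y, ddof=1)[0, 1] / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


def pearson_matrix(df: pd.DataFrame, pairwise: bool = False
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p matrices over the numeric columns.

    Complete-case by default; ``pairwise=True`` uses pairwise-complete
    observations per trait pair.  Zero-variance traits yield NaN with a
    warning.
    """
    num = df.select_dtypes(include=[np.number])
    if not pairwise:
        num = num.dropna(axis=0)
    if len(num) < 3:
        raise ValueError("pearson_matrix: need at least 3 complete rows")
    cols = list(num.columns)
    constant = [c for c in cols if num[c].dropna().std(ddof=1) == 0]
    if constant:
        warnings.warn(f"zero-variance traits, correlations undefined: {constant}")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = num[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                continue
            rij, pij = _pearson_pair(pair.iloc[:, 0].to_numpy(float),
                                     pair.iloc[:, 1].to_numpy(float))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[str]


def cluster_traits(r: pd.DataFrame) -> ClusterResult:
    """Average-linkage hierarchical clustering of traits on distance 1-|r|.

    Traits are sorted alphabetically before clustering so ties in merge
    heights resolve deterministically regardless of input column order.
    """
    mat = r.to_numpy(float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-10,
                                                      equal_nan=True):
        raise ValueError("cluster_traits: correlation matrix must be square "
                         "and symmetric")
    cols = sorted(str(c) for c in r.columns)
    rr = r.loc[cols, cols].to_numpy(float)
    dist = 1.0 - np.abs(rr)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(z)
    return ClusterResult(z, [cols[i] for i in order])
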