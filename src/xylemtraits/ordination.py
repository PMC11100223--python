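"""PCA of the species x trait matrix on the correlation scale.

Species means are z-scored per trait, the correlation matrix is
eigendecomposed, and component signs are fixed so the largest-magnitude
loading of each component is positive, making outputs reproducible across
LAPACK builds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (mean 0, sample SD 1); zero-variance columns
    are an error naming the trait."""
    if len(df) < 2:
        raise ValueError("standardize: need at least 2 rows")
    num = df.select_dtypes(include=[np.number])
    sd = num.std(ddof=1)
    dead = list(sd.index[sd == 0])
    if dead:
        raise ValueError(f"standardize: zero-variance traits: {dead}")
    return (num - num.mean()) / sd


@dataclass
class PcaResult:
    loadings: pd.DataFrame          # traits x components, orthonormal columns
    scores: pd.DataFrame            # rows x components
    explained_fraction: np.ndarray  # per component, sums to 1
    eigenvalues: np.ndarray


def pca_fit(z: pd.DataFrame) -> PcaResult:
    """PCA of an already-standardized matrix via eigendecomposition of its
    correlation (= covariance) matrix.

    Components are ordered by decreasing variance; rank-deficient inputs
    yield trailing zero-variance components (reported, not an error).
    """
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("pca_fit: need at least 2 rows and 2 columns")
    x = z.to_numpy(float)
    corr = np.cov(x, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        imax = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[imax, k] < 0:
            evecs[:, k] = -evecs[:, k]
    comp = [f"PC{i + 1}" for i in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=z.columns, columns=comp)
    scores = pd.DataFrame(x @ evecs, index=z.index, columns=comp)
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(loadings, scores, frac, evals)
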