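"""PCA-based clustering of population pools.

The multivariate step asks whether pools separate in the joint character
space: missing values are imputed with pool means, every character is
z-scored (so the PCA is on the correlation structure), components are
extracted, and pool differences are tested with a one-factor ANOVA on the
scores of each leading component, excluding pools below a minimum sample
size. The derived tail fork depth is excluded from PCA input — it is a
linear combination of T1 and T6 and can be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .characters import CharClass, DEFAULT_CHARACTER_MAP, characters_of_class
from .dataset import SpecimenRecord, TestResult, to_frame

MIN_POOL = 7  # pools below this n are excluded from significance tests


def impute_pool_means(matrix: pd.DataFrame, pool_labels: Sequence[str]) -> pd.DataFrame:
    """Fill missing cells with the observed mean of the character in the
    specimen's pool; observed cells are unchanged.

    A character entirely missing within a pool falls back to the global
    character mean (logged with a warning).
    """
    out = matrix.copy()
    pools = pd.Series(list(pool_labels), index=matrix.index)
    for col in out.columns:
        col_vals = out[col]
        global_mean = col_vals.mean()
        for pool, idx in pools.groupby(pools).groups.items():
            sub = col_vals.loc[idx]
            if sub.isna().all():
                if sub.size:
                    warnings.warn(
                        f"{col}: no observations in pool {pool}; imputed with global mean"
                    )
                fill = global_mean
            else:
                fill = sub.mean()
            out.loc[idx, col] = sub.fillna(fill)
    return out


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and scale to sample SD 1 (n−1)."""
    sd = matrix.std(ddof=1)
    dead = sd[(sd == 0) | sd.isna()].index.tolist()
    if dead:
        raise ValueError(f"zero-variance character(s): {', '.join(map(str, dead))}")
    return (matrix - matrix.mean()) / sd


@dataclass
class PcaResult:
    """Loadings, specimen scores and explained-variance shares.

    ``loadings`` is character × component with unit-norm columns, oriented
    so that each component's largest-magnitude loading is positive.
    ``scores`` is specimen × component (centered data times loadings).
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_explained: np.ndarray
    anova: list[TestResult] | None = None
    excluded_pools: list[str] | None = None


def pca(matrix: pd.DataFrame | np.ndarray) -> PcaResult:
    """Principal component analysis of a complete numeric matrix.

    Input is expected to be imputed and z-scored already, making this a
    correlation-structure PCA; the components are the eigenvectors of the
    sample covariance of the input, with explained variance equal to the
    eigenvalue share of total variance.
    """
    df = pd.DataFrame(matrix)
    X = df.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input contains non-finite values; impute first")
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    # SVD of the centered matrix == eigendecomposition of its covariance
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / max(n - 1, 1)
    loadings = vt.T  # columns are unit-norm eigenvectors
    # fixed sign convention: largest-|loading| entry of each component positive
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    scores = Xc @ loadings
    total_var = X.var(axis=0, ddof=1).sum()
    comps = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=df.columns, columns=comps),
        scores=pd.DataFrame(scores, index=df.index, columns=comps),
        variance_explained=eig / total_var,
    )


def anova_on_components(
    scores: pd.DataFrame,
    pool_labels: Sequence[str],
    min_pool: int = MIN_POOL,
    n_components: int | None = None,
) -> tuple[list[TestResult], list[str]]:
    """One-factor (pool) ANOVA on each component's scores.

    Pools with fewer than ``min_pool`` specimens are excluded and listed;
    at least two eligible pools are required.
    """
    pools = pd.Series(list(pool_labels), index=scores.index)
    counts = pools.value_counts()
    eligible = sorted(counts[counts >= min_pool].index)
    excluded = sorted(counts[counts < min_pool].index)
    if len(eligible) < 2:
        raise ValueError(f"fewer than 2 pools with n >= {min_pool}")
    cols = scores.columns[:n_components] if n_components else scores.columns
    results = []
    for col in cols:
        groups = [scores.loc[pools == p, col].to_numpy() for p in eligible]
        f, p = stats.f_oneway(*groups)
        n_tot = sum(g.size for g in groups)
        results.append(
            TestResult(
                statistic=float(f),
                df=(float(len(groups) - 1), float(n_tot - len(groups))),
                p=float(p),
                test_name="anova",
            )
        )
    return results, excluded


def pca_by_pool(
    records: Sequence[SpecimenRecord],
    char_class: CharClass | str = CharClass.BIOMETRIC,
    min_pool: int = MIN_POOL,
    definitions=None,
) -> PcaResult:
    """Full multivariate pipeline on specimen records.

    Selects the characters of one class (derived characters excluded),
    imputes pool means, z-scores, runs PCA, and attaches per-component
    pool ANOVAs computed on pools with n >= ``min_pool``.
    """
    defs = definitions if definitions is not None else DEFAULT_CHARACTER_MAP
    chars = [
        d.name
        for d in characters_of_class(char_class, defs, include_derived=False)
    ]
    frame = to_frame(records, defs)
    chars = [c for c in chars if c in frame.columns]
    if not chars:
        raise ValueError("no characters of the requested class in the dataset")
    matrix = frame[chars].astype(float)
    pools = frame["pool"]
    if pools.isna().any():
        raise ValueError("all records must have pools assigned before PCA")
    filled = impute_pool_means(matrix, pools)
    result = pca(zscore(filled))
    result.anova, result.excluded_pools = anova_on_components(
        result.scores, pools, min_pool=min_pool
    )
    return result
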