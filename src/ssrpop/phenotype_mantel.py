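"""Trait descriptive statistics, phenotypic distances, PCA and Mantel tests.

Traits are measured in heterogeneous units (cm, mm, g/plant, days, counts),
so pairwise Euclidean distances and PCA default to z-standardized traits;
the raw-scale alternative is a flag.  The Mantel statistic is the Pearson
correlation of the off-diagonal (upper-triangle) entries of two distance
matrices over the same accessions; significance comes from simultaneous
row/column permutation of the second matrix, one-sided for positive
association, with the +1 correction:

    p = (#{permuted r >= observed r} + 1) / (n_permutations + 1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .distance_tree import DistanceMatrix

__all__ = [
    "MantelResult",
    "load_trait_table",
    "descriptive_stats",
    "standardize",
    "euclidean_matrix",
    "pca",
    "mantel",
    "per_trait_mantel",
]

TRAIT_NAMES = (
    "PH", "SD", "FLL", "FLW", "PLL", "PLW", "LFI", "TN", "HD", "DMY", "FMY",
)


@dataclass(frozen=True)
class MantelResult:
    r: float
    n_permutations: int
    p_value: float
    seed: int | None


def load_trait_table(path) -> pd.DataFrame:
    """Accessions x traits TSV; rejects missing or non-numeric values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] < 2:
        raise ValueError("trait table needs at least 2 accessions")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing values in traits: {bad}")
    return df.astype(float)


def descriptive_stats(traits: pd.DataFrame) -> pd.DataFrame:
    """Per-trait mean, sample sd, min, max and CV% (100 * sd / mean).

    A trait with mean 0 gets CV = NaN with a warning rather than an error.
    """
    mean = traits.mean()
    sd = traits.std(ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * sd / mean
    if (mean == 0).any():
        warnings.warn(
            f"CV undefined for zero-mean traits: {list(traits.columns[mean == 0])}",
            stacklevel=2,
        )
        cv[mean == 0] = np.nan
    cv[sd == 0] = 0.0
    out = pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "min": traits.min(),
            "max": traits.max(),
            "cv_percent": cv,
        }
    )
    out.index.name = "trait"
    return out


def standardize(traits: pd.DataFrame, drop_constant: bool = True) -> pd.DataFrame:
    """Z-score each trait; zero-variance traits are dropped with a warning."""
    sd = traits.std(ddof=1)
    constant = list(traits.columns[sd == 0])
    if constant:
        if not drop_constant:
            raise ValueError(f"zero-variance traits: {constant}")
        warnings.warn(f"dropping zero-variance traits: {constant}", stacklevel=2)
        traits = traits.drop(columns=constant)
        sd = sd.drop(constant)
    if traits.shape[1] == 0:
        raise ValueError("no traits left after dropping constant columns")
    return (traits - traits.mean()) / sd


def euclidean_matrix(traits: pd.DataFrame, standardize_traits: bool = True) -> DistanceMatrix:
    """Pairwise Euclidean distance between accessions over (z-scored) traits."""
    t = standardize(traits) if standardize_traits else traits
    d = squareform(pdist(t.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(list(traits.index.astype(str)), d)


def pca(
    traits: pd.DataFrame, standardize_traits: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA via eigendecomposition of the correlation (or covariance) matrix.

    Returns (scores, loadings, explained variance percentages summing to
    100).  Component signs are fixed by making the largest-magnitude entry
    of each loading vector positive.
    """
    t = standardize(traits) if standardize_traits else traits
    X = t.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    if not np.any(np.diag(cov) > 0):
        raise ValueError("trait matrix has rank 0")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] = -evecs[:, k]
    explained = 100.0 * evals / evals.sum()
    comps = [f"PC{i + 1}" for i in range(len(evals))]
    scores = pd.DataFrame(Xc @ evecs, index=t.index, columns=comps)
    loadings = pd.DataFrame(evecs, index=t.columns, columns=comps)
    return scores, loadings, explained


def _triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (positive) Mantel test between two distance matrices.

    Labels must match in the same order; the null distribution permutes the
    rows and columns of ``d2`` simultaneously.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must have identical labels in order")
    n = d1.n
    if n < 4:
        raise ValueError("need at least 4 labels for a meaningful Mantel test")
    x = _triangle(d1.values)
    y = _triangle(d2.values)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a distance triangle; r undefined")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xz * yz))
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = d2.values[np.ix_(perm, perm)][iu]
        ypz = (yp - yp.mean()) / yp.std()
        if float(np.mean(xz * ypz)) >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, n_permutations=n_permutations, p_value=p, seed=seed)


def per_trait_mantel(
    genetic: DistanceMatrix,
    traits: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mantel r and p of the genetic matrix vs each single-trait distance.

    Each trait is z-standardized and turned into its own Euclidean distance
    matrix.  Constant traits are reported with NaN r/p and a warning.
    """
    rows = []
    rng = np.random.default_rng(seed)
    for trait in traits.columns:
        col = traits[[trait]]
        if col[trait].std(ddof=1) == 0:
            warnings.warn(f"trait {trait!r} is constant; Mantel undefined", stacklevel=2)
            rows.append({"trait": trait, "r": np.nan, "p_value": np.nan})
            continue
        dmat = euclidean_matrix(col, standardize_traits=True)
        res = mantel(
            genetic, dmat, n_permutations=n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rows.append({"trait": trait, "r": res.r, "p_value": res.p_value})
    return pd.DataFrame(rows).set_index("trait")
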