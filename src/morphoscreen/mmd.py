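"""Maximum mean discrepancy: unbiased squared-MMD estimation and feature ranking.

MMD measures the distance between the mean embeddings of two distributions
in the RKHS of a characteristic kernel (here Gaussian), so it vanishes iff
the distributions agree. The unbiased empirical estimator for samples X
(size m) and Y (size n) is

    MMD^2 = 1/(m(m-1)) sum_{i != j} k(x_i, x_j)
          + 1/(n(n-1)) sum_{i != j} k(y_i, y_j)
          - 2/(mn)     sum_{i, j}   k(x_i, y_j)

with the cross term over all m*n pairs (the two samples' indices are
unrelated). A variant that additionally excludes index-equal cross pairs is
available as ``convention="printed"`` for fidelity with a common typo in
print; the two differ by exactly the excluded diagonal terms.

The estimator is unbiased, hence may be negative; the reported non-negative
"MMD score" is sqrt(max(0, MMD^2)). The kernel bandwidth defaults to the
median heuristic on the pooled sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from .features.registry import FEATURE_CATEGORIES, FEATURE_NAMES, N_FEATURES
from .synthetic import feature_matrix

logger = logging.getLogger(__name__)

CONVENTIONS = ("all-pairs", "printed")


@dataclass
class MMDResult:
    mmd2: float
    mmd_score: float
    sigma: float
    m: int
    n: int
    convention: str = "all-pairs"

    def to_dict(self) -> dict:
        return {
            "mmd2": self.mmd2,
            "mmd_score": self.mmd_score,
            "sigma": self.sigma,
            "m": self.m,
            "n": self.n,
            "convention": self.convention,
        }


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """k(x, y) = exp(-||x - y||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if x.shape != y.shape:
        raise ValueError("x and y must have equal dimensions")
    d2 = float(((x - y) ** 2).sum())
    return float(np.exp(-d2 / (2.0 * sigma ** 2)))


def _gram(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(X, Y, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma ** 2))


def median_heuristic_bandwidth(
    X: np.ndarray,
    Y: np.ndarray | None = None,
    max_points: int = 2000,
    seed: int = 0,
) -> float:
    """Median of nonzero pairwise distances over the pooled sample.

    Falls back to the smallest nonzero distance if the median is 0; all
    points identical is an error. Samples larger than ``max_points`` are
    subsampled with the given seed before the O(n^2) distance computation.
    """
    pooled = np.atleast_2d(np.asarray(X, dtype=float))
    if pooled.ndim == 2 and pooled.shape[1] == 0:
        raise ValueError("empty feature dimension")
    if Y is not None:
        pooled = np.vstack([pooled, np.atleast_2d(np.asarray(Y, dtype=float))])
    if len(pooled) < 2:
        raise ValueError("pooled sample must contain at least 2 points")
    if len(pooled) > max_points:
        rng = np.random.default_rng(seed)
        pooled = pooled[rng.choice(len(pooled), max_points, replace=False)]
    d = pdist(pooled)
    nonzero = d[d > 0]
    if nonzero.size == 0:
        raise ValueError("all points identical; bandwidth undefined")
    med = float(np.median(d))
    return med if med > 0 else float(nonzero.min())


def mmd2_unbiased(
    X: np.ndarray,
    Y: np.ndarray,
    sigma: float | None = None,
    convention: str = "all-pairs",
) -> MMDResult:
    """Unbiased empirical squared MMD with a Gaussian kernel.

    Within-sample sums exclude i = j. The default cross term runs over all
    m*n pairs; ``convention="printed"`` excludes index-equal cross pairs as
    well. ``sigma=None`` selects the pooled median-heuristic bandwidth.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = len(X), len(Y)
    if m < 2 or n < 2:
        raise ValueError(f"m and n must be >= 2 (got m={m}, n={n})")
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    if sigma is None:
        sigma = median_heuristic_bandwidth(X, Y)
    if sigma <= 0:
        raise ValueError("sigma must be strictly positive")

    Kxx = _gram(X, X, sigma)
    Kyy = _gram(Y, Y, sigma)
    Kxy = _gram(X, Y, sigma)

    term_x = (Kxx.sum() - np.trace(Kxx)) / (m * (m - 1))
    term_y = (Kyy.sum() - np.trace(Kyy)) / (n * (n - 1))
    cross = Kxy.sum()
    if convention == "printed":
        cross -= np.trace(Kxy)  # removes the min(m, n) index-equal pairs
    mmd2 = float(term_x + term_y - 2.0 * cross / (m * n))
    return MMDResult(
        mmd2=mmd2,
        mmd_score=float(np.sqrt(max(0.0, mmd2))),
        sigma=float(sigma),
        m=m,
        n=n,
        convention=convention,
    )


def per_feature_mmd(
    X: np.ndarray,
    Y: np.ndarray,
    seed: int = 0,
    bandwidth_subsample: int = 1024,
) -> pd.DataFrame:
    """MMD score of every registry feature between two tables/matrices.

    Each feature's two 1-D samples are standardized by the pooled mean and
    scale, the bandwidth is the per-feature median heuristic, and the score
    is sqrt(max(0, MMD^2)). Features constant in the pooled sample get score
    0 (logged). Returns a DataFrame (index, name, category, mmd2, mmd_score,
    sigma, rank) ordered by registry index; rank is 1 for the largest score,
    ties broken by ascending index.
    """
    X = _as_matrix(X)
    Y = _as_matrix(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the feature registry")
    m, n = len(X), len(Y)
    if m < 2 or n < 2:
        raise ValueError("m and n must be >= 2")
    p = X.shape[1]

    mmd2s = np.zeros(p)
    scores = np.zeros(p)
    sigmas = np.full(p, np.nan)
    for j in range(p):
        xj, yj = X[:, j], Y[:, j]
        pooled = np.concatenate([xj, yj])
        mu, sd = pooled.mean(), pooled.std()
        if sd == 0:
            logger.info("feature %d constant in both samples; score 0", j + 1)
            continue
        xs, ys_ = (xj - mu) / sd, (yj - mu) / sd
        try:
            sigma = median_heuristic_bandwidth(
                xs[:, None], ys_[:, None], max_points=bandwidth_subsample, seed=seed
            )
        except ValueError:
            continue
        res = mmd2_unbiased(xs[:, None], ys_[:, None], sigma=sigma)
        mmd2s[j], scores[j], sigmas[j] = res.mmd2, res.mmd_score, sigma

    order = np.lexsort((np.arange(p), -scores))
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)

    names = FEATURE_NAMES if p == N_FEATURES else [f"f{j + 1:03d}" for j in range(p)]
    cats = (
        FEATURE_CATEGORIES if p == N_FEATURES else ["unknown"] * p
    )
    return pd.DataFrame(
        {
            "index": np.arange(1, p + 1),
            "name": names,
            "category": cats,
            "mmd2": mmd2s,
            "mmd_score": scores,
            "sigma": sigmas,
            "rank": rank,
        }
    )


def ranking_order(ranking: pd.DataFrame) -> np.ndarray:
    """0-based feature indices ordered best-to-worst by MMD rank."""
    return (ranking.sort_values("rank")["index"].to_numpy() - 1).astype(int)


def default_retain_grid(p: int = N_FEATURES, points: int = 10) -> list[int]:
    """Descending, approximately log-spaced feature-count grid down to 1."""
    grid = np.unique(np.round(np.geomspace(1, p, points)).astype(int))
    return sorted(set(grid.tolist()), reverse=True)


def elimination_curve(
    X: np.ndarray,
    y: np.ndarray,
    ranking: pd.DataFrame,
    retain_grid: list[int] | None = None,
    k: int = 10,
    C: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated accuracy as low-MMD features are removed.

    For each grid value r the top-r features by MMD rank are kept and k-fold
    CV accuracy is computed with the same fold seed throughout, so the
    full-feature point reproduces the unrestricted CV exactly. Grid values
    above the feature count are clipped with a warning.
    """
    from .classify import cross_validate  # local import avoids a cycle

    X = _as_matrix(X)
    y = np.asarray(y)
    order = ranking_order(ranking)
    if len(order) != X.shape[1]:
        raise ValueError("ranking must cover all features of X")
    if retain_grid is None:
        retain_grid = default_retain_grid(X.shape[1])
    rows = []
    for r in retain_grid:
        if r > X.shape[1]:
            logger.warning("retain %d clipped to %d features", r, X.shape[1])
            r = X.shape[1]
        if r < 1:
            continue
        keep = order[:r]
        cv = cross_validate(X[:, keep], y, k=k, C=C, seed=seed)
        rows.append(
            {
                "n_features": r,
                "accuracy": cv.mean_accuracy,
                "se": cv.se,
            }
        )
    return pd.DataFrame(rows).drop_duplicates(subset="n_features")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        try:
            return feature_matrix(X)
        except KeyError:
            return X.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(X, dtype=float))
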