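"""Compositional dissimilarity and distance-matrix statistics.

The response variable throughout is the Horn-Morisita dissimilarity: one
minus the probability-of-conspecific-draw overlap between two abundance
vectors, in the variance-normalized form that accepts non-integer
abundances,

    d(x, y) = 1 - 2 * sum_i x_i y_i / ((sum x_i^2/X^2 + sum y_i^2/Y^2) * X * Y)

with X = sum x, Y = sum y.  It is symmetric, lies in [0, 1], and is
invariant to proportional rescaling of either community, which makes it
robust to unequal sampling effort between sites.  The classical Morisita
index (integer counts, Simpson-index denominators) is kept behind a flag
for comparison.

Class-structure contrasts ("is dissimilarity greater between ecoregions
than within?") are Mantel correlations between the dissimilarity matrix
and a between-class indicator matrix, with one-sided permutation
inference over site labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "horn_morisita",
    "morisita",
    "pairwise_dissimilarity",
    "geographic_distance",
    "class_contrast",
    "ClassContrastResult",
    "condense",
    "squareform_ids",
]


def _validate_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    X = x.sum()
    Y = y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("undefined for empty community (zero-total vector)")
    return x, y, X, Y


def horn_morisita(x, y) -> float:
    """Horn-Morisita dissimilarity between two abundance vectors."""
    x, y, X, Y = _validate_pair(x, y)
    dx = (x * x).sum() / (X * X)
    dy = (y * y).sum() / (Y * Y)
    overlap = 2.0 * (x * y).sum() / ((dx + dy) * X * Y)
    return float(1.0 - overlap)


def morisita(x, y) -> float:
    """Classical Morisita dissimilarity (requires integer counts >= 0)."""
    x, y, X, Y = _validate_pair(x, y)
    if not (np.allclose(x, np.round(x)) and np.allclose(y, np.round(y))):
        raise ValueError("classical Morisita is defined for integer counts")
    if X < 2 or Y < 2:
        raise ValueError("classical Morisita needs at least 2 individuals per site")
    lx = (x * (x - 1)).sum() / (X * (X - 1))
    ly = (y * (y - 1)).sum() / (Y * (Y - 1))
    overlap = 2.0 * (x * y).sum() / ((lx + ly) * X * Y)
    return float(1.0 - overlap)


def pairwise_dissimilarity(abundances, variant: str = "horn") -> np.ndarray:
    """All-pairs dissimilarity matrix over the rows of a site x species table.

    Vectorized for the default Horn-Morisita variant; the classical
    variant falls back to an explicit double loop.
    """
    A = np.asarray(abundances, dtype=float)
    if A.ndim != 2:
        raise ValueError("expected a 2-D site x species abundance table")
    if (A < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = A.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("undefined for empty community (zero-total site)")
    n = A.shape[0]
    if variant == "horn":
        simpson = (A * A).sum(axis=1) / (totals * totals)
        cross = A @ A.T
        denom = (simpson[:, None] + simpson[None, :]) * totals[:, None] * totals[None, :]
        D = 1.0 - 2.0 * cross / denom
    elif variant == "morisita":
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = morisita(A[i], A[j])
    else:
        raise ValueError(f"unknown variant {variant!r}")
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return D


def geographic_distance(centroids, haversine: bool = False) -> np.ndarray:
    """Pairwise distance between site centroids given as (lat, lon) rows.

    Defaults to plain Euclidean distance on decimal degrees; great-circle
    (haversine, km) is available behind the flag.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("centroids must be an (n, 2) array of (lat, lon)")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    if haversine:
        lat = np.radians(pts[:, 0])
        lon = np.radians(pts[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        D = 2 * 6371.0088 * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    else:
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
    np.fill_diagonal(D, 0.0)
    return D


def condense(D: np.ndarray) -> np.ndarray:
    """Unfold the off-diagonal of a symmetric matrix, row-major over i < j.

    This ordering is shared by every distance-matrix statistic in the
    package so regression vectors align bit-identically across modules.
    """
    D = np.asarray(D)
    n = D.shape[0]
    iu = np.triu_indices(n, 1)
    return D[iu]


def squareform_ids(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) index pair arrays in the shared i < j row-major order."""
    return np.triu_indices(n, 1)


@dataclass
class ClassContrastResult:
    """Mantel contrast of dissimilarity against a class partition."""

    r: float
    p: float
    n_perm: int
    seed: int | None = None


def class_contrast(D, labels, n_perm: int = 999, seed=None) -> ClassContrastResult:
    """Between-class vs within-class dissimilarity contrast.

    Builds the indicator matrix M (1 where site labels differ) and
    returns the Pearson correlation r of the unfolded triangles of D and
    M, with a one-sided (greater) permutation p-value from permuting the
    site labels, using the add-one correction
    ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``.
    """
    D = np.asarray(D, dtype=float)
    labels = np.asarray(labels)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels must align with D")
    if np.unique(labels).size < 2:
        raise ValueError("contrast undefined: single class")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    y = D[iu]
    yc = y - y.mean()
    ynorm = np.sqrt((yc * yc).sum())

    def r_for(lab):
        m = (lab[iu[0]] != lab[iu[1]]).astype(float)
        mc = m - m.mean()
        denom = ynorm * np.sqrt((mc * mc).sum())
        if denom == 0:
            raise ValueError("zero variance in indicator matrix")
        return float((yc * mc).sum() / denom)

    r_obs = r_for(labels)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if r_for(labels[perm]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return ClassContrastResult(r=r_obs, p=p, n_perm=n_perm, seed=seed)
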