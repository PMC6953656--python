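"""Multiple regression on distance matrices (MRM) and the Mantel test.

Distance matrices cannot be fed to ordinary regression row-by-row: the
n(n-1)/2 pairwise entries are not independent observations.  MRM keeps
the OLS machinery on the unfolded lower triangles but replaces its
sampling theory with a permutation null built by simultaneously
permuting the rows and columns of the response matrix — the matrix
analogue of permuting observations — while the predictor matrices stay
fixed.  The Mantel test is the single-predictor special case, reported
as a correlation.

Environmental predictor matrices are absolute per-variable differences
|e_i - e_j|; predictors are z-standardized on the unfolded scale by
default so coefficient magnitudes are comparable across variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissimilarity import condense

__all__ = ["mantel", "mrm", "MRMResult", "env_distance_matrices", "model_comparison"]


def _permuted_condensed(D: np.ndarray, perm: np.ndarray, iu) -> np.ndarray:
    Dp = D[np.ix_(perm, perm)]
    return Dp[iu]


def mantel(Dy, Dx, n_perm: int = 999, seed=None) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with permutation p.

    One-sided (greater) test with the add-one correction; the response
    matrix's sites are permuted, ``n_perm`` times.
    """
    Dy = np.asarray(Dy, dtype=float)
    Dx = np.asarray(Dx, dtype=float)
    if Dy.shape != Dx.shape or Dy.ndim != 2 or Dy.shape[0] != Dy.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = Dy.shape[0]
    iu = np.triu_indices(n, 1)
    x = Dx[iu]
    y = Dy[iu]
    xc = x - x.mean()
    xn = np.sqrt((xc * xc).sum())
    yc = y - y.mean()
    yn = np.sqrt((yc * yc).sum())
    if xn == 0 or yn == 0:
        raise ValueError("zero variance in a distance matrix triangle")
    r_obs = float((xc * yc).sum() / (xn * yn))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        yp = _permuted_condensed(Dy, rng.permutation(n), iu)
        ypc = yp - yp.mean()
        r = (xc * ypc).sum() / (xn * np.sqrt((ypc * ypc).sum()))
        if r >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p


@dataclass
class MRMResult:
    """Fitted MRM: OLS on unfolded triangles with permutation inference."""

    predictor_names: list[str]
    coefficients: np.ndarray  # intercept first
    r_squared: float
    p_overall: float
    p_coefficients: np.ndarray  # aligned to non-intercept coefficients
    t_statistics: np.ndarray
    n_perm: int
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        rows = [{"term": "(intercept)", "coefficient": self.coefficients[0], "p": np.nan}]
        for k, name in enumerate(self.predictor_names):
            rows.append(
                {"term": name, "coefficient": self.coefficients[k + 1], "p": self.p_coefficients[k]}
            )
        return pd.DataFrame(rows)


def _design(predictors: dict[str, np.ndarray], iu, standardize: bool):
    names = list(predictors)
    cols = []
    for name in names:
        v = np.asarray(predictors[name], dtype=float)[iu]
        if standardize:
            sd = v.std()
            if sd == 0:
                raise ValueError(f"predictor {name!r} has zero variance")
            v = (v - v.mean()) / sd
        cols.append(v)
    X = np.column_stack([np.ones(len(cols[0]))] + cols)
    return names, X


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns: ones whose removal restores full rank
        offending = []
        for k in range(1, X.shape[1]):
            Xr = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                offending.append(names[k - 1])
        raise ValueError(f"collinear predictors (rank-deficient design): {offending}")


def mrm(
    Dy,
    predictors: dict[str, np.ndarray],
    n_perm: int = 999,
    seed=None,
    standardize: bool = True,
) -> MRMResult:
    """Multiple regression of a dissimilarity matrix on predictor matrices.

    The overall p-value comes from the permutation null of R²; each
    coefficient's p-value from the null of its |t| statistic.  Only the
    response matrix is permuted (standard MRM scheme).
    """
    Dy = np.asarray(Dy, dtype=float)
    if not predictors:
        raise ValueError("at least one predictor matrix required")
    n = Dy.shape[0]
    iu = np.triu_indices(n, 1)
    y = Dy[iu]
    names, X = _design(predictors, iu, standardize)
    _check_rank(X, names)
    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T  # hat projector onto coefficients
    m, k1 = X.shape

    def fit(yv):
        beta = H @ yv
        resid = yv - X @ beta
        sse = float(resid @ resid)
        sst = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst if sst > 0 else np.nan
        dof = m - k1
        sigma2 = sse / dof if dof > 0 else np.nan
        se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
        t = beta / se
        return beta, r2, t

    beta, r2, t = fit(y)
    if not np.isfinite(r2):
        raise ValueError("zero variance in response matrix")
    rng = np.random.default_rng(seed)
    ge_r2 = 0
    ge_t = np.zeros(k1 - 1, dtype=int)
    for _ in range(n_perm):
        yp = _permuted_condensed(Dy, rng.permutation(n), iu)
        _, r2p, tp = fit(yp)
        if r2p >= r2:
            ge_r2 += 1
        ge_t += np.abs(tp[1:]) >= np.abs(t[1:])
    p_overall = (1 + ge_r2) / (n_perm + 1)
    p_coef = (1 + ge_t) / (n_perm + 1)
    return MRMResult(
        predictor_names=names,
        coefficients=beta,
        r_squared=r2,
        p_overall=p_overall,
        p_coefficients=p_coef,
        t_statistics=t[1:],
        n_perm=n_perm,
        seed=seed,
    )


def env_distance_matrices(env_table: pd.DataFrame, columns: list[str]) -> dict[str, np.ndarray]:
    """Per-variable |e_i - e_j| distance matrices from a site table."""
    out = {}
    for col in columns:
        v = env_table[col].to_numpy(dtype=float)
        out[col] = np.abs(v[:, None] - v[None, :])
    return out


def model_comparison(
    Dy,
    geographic: np.ndarray,
    climate: dict[str, np.ndarray],
    vegetation: dict[str, np.ndarray],
    n_perm: int = 999,
    seed=None,
) -> pd.DataFrame:
    """Fit the nested MRM ladder and tabulate r² and overall p per model.

    Models: geographic alone; + climate; + vegetation; + both.  Because
    the models are nested OLS fits, r² is non-decreasing down the table.
    """
    if not climate or not vegetation:
        raise ValueError("climate and vegetation predictor sets must be nonempty")
    geo = {"geographic": np.asarray(geographic, dtype=float)}
    models = [
        ("geographic", geo),
        ("geographic + climate", {**geo, **climate}),
        ("geographic + vegetation", {**geo, **vegetation}),
        ("geographic + climate + vegetation", {**geo, **climate, **vegetation}),
    ]
    rows = []
    for name, preds in models:
        res = mrm(Dy, preds, n_perm=n_perm, seed=seed)
        rows.append({"model": name, "r_squared": res.r_squared, "p": res.p_overall})
    return pd.DataFrame(rows)
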