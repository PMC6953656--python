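"""Generalized dissimilarity modeling (GDM) from first principles.

GDM regresses compositional dissimilarity d_ij in [0, 1] on monotone
transforms of environmental and geographic differences between sites.
Each predictor x is expanded in monotone I-spline basis functions
I_1..I_K (integrated M-splines rising from 0 to 1 over the predictor's
observed range, knots at its 0/50/100 percentiles by default), and the
linear predictor is

    eta_ij = beta_0 + sum_p sum_k beta_pk |I_pk(x_pi) - I_pk(x_pj)|

with all coefficients constrained non-negative so that predicted
dissimilarity can only grow with environmental separation.  Expected
dissimilarity follows the negative-exponential link

    mu_ij = 1 - exp(-eta_ij)

which captures the asymptotic saturation of turnover over large
gradients.  The fit minimizes the weighted continuous-binomial deviance

    D = 2 sum_ij w_ij [ d ln(d/mu) + (1-d) ln((1-d)/(1-mu)) ]

(0 ln 0 = 0) by iteratively reweighted least squares with a
non-negative least-squares inner solve; the deviance is convex in beta
under this link, so the constrained optimum is unique.  Site pairs are
weighted by species richness, w_ij = (S_i + S_j) / (2 max_s S_s), which
damps the influence of poorly sampled sites in ad hoc occurrence data.

A predictor's fitted spline rises to the sum of its coefficients — its
"magnitude", the maximum partial ecological distance attributable to
that gradient.  Predictor significance is assessed by permuting a
predictor's site values, refitting, and comparing deviance explained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .raster import RasterGrid

__all__ = [
    "ISplineBasis",
    "ispline_eval",
    "SitePairTable",
    "build_site_pairs",
    "GDMModel",
    "fit_gdm",
    "gdm_deviance",
    "predict_dissimilarity",
    "PredictorSummary",
    "predictor_significance",
    "transform_env",
    "beta_map",
]

_D_EPS = 1e-9  # nudge for observed d == 1 so log terms stay finite
_MU_EPS = 1e-10


# ---------------------------------------------------------------------
# I-spline basis


def _knot_triples(knots: np.ndarray) -> list[tuple[float, float, float]]:
    """Consecutive-knot triples with boundary multiplicity 2.

    For knots (k_0 .. k_{K-1}) the padded sequence is
    (k_0, k_0, .., k_{K-1}, k_{K-1}) and basis i uses the triple
    (t_i, t_{i+1}, t_{i+2}), yielding exactly K basis functions.
    """
    padded = np.concatenate([[knots[0]], knots, [knots[-1]]])
    return [(padded[i], padded[i + 1], padded[i + 2]) for i in range(len(knots))]


def ispline_eval(knots, x) -> np.ndarray:
    """Evaluate the monotone I-spline basis at x.

    Piecewise-quadratic I-splines (running integrals of order-2
    M-splines, normalized to rise from 0 at/below the minimum knot to 1
    at/above the maximum knot); x is clamped to the knot range.  Returns
    an array of shape ``(len(x), n_splines)``.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.size < 2 or not (np.diff(knots) >= 0).all():
        raise ValueError("knots must be a non-decreasing vector of length >= 2")
    if knots[0] == knots[-1]:
        raise ValueError("constant predictor: min knot equals max knot")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros((x.size, knots.size))
    for i, (q1, q2, q3) in enumerate(_knot_triples(knots)):
        col = np.zeros_like(x)
        col[x >= q3] = 1.0
        if q2 > q1:
            sel = (x > q1) & (x < q2)
            col[sel] = (x[sel] - q1) ** 2 / ((q2 - q1) * (q3 - q1))
        if q3 > q2:
            sel = (x >= q2) & (x < q3)
            col[sel] = 1.0 - (q3 - x[sel]) ** 2 / ((q3 - q2) * (q3 - q1))
        out[:, i] = col
    return out


@dataclass
class ISplineBasis:
    """Per-predictor knot vectors (percentile-placed, order-3 I-splines)."""

    knots: dict[str, np.ndarray]
    n_splines: int = 3

    @classmethod
    def from_site_values(cls, site_values: pd.DataFrame, n_splines: int = 3) -> "ISplineBasis":
        knots = {}
        for col in site_values.columns:
            v = site_values[col].to_numpy(dtype=float)
            q = np.percentile(v, np.linspace(0, 100, n_splines))
            if q[0] == q[-1]:
                raise ValueError(f"constant predictor {col!r}: min knot equals max knot")
            knots[col] = q
        return cls(knots=knots, n_splines=n_splines)

    def evaluate(self, predictor: str, x) -> np.ndarray:
        if predictor not in self.knots:
            raise KeyError(f"no knots for predictor {predictor!r}")
        return ispline_eval(self.knots[predictor], x)


# ---------------------------------------------------------------------
# Site pairs


@dataclass
class SitePairTable:
    """All unordered site pairs with dissimilarity, weights and predictors.

    Site-level predictor values are stored once (``site_values``) with
    pair index arrays, so permutation tests can shuffle a predictor
    across sites and rebuild pairs cheaply.
    """

    site_ids: np.ndarray
    i_idx: np.ndarray  # (m,) first site of each pair (i < j, row-major)
    j_idx: np.ndarray
    d: np.ndarray  # (m,) observed dissimilarity
    w: np.ndarray  # (m,) richness weights
    site_values: pd.DataFrame  # (n_sites, n_predictors)

    @property
    def n_pairs(self) -> int:
        return self.d.size

    @property
    def predictor_names(self) -> list[str]:
        return list(self.site_values.columns)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "site_i": self.site_ids[self.i_idx],
                "site_j": self.site_ids[self.j_idx],
                "distance": self.d,
                "weight": self.w,
            }
        )
        for col in self.site_values.columns:
            v = self.site_values[col].to_numpy()
            df[f"{col}_i"] = v[self.i_idx]
            df[f"{col}_j"] = v[self.j_idx]
        return df

    def with_permuted_predictor(self, predictor: str, rng) -> "SitePairTable":
        sv = self.site_values.copy()
        sv[predictor] = rng.permutation(sv[predictor].to_numpy())
        return SitePairTable(self.site_ids, self.i_idx, self.j_idx, self.d, self.w, sv)


def build_site_pairs(
    D: np.ndarray,
    env: pd.DataFrame,
    richness: np.ndarray,
    predictors: list[str] | None = None,
) -> SitePairTable:
    """Unfold a dissimilarity matrix into the GDM site-pair table.

    ``env`` must carry ``site``, ``lat``, ``lon`` plus predictor
    columns; latitude and longitude enter as two separate predictors.
    Pair weights are (S_i + S_j) / (2 max S).
    """
    D = np.asarray(D, dtype=float)
    richness = np.asarray(richness, dtype=float)
    n = D.shape[0]
    if len(env) != n or richness.size != n:
        raise ValueError("D, env and richness must align on sites")
    if (richness <= 0).any():
        raise ValueError("species richness of 0 at a retained site")
    if predictors is None:
        predictors = [c for c in env.columns if c != "site"]
    site_values = env[predictors].reset_index(drop=True).astype(float)
    i_idx, j_idx = np.triu_indices(n, 1)
    d = D[i_idx, j_idx]
    if (d < 0).any() or (d > 1).any():
        raise ValueError("dissimilarities must lie in [0, 1]")
    w = (richness[i_idx] + richness[j_idx]) / (2.0 * richness.max())
    return SitePairTable(
        site_ids=env["site"].to_numpy() if "site" in env else np.arange(n),
        i_idx=i_idx,
        j_idx=j_idx,
        d=d,
        w=w,
        site_values=site_values,
    )


# ---------------------------------------------------------------------
# Fitting


def gdm_deviance(d: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    """Weighted continuous-binomial deviance with the 0 ln 0 convention."""
    mu = np.clip(mu, _MU_EPS, 1.0 - _MU_EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(d > 0, d * np.log(d / mu), 0.0)
        t2 = np.where(d < 1, (1.0 - d) * np.log((1.0 - d) / (1.0 - mu)), 0.0)
    return float(2.0 * (w * (t1 + t2)).sum())


@dataclass
class GDMModel:
    """A fitted generalized dissimilarity model."""

    basis: ISplineBasis
    intercept: float
    coefficients: dict[str, np.ndarray]  # predictor -> (n_splines,) >= 0
    null_deviance: float
    model_deviance: float
    converged: bool
    n_iter: int
    predictor_names: list[str] = field(default_factory=list)

    @property
    def pct_deviance_explained(self) -> float:
        if self.null_deviance <= 0:
            return 0.0
        return 100.0 * (self.null_deviance - self.model_deviance) / self.null_deviance

    def importance(self) -> dict[str, float]:
        """Per-predictor magnitude: the fitted spline's maximum height."""
        return {p: float(c.sum()) for p, c in self.coefficients.items()}

    def coefficient_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.intercept]] + [self.coefficients[p] for p in self.predictor_names]
        )

    # -- serialization -------------------------------------------------

    def to_text(self) -> str:
        lines = ["# betascape GDM model", f"intercept {self.intercept!r}"]
        lines.append(f"null_deviance {self.null_deviance!r}")
        lines.append(f"model_deviance {self.model_deviance!r}")
        lines.append(f"converged {int(self.converged)} n_iter {self.n_iter}")
        for p in self.predictor_names:
            k = " ".join(repr(float(v)) for v in self.basis.knots[p])
            c = " ".join(repr(float(v)) for v in self.coefficients[p])
            lines.append(f"predictor {p} knots {k} coefficients {c}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "GDMModel":
        intercept = null_dev = model_dev = 0.0
        converged, n_iter = True, 0
        knots: dict[str, np.ndarray] = {}
        coefs: dict[str, np.ndarray] = {}
        names: list[str] = []
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "intercept":
                intercept = float(parts[1])
            elif parts[0] == "null_deviance":
                null_dev = float(parts[1])
            elif parts[0] == "model_deviance":
                model_dev = float(parts[1])
            elif parts[0] == "converged":
                converged = bool(int(parts[1]))
                n_iter = int(parts[3])
            elif parts[0] == "predictor":
                name = parts[1]
                ci = parts.index("coefficients")
                knots[name] = np.array([float(v) for v in parts[3:ci]])
                coefs[name] = np.array([float(v) for v in parts[ci + 1 :]])
                names.append(name)
        basis = ISplineBasis(knots=knots, n_splines=len(next(iter(coefs.values()))))
        return cls(basis, intercept, coefs, null_dev, model_dev, converged, n_iter, names)

    @classmethod
    def load(cls, path) -> "GDMModel":
        with open(path) as fh:
            return cls.from_text(fh.read())


def _design_matrix(pairs: SitePairTable, basis: ISplineBasis) -> np.ndarray:
    """(m, 1 + P*K) design: intercept then |I_pk(x_i) - I_pk(x_j)| blocks."""
    cols = [np.ones(pairs.n_pairs)]
    for p in pairs.predictor_names:
        I = basis.evaluate(p, pairs.site_values[p].to_numpy())  # (n_sites, K)
        cols.append(np.abs(I[pairs.i_idx] - I[pairs.j_idx]))
    return np.column_stack(cols)


def _weighted_nnls(X: np.ndarray, z: np.ndarray, w: np.ndarray) -> np.ndarray:
    """argmin_{beta >= 0} || sqrt(w) (X beta - z) ||^2.

    Solved through the normal equations: with G = X'WX = LL', the
    objective equals ||L' beta - L^{-1} X'Wz||^2 up to a constant, so a
    k x k NNLS suffices regardless of the number of pairs.  Falls back
    to NNLS on the full weighted matrix if G is (near-)singular, e.g.
    with duplicated predictors.
    """
    Xw = X * w[:, None]
    G = Xw.T @ X
    b = Xw.T @ z
    try:
        L = np.linalg.cholesky(G + 1e-12 * np.trace(G) / G.shape[0] * np.eye(G.shape[0]))
        c = np.linalg.solve(L, b)
        beta, _ = nnls(L.T, c)
    except np.linalg.LinAlgError:
        sw = np.sqrt(w)
        beta, _ = nnls(X * sw[:, None], z * sw)
    return beta


def _irls_nnls(
    X: np.ndarray, d: np.ndarray, w: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, int, list[float]]:
    """Deviance-minimizing non-negative fit under mu = 1 - exp(-eta)."""
    mu = np.clip(0.5 * (d + d.mean()), 0.02, 0.98)
    eta = -np.log1p(-mu)
    beta = np.zeros(X.shape[1])
    dev = gdm_deviance(d, mu, w)
    trace = [dev]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        one_minus_mu = np.clip(1.0 - mu, _MU_EPS, 1.0)
        mu_c = np.clip(mu, _MU_EPS, 1.0)
        # dmu/deta = exp(-eta) = 1 - mu; binomial variance mu(1-mu)
        w_irls = w * one_minus_mu / mu_c
        z = eta + (d - mu) / one_minus_mu
        beta_new = _weighted_nnls(X, z, np.maximum(w_irls, 0.0))
        eta_new = X @ beta_new
        mu_new = -np.expm1(-eta_new)
        dev_new = gdm_deviance(d, mu_new, w)
        # step-halving toward the previous coefficients if deviance worsens
        step = 1.0
        while dev_new > dev + 1e-12 and step > 1e-6:
            step *= 0.5
            beta_try = beta + step * (beta_new - beta)
            eta_try = X @ beta_try
            mu_try = -np.expm1(-eta_try)
            dev_try = gdm_deviance(d, mu_try, w)
            if dev_try <= dev_new:
                beta_new, eta_new, mu_new, dev_new = beta_try, eta_try, mu_try, dev_try
        dev_new = max(dev_new, 0.0)  # roundoff can dip a perfect fit below zero
        # relative change, with the scale floored so a deviance collapsing
        # to ~0 (perfect fit) still registers as converged
        scale = max(dev_new, 1e-6 * trace[0], 1e-300)
        rel = abs(dev - dev_new) / scale
        beta, eta, mu, dev = beta_new, eta_new, mu_new, dev_new
        trace.append(dev)
        if rel < tol:
            converged = True
            break
    return beta, dev, converged, it, trace


def fit_gdm(
    pairs: SitePairTable,
    n_splines: int = 3,
    max_iter: int = 500,
    tol: float = 1e-8,
    basis: ISplineBasis | None = None,
) -> GDMModel:
    """Fit a GDM to a site-pair table.

    Knots default to the 0/50/100 percentiles of each predictor's site
    values.  Observed d == 1 is nudged to 1 - 1e-9 so the log terms stay
    finite.  Raises on non-convergence, with the deviance trace in the
    message.
    """
    d = np.asarray(pairs.d, dtype=float)
    if (d < 0).any() or (d > 1).any():
        raise ValueError("dissimilarities must lie in [0, 1]")
    d = np.minimum(d, 1.0 - _D_EPS)
    w = np.asarray(pairs.w, dtype=float)
    if basis is None:
        basis = ISplineBasis.from_site_values(pairs.site_values, n_splines=n_splines)
    X = _design_matrix(pairs, basis)
    beta, dev, converged, n_iter, trace = _irls_nnls(X, d, w, max_iter, tol)
    if not converged:
        raise RuntimeError(
            f"GDM fit did not converge in {max_iter} iterations; deviance trace tail: "
            f"{[f'{v:.6g}' for v in trace[-5:]]}"
        )
    # null model: intercept only, same link and weights
    beta0, null_dev, null_conv, _, _ = _irls_nnls(
        np.ones((d.size, 1)), d, w, max_iter, tol
    )
    names = pairs.predictor_names
    K = basis.n_splines
    coefs = {p: beta[1 + k * K : 1 + (k + 1) * K].copy() for k, p in enumerate(names)}
    return GDMModel(
        basis=basis,
        intercept=float(beta[0]),
        coefficients=coefs,
        null_deviance=float(null_dev),
        model_deviance=float(dev),
        converged=converged and null_conv,
        n_iter=n_iter,
        predictor_names=names,
    )


def predict_dissimilarity(model: GDMModel, pairs: SitePairTable) -> np.ndarray:
    """Predicted dissimilarity mu in [0, 1) for the pairs under the model."""
    for p in pairs.predictor_names:
        if p not in model.coefficients:
            raise KeyError(f"unseen predictor {p!r}")
    X = _design_matrix(pairs, model.basis)
    beta = model.coefficient_vector()
    return -np.expm1(-(X @ beta))


# ---------------------------------------------------------------------
# Predictor significance


@dataclass
class PredictorSummary:
    """Permutation importance/significance per predictor."""

    table: pd.DataFrame  # predictor, importance, p, keep
    n_perm: int
    alpha: float
    observed_pct_deviance: float

    def kept(self) -> list[str]:
        return self.table.loc[self.table["keep"], "predictor"].tolist()


def predictor_significance(
    pairs: SitePairTable,
    n_splines: int = 3,
    n_perm: int = 100,
    seed=None,
    alpha: float = 0.05,
    model: GDMModel | None = None,
) -> PredictorSummary:
    """Permutation test of each predictor's contribution to the GDM.

    For each predictor, its site values are permuted across sites
    (response and other predictors fixed), the pairs rebuilt and the
    model refitted; p = (1 + #{permuted %deviance >= observed}) /
    (n_perm + 1).  Importance is the predictor's coefficient sum.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if model is None:
        model = fit_gdm(pairs, n_splines=n_splines)
    obs = model.pct_deviance_explained
    importance = model.importance()
    rows = []
    for p in pairs.predictor_names:
        count = 0
        for _ in range(n_perm):
            perm_pairs = pairs.with_permuted_predictor(p, rng)
            try:
                perm_model = fit_gdm(perm_pairs, n_splines=n_splines)
            except RuntimeError:
                continue  # treat a failed refit as not exceeding observed
            if perm_model.pct_deviance_explained >= obs:
                count += 1
        pval = (1 + count) / (n_perm + 1)
        rows.append(
            {"predictor": p, "importance": importance[p], "p": pval, "keep": pval <= alpha}
        )
    return PredictorSummary(
        table=pd.DataFrame(rows), n_perm=n_perm, alpha=alpha, observed_pct_deviance=obs
    )


# ---------------------------------------------------------------------
# Biological-space transform and RGB beta-diversity map


def transform_env(
    model: GDMModel, env_stack: dict[str, RasterGrid], predictors: list[str] | None = None
) -> dict[str, RasterGrid]:
    """Transform rasters to biological space: f_p(x) = sum_k beta_pk I_pk(x).

    Each output pixel is the partial ecological distance from the bottom
    of the predictor's gradient, bounded by [0, importance_p].  Nodata
    propagates.
    """
    predictors = predictors if predictors is not None else model.predictor_names
    out = {}
    for p in predictors:
        if p not in model.coefficients:
            raise KeyError(f"model has no predictor {p!r}")
        if p not in env_stack:
            raise KeyError(f"missing raster for kept predictor {p!r}")
        grid = env_stack[p]
        valid = grid.valid_mask()
        vals = np.asarray(grid.values, dtype=float)
        flat = model.basis.evaluate(p, vals.ravel()) @ model.coefficients[p]
        f = flat.reshape(vals.shape)
        f = np.where(valid, f, np.nan)
        out[p] = RasterGrid(f, grid.transform, nodata=np.nan, crs_tag=grid.crs_tag)
    return out


def beta_map(transformed: dict[str, RasterGrid], seed=None):
    """Reduce transformed layers to an RGB beta-diversity map via PCA.

    PCA runs over valid pixels of the centered transformed stack; the
    first three components are min-max scaled to [0, 255] and assigned
    to red, green and blue.  Component signs are fixed so each loading
    vector's largest-magnitude entry is positive, making the colors
    reproducible.  Returns ``(rgb, valid_mask, transform)`` where rgb is
    a (rows, cols, 3) uint8 array (invalid pixels are zero/black).
    """
    from sklearn.decomposition import PCA

    if not transformed:
        raise ValueError("no transformed layers")
    grids = list(transformed.values())
    ref = grids[0]
    layers = [np.asarray(g.values, dtype=float) for g in grids]
    if len(layers) < 3:
        warnings.warn("fewer than 3 transformed layers; padding with zero layers")
        while len(layers) < 3:
            layers.append(np.zeros_like(layers[0]))
    stack = np.stack(layers, axis=-1)  # (rows, cols, L)
    valid = np.all(np.isfinite(stack), axis=-1)
    if valid.sum() < 1:
        raise ValueError("no valid pixels")
    Xv = stack[valid]
    n_comp = min(3, Xv.shape[1], max(1, Xv.shape[0] - 1))
    pca = PCA(n_components=n_comp, random_state=0)
    scores = pca.fit_transform(Xv - Xv.mean(axis=0))
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_comp):
        j = int(np.argmax(np.abs(pca.components_[k])))
        if pca.components_[k, j] < 0:
            scores[:, k] = -scores[:, k]
    if n_comp < 3:
        scores = np.column_stack([scores, np.zeros((scores.shape[0], 3 - n_comp))])
    rgb = np.zeros((*valid.shape, 3), dtype=np.uint8)
    for k in range(3):
        s = scores[:, k]
        rng_s = s.max() - s.min()
        chan = np.zeros_like(s) if rng_s == 0 else (s - s.min()) / rng_s * 255.0
        rgb[valid, k] = np.round(chan).astype(np.uint8)
    return rgb, valid, ref.transform
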