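"""Estimation of the technical taxa-accumulation trend f_t(g, log y).

In 16S surveys the number of detected sub-genus taxa for a genus grows
with the genus's recovered abundance, largely because amplification and
sequencing errors spawn spurious read clusters at a rate that increases
with the source's read count.  The within-genus accumulation data — the
pairs (log y_gj, log n_gj) over detected (genus, sample) cells — therefore
carry a predominantly *technical* signal, which we summarise as

    z_gj = log n_gj = kappa + f_R(log y_gj) + f_G(g) + eps_gj,
    eps_gj ~ N(0, sigma^2),

with f_R a smooth abundance-dependent curve (cubic smoothing spline,
roughness-penalised by the integrated squared second derivative, smoothing
parameter chosen by generalized cross-validation) and f_G unpenalised
per-genus offsets under a sum-to-zero constraint.  Genus effects are
Wald-tested and Benjamini-Hochberg filtered: only significant effects are
retained in the fitted control

    f_t_hat(g, log y) = kappa + f_R_hat(log y) + f_G_hat(g) * retained(g).

A loess alternative pools all cells into a single smooth (no genus
effects); both strategies expose the same :class:`TrendFit` evaluation
surface for downstream regressions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.stats import norm
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .data_model import GenusAggregate

logger = logging.getLogger("richtrend")

_DEGREE = 3  # cubic


@dataclass
class TrendFit:
    """Fitted technical control, evaluable at arbitrary (genus, log y).

    For the spline method, ``spline_coef`` holds coefficients on the
    constrained basis B(x) @ Z (Z removes the constant direction so the
    intercept kappa is identified); ``genus_effects`` is a per-genus table
    with Wald statistics, BH-adjusted p-values and the retained flag.  For
    the loess method the curve is stored as an interpolation grid and
    ``genus_effects`` is empty.
    """

    method: str
    kappa: float
    logy_range: tuple[float, float]
    genus_effects: pd.DataFrame
    lambda_: float = np.nan
    sigma2: float = np.nan
    gcv: float = np.nan
    n_points: int = 0
    edf: float = np.nan
    alpha_G: float = 0.05
    # spline pieces
    knots: np.ndarray | None = None
    spline_coef: np.ndarray | None = None
    constraint: np.ndarray | None = None
    # loess pieces
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None

    # -- evaluation ---------------------------------------------------------

    def f_R(self, log_y) -> np.ndarray:
        """The abundance-dependent smooth alone, clamped to the fitted range."""
        x = np.atleast_1d(np.asarray(log_y, dtype=float))
        if np.isnan(x).any():
            raise ValueError("NaN log-abundance passed to trend evaluation")
        x = np.clip(x, self.logy_range[0], self.logy_range[1])
        if self.method == "spline":
            B = BSpline.design_matrix(x, self.knots, _DEGREE).toarray()
            return B @ (self.constraint @ self.spline_coef)
        return np.interp(x, self.grid_x, self.grid_y) - self.kappa

    def retained_effects(self) -> dict:
        """Mapping genus -> retained effect (non-retained genera absent)."""
        cache = getattr(self, "_eff_cache", None)
        if cache is None:
            ge = self.genus_effects
            cache = {} if ge.empty else {
                g: float(e) for g, e, kept in zip(ge.index, ge["estimate"], ge["retained"])
                if bool(kept)}
            object.__setattr__(self, "_eff_cache", cache)
        return cache

    def genus_effect(self, genus) -> float:
        """Retained genus offset; 0 for unseen or non-retained genera."""
        if genus is None:
            return 0.0
        return self.retained_effects().get(genus, 0.0)

    def evaluate(self, genus, log_y):
        """f_t_hat(g, log y) = kappa + f_R(log y) + retained genus effect."""
        val = self.kappa + self.f_R(log_y) + self.genus_effect(genus)
        return val if np.ndim(log_y) else float(val[0])

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "method": self.method,
            "kappa": self.kappa,
            "logy_range": list(self.logy_range),
            "lambda": None if np.isnan(self.lambda_) else self.lambda_,
            "sigma2": None if np.isnan(self.sigma2) else self.sigma2,
            "gcv": None if np.isnan(self.gcv) else self.gcv,
            "n_points": self.n_points,
            "edf": None if np.isnan(self.edf) else self.edf,
            "alpha_G": self.alpha_G,
            "knots": None if self.knots is None else list(self.knots),
            "spline_coef": None if self.spline_coef is None else list(self.spline_coef),
            "constraint": None if self.constraint is None else [list(r) for r in self.constraint],
            "grid_x": None if self.grid_x is None else list(self.grid_x),
            "grid_y": None if self.grid_y is None else list(self.grid_y),
            "genus_effects": self.genus_effects.reset_index().to_dict(orient="list"),
        }
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TrendFit":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        ge = pd.DataFrame(doc["genus_effects"])
        ge = ge.set_index("genus") if "genus" in ge.columns else _empty_genus_table()
        arr = lambda v: None if v is None else np.asarray(v, dtype=float)
        return cls(
            method=doc["method"], kappa=doc["kappa"],
            logy_range=tuple(doc["logy_range"]), genus_effects=ge,
            lambda_=np.nan if doc["lambda"] is None else doc["lambda"],
            sigma2=np.nan if doc["sigma2"] is None else doc["sigma2"],
            gcv=np.nan if doc["gcv"] is None else doc["gcv"],
            n_points=doc["n_points"],
            edf=np.nan if doc["edf"] is None else doc["edf"],
            alpha_G=doc["alpha_G"],
            knots=arr(doc["knots"]), spline_coef=arr(doc["spline_coef"]),
            constraint=arr(doc["constraint"]),
            grid_x=arr(doc["grid_x"]), grid_y=arr(doc["grid_y"]),
        )

    def genus_effects_tsv(self, path) -> None:
        self.genus_effects.to_csv(path, sep="\t", index_label="genus")


def _empty_genus_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["estimate", "se", "z", "p", "p_bh", "retained"],
    ).rename_axis("genus")


# ---------------------------------------------------------------------------
# spline machinery


def _knot_vector(x: np.ndarray, max_interior: int = 30) -> np.ndarray:
    """Cubic-spline knot vector with interior knots at quantiles of x."""
    lo, hi = float(x.min()), float(x.max())
    n_unique = np.unique(x).size
    n_int = int(min(max_interior, max(2, n_unique // 4)))
    qs = np.linspace(0, 1, n_int + 2)[1:-1]
    interior = np.unique(np.quantile(x, qs))
    interior = interior[(interior > lo) & (interior < hi)]
    return np.r_[[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)]


def _penalty_matrix(knots: np.ndarray) -> np.ndarray:
    """Integral of products of second derivatives of the cubic B-spline basis.

    The second derivative of a cubic B-spline is piecewise linear, so the
    integrand on each knot span is quadratic and Simpson's rule is exact.
    Cached on the knot vector (bootstrap refits reuse the original knots).
    """
    return _penalty_matrix_cached(tuple(float(t) for t in knots))


@lru_cache(maxsize=64)
def _penalty_matrix_cached(knots_key: tuple) -> np.ndarray:
    knots = np.asarray(knots_key)
    K = len(knots) - _DEGREE - 1
    spans = np.unique(knots)
    P = np.zeros((K, K))
    eye = np.eye(K)
    d2 = [BSpline(knots, eye[k], _DEGREE).derivative(2) for k in range(K)]
    for a, b in zip(spans[:-1], spans[1:]):
        pts = np.array([a, (a + b) / 2.0, b])
        # evaluate just inside the span to dodge breakpoint discontinuities
        eps = (b - a) * 1e-9
        pts_in = np.clip(pts, a + eps, b - eps)
        D = np.column_stack([f(pts_in) for f in d2])  # 3 x K
        w = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
        P += D.T @ (w[:, None] * D)
    return P


def _trend_design(agg: GenusAggregate):
    """Extract detected cells (n >= 1): z = log n, x = log y, genus labels."""
    n = agg.n.to_numpy(dtype=float)
    y = agg.y.to_numpy(dtype=float)
    g_idx, s_idx = np.nonzero(n >= 1)
    z = np.log(n[g_idx, s_idx])
    x = np.log(y[g_idx, s_idx])
    genera = np.asarray(agg.group_ids, dtype=object)[g_idx]
    return z, x, genera


def fit_trend_spline(agg: GenusAggregate, min_points_per_genus: int = 3,
                     alpha_G: float = 0.05, max_interior_knots: int = 30,
                     n_lambda: int = 40,
                     lambda_: float | None = None,
                     knots: np.ndarray | None = None) -> TrendFit:
    """Penalized smoothing-spline fit of the within-genus accumulation trend.

    Only detected cells (n_gj >= 1) enter, with response z = log n_gj.  The
    smoothing parameter is chosen by GCV on a 40-point log-spaced grid
    (ties broken toward the smoother fit) unless ``lambda_`` is given
    (used e.g. when re-fitting on bootstrap resamples).  Genera with fewer
    than ``min_points_per_genus`` cells contribute to f_R but receive no
    genus effect.
    """
    z, x, genera = _trend_design(agg)
    n_obs = z.size
    if n_obs < 10 or np.unique(x).size < 10:
        raise ValueError(
            f"trend fitting needs >= 10 detected cells with >= 10 distinct "
            f"log-abundance values; got {n_obs} cells, {np.unique(x).size} distinct"
        )
    if knots is None:
        knots = _knot_vector(x, max_interior_knots)
    K = len(knots) - _DEGREE - 1
    xc = np.clip(x, knots[0], knots[-1])
    B = BSpline.design_matrix(xc, knots, _DEGREE).toarray()
    # remove the constant direction from the basis so kappa is identified:
    # constrain the fitted smooth to have zero mean over the data
    c = B.mean(axis=0, keepdims=True)
    Z = null_space(c)  # K x (K-1)
    BZ = B @ Z
    P_s = Z.T @ _penalty_matrix(knots) @ Z

    # genus effect block: sum-to-zero (effect) coding over eligible genera
    counts = pd.Series(genera).value_counts()
    eligible = sorted(counts.index[counts >= min_points_per_genus])
    m = len(eligible)
    if m >= 2:
        pos = {g: i for i, g in enumerate(eligible)}
        Gm = np.zeros((n_obs, m - 1))
        for row, g in enumerate(genera):
            i = pos.get(g)
            if i is None:
                continue
            if i < m - 1:
                Gm[row, i] = 1.0
            else:
                Gm[row, :] = -1.0
    else:
        Gm = np.zeros((n_obs, 0))
        eligible, m = [], 0

    X = np.column_stack([np.ones(n_obs), BZ, Gm])
    p = X.shape[1]
    P = np.zeros((p, p))
    sl = slice(1, 1 + K - 1)
    P[sl, sl] = P_s

    XtX = X.T @ X
    Xtz = X.T @ z
    if m >= 2:
        gcols = XtX[1 + K - 1:, 1 + K - 1:]
        if np.linalg.matrix_rank(gcols) < gcols.shape[0]:
            warnings.warn("genus design is collinear; genus effects may be unstable")

    if lambda_ is None:
        scale = np.trace(XtX[sl, sl]) / max(np.trace(P_s), 1e-300)
        grid = scale * np.logspace(-4, 4, n_lambda)
        best = None
        for lam in grid[::-1]:  # largest first: ties go to the smoother fit
            beta, rss, tr = _pls_solve(XtX, Xtz, P, lam, X, z)
            gcv = n_obs * rss / max(n_obs - tr, 1e-10) ** 2
            if best is None or gcv < best[0] - 1e-12:
                best = (gcv, lam, beta, rss, tr)
        gcv, lam, beta, rss, tr = best
    else:
        lam = float(lambda_)
        beta, rss, tr = _pls_solve(XtX, Xtz, P, lam, X, z)
        gcv = n_obs * rss / max(n_obs - tr, 1e-10) ** 2

    sigma2 = rss / max(n_obs - tr, 1e-10)
    A = XtX + lam * P
    Ainv = np.linalg.inv(A)
    cov = sigma2 * (Ainv @ XtX @ Ainv)  # sandwich, lambda treated as fixed

    # genus effect table (all eligible genera, incl. the implicit last one)
    ge = _empty_genus_table()
    if m >= 2:
        gsl = slice(1 + K - 1, p)
        est = np.empty(m)
        se = np.empty(m)
        est[: m - 1] = beta[gsl]
        covg = cov[gsl, gsl]
        se[: m - 1] = np.sqrt(np.clip(np.diag(covg), 0, None))
        est[m - 1] = -est[: m - 1].sum()
        se[m - 1] = np.sqrt(max(np.ones(m - 1) @ covg @ np.ones(m - 1), 0))
        zstat = est / np.where(se > 0, se, np.inf)
        praw = 2 * norm.sf(np.abs(zstat))
        _, pbh, _, _ = multipletests(praw, method="fdr_bh")
        retained = pbh <= alpha_G
        ge = pd.DataFrame(
            {"estimate": est, "se": se, "z": zstat, "p": praw,
             "p_bh": pbh, "retained": retained},
            index=pd.Index(eligible, name="genus"),
        )

    return TrendFit(
        method="spline", kappa=float(beta[0]),
        logy_range=(float(x.min()), float(x.max())),
        genus_effects=ge, lambda_=float(lam), sigma2=float(sigma2),
        gcv=float(gcv), n_points=int(n_obs), edf=float(tr), alpha_G=alpha_G,
        knots=np.asarray(knots, dtype=float),
        spline_coef=np.asarray(beta[sl], dtype=float),
        constraint=np.asarray(Z, dtype=float),
    )


def _pls_solve(XtX, Xtz, P, lam, X, z):
    A = XtX + lam * P
    beta = np.linalg.solve(A, Xtz)
    resid = z - X @ beta
    rss = float(resid @ resid)
    tr = float(np.trace(np.linalg.solve(A, XtX)))
    return beta, rss, tr


def fit_trend_loess(agg: GenusAggregate, span: float = 0.75) -> TrendFit:
    """Pooled loess smooth of z = log n on log y (no genus effects).

    Evaluation interpolates the fitted curve and clamps outside the
    observed log-abundance range (constant extrapolation).
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    z, x, _ = _trend_design(agg)
    if z.size < 10:
        raise ValueError(f"loess trend fitting needs >= 10 detected cells; got {z.size}")
    fitted = lowess(z, x, frac=span, return_sorted=True)
    gx, gy = fitted[:, 0], fitted[:, 1]
    # collapse duplicate abscissae for interpolation
    ux, inv = np.unique(gx, return_inverse=True)
    uy = np.zeros_like(ux)
    cnt = np.zeros_like(ux)
    np.add.at(uy, inv, gy)
    np.add.at(cnt, inv, 1.0)
    uy /= cnt
    kappa = float(np.mean(uy))
    return TrendFit(
        method="loess", kappa=kappa,
        logy_range=(float(x.min()), float(x.max())),
        genus_effects=_empty_genus_table(), n_points=int(z.size),
        grid_x=ux, grid_y=uy,
    )


def evaluate_trend(fit: TrendFit, genus, log_y):
    """f_t_hat(g, log y); genus effect 0 for unseen / non-retained genera."""
    return fit.evaluate(genus, log_y)
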