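"""Differential richness regressions with the fitted technical control.

Three log-link count regressions share one idea: include a transform of
the fitted technical trend f_t_hat as a covariate, so that abundance-driven
spurious-taxa accumulation is absorbed before group contrasts are read off.

genus-specific     log E[n_gj]  = X_j' mu_g + nu_g * f_t_hat(g, log y_gj)
sample-wide        log E[n_+j]  = X_j' zeta + gamma * log sum_{g det.} exp(f_t_hat)
genus collection   log E[n_kj]  = X_j' psi_k + gamma_k * log sum_{g in k det.} exp(f_t_hat)

Variance functions: Poisson for the genus model, negative binomial (NB2,
dispersion profiled by maximum likelihood) for the sample-wide and
collection models, following the continuous-Poisson-mixture view of
sample-wide accumulations.  Fitting is iteratively reweighted least
squares; Wald inference per coefficient.  Bootstrap-t intervals re-fit the
trend and the GLM on stratified sample resamples.  An inverse-variance
weighted regression is provided for running the same contrasts on
asymptotic richness estimates (Chao1/ACE) with their standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm

from .data_model import DesignMatrix, GenusAggregate
from .trend import TrendFit, fit_trend_spline, fit_trend_loess

logger = logging.getLogger("richtrend")

_Z975 = norm.ppf(0.975)


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# IRLS engine (log link; Poisson or NB2 variance)


def poisson_loglik(y, mu):
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def nb2_loglik(y, mu, alpha):
    if alpha <= 0:
        return poisson_loglik(y, mu)
    r = 1.0 / alpha
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


def irls_fit(y, X, offset=None, family: str = "poisson", alpha: float = 0.0,
             tol: float = 1e-8, maxiter: int = 50):
    """Log-link IRLS for Poisson / NB2(alpha fixed) regression.

    Returns dict with beta, cov (inverse expected information), mu,
    loglik, deviance, converged, n_iter.  Convergence is on the relative
    deviance change (typically well under ten iterations).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if n < p:
        raise FitError(f"{n} observations for {p} coefficients")
    mu = np.clip(y, 0.5, None)
    eta = np.log(mu) - off
    beta = None
    dev_old = np.inf
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        mu = np.exp(eta + off)
        mu = np.clip(mu, 1e-300, 1e300)
        if family == "poisson":
            w = mu
        else:
            w = mu / (1.0 + alpha * mu)
        zw = eta + (y - mu) / mu
        WX = X * w[:, None]
        A = X.T @ WX
        try:
            beta = np.linalg.solve(A, WX.T @ zw)
        except np.linalg.LinAlgError as exc:
            raise FitError("singular weighted design (separation or rank deficiency)") from exc
        eta = X @ beta
        mu = np.exp(np.clip(eta + off, -700, 700))
        dev = -2.0 * (nb2_loglik(y, mu, alpha) if family != "poisson"
                      else poisson_loglik(y, np.clip(mu, 1e-300, None)))
        if np.isfinite(dev) and abs(dev_old - dev) <= tol * (abs(dev) + 0.1):
            converged = True
            dev_old = dev
            break
        dev_old = dev
    mu = np.exp(np.clip(X @ beta + off, -700, 700))
    w = mu if family == "poisson" else mu / (1.0 + alpha * mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information matrix") from exc
    ll = poisson_loglik(y, np.clip(mu, 1e-300, None)) if family == "poisson" \
        else nb2_loglik(y, mu, alpha)
    return {"beta": beta, "cov": cov, "mu": mu, "loglik": ll,
            "deviance": dev_old, "converged": converged, "n_iter": it}


def fit_nb(y, X, offset=None, alpha_min: float = 1e-8, alpha_max: float = 10.0,
           tol: float = 1e-8, maxiter: int = 50):
    """NB2 regression with dispersion profiled by maximum likelihood.

    Starts from a Poisson fit and a method-of-moments dispersion estimate;
    falls back to Poisson when the profiled dispersion hits the lower
    boundary (data not overdispersed).
    """
    y = np.asarray(y, dtype=float)
    pois = irls_fit(y, X, offset=offset, family="poisson", tol=tol, maxiter=maxiter)
    mu = pois["mu"]
    n, p = np.asarray(X).shape
    mom = float(np.sum(((y - mu) ** 2 - mu) / mu**2) / max(n - p, 1))
    if mom <= alpha_min:
        out = dict(pois)
        out["alpha"] = 0.0
        out["family"] = "poisson"
        logger.debug("dispersion at boundary; Poisson fallback")
        return out

    def negprof(log_a):
        a = np.exp(log_a)
        try:
            fit = irls_fit(y, X, offset=offset, family="nb", alpha=a,
                           tol=tol, maxiter=maxiter)
        except FitError:
            return np.inf
        return -fit["loglik"]

    res = minimize_scalar(negprof, bounds=(np.log(alpha_min), np.log(alpha_max)),
                          method="bounded", options={"xatol": 1e-4})
    a_hat = float(np.exp(res.x))
    if a_hat <= alpha_min * 1.5:
        out = dict(pois)
        out["alpha"] = 0.0
        out["family"] = "poisson"
        return out
    fit = irls_fit(y, X, offset=offset, family="nb", alpha=a_hat,
                   tol=tol, maxiter=maxiter)
    fit["alpha"] = a_hat
    fit["family"] = "nb"
    return fit


# ---------------------------------------------------------------------------
# result container


@dataclass
class DifferentialRichnessResult:
    """Per-term Wald table plus model metadata for one richness regression."""

    kind: str                      # genus_richness | samplewide_richness | collection_richness | meta_regression
    terms: pd.DataFrame            # index term: estimate, se, z, p, ci_low, ci_high
    dispersion: float = 0.0
    variance_function: str = "poisson"
    converged: bool = True
    n_obs: int = 0
    trend_coef: float = np.nan     # nu_g / gamma / gamma_k
    status: str = "ok"
    n_dropped: int = 0
    genus: str | None = None

    def coef(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.copy()
        out["dispersion"] = self.dispersion
        out["n"] = self.n_obs
        out["status"] = self.status
        return out


def _wald_table(beta, cov, names) -> pd.DataFrame:
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = beta / np.where(se > 0, se, np.inf)
    p = 2 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": p,
         "ci_low": beta - _Z975 * se, "ci_high": beta + _Z975 * se},
        index=pd.Index(names, name="term"),
    )


# ---------------------------------------------------------------------------
# the three models


def trend_covariate_vif(ft: np.ndarray, Xs: np.ndarray) -> float:
    """Variance inflation factor of the trend covariate against the design."""
    var = float(np.var(ft))
    if var <= 0:
        return np.inf
    coef, *_ = np.linalg.lstsq(Xs, ft, rcond=None)
    r2 = 1.0 - float(np.var(ft - Xs @ coef)) / var
    return 1.0 / max(1.0 - r2, 1e-12)


def genus_differential_richness(agg: GenusAggregate, trend: TrendFit,
                                X: DesignMatrix, genus, min_nonzero: int = 5,
                                nu_mode: str = "auto", vif_threshold: float = 10.0,
                                include_genus_effect: bool = True,
                                variance_function: str = "poisson") -> DifferentialRichnessResult:
    """Genus-specific model: Poisson GLM of n_gj on X plus nu_g * f_t_hat.

    Only samples where the genus is detected (y_gj > 0) enter; the trend
    covariate is f_t_hat evaluated with the genus's retained effect (set
    ``include_genus_effect=False`` to use kappa + f_R only).

    ``nu_mode`` controls the trend coefficient nu_g: ``'free'`` estimates
    it, ``'offset'`` pins it to 1, and ``'auto'`` (default) estimates it
    unless the trend covariate is nearly collinear with the design (VIF
    above ``vif_threshold``, the textbook collinearity rule of thumb), in
    which case nu_g is pinned to 1 — the regime empirically observed when
    abundance alone drives accumulation.  Without within-group abundance
    spread a free nu_g is unidentified and would make the group contrast
    arbitrarily noisy.
    """
    if genus not in agg.n.index:
        raise KeyError(f"unknown genus {genus!r}")
    if nu_mode not in {"auto", "free", "offset"}:
        raise ValueError(f"unknown nu_mode {nu_mode!r}")
    yv = agg.y.loc[genus]
    det = yv.index[yv > 0]
    if len(det) < min_nonzero:
        return DifferentialRichnessResult(
            kind="genus_richness", terms=_wald_table(np.array([]), np.zeros((0, 0)), []),
            status=f"insufficient detection ({len(det)} < {min_nonzero})",
            converged=False, genus=genus)
    X.check_full_rank(det)
    Xs = X.values_for(det)
    ft = trend.evaluate(genus if include_genus_effect else None,
                        np.log(yv[det].to_numpy(dtype=float)))
    nv = agg.n.loc[genus, det].to_numpy(dtype=float)
    names = list(X.columns)
    offset_mode = nu_mode == "offset" or (
        nu_mode == "auto" and trend_covariate_vif(ft, Xs) > vif_threshold)
    try:
        if offset_mode:
            fit = (irls_fit(nv, Xs, offset=ft) if variance_function == "poisson"
                   else fit_nb(nv, Xs, offset=ft))
        else:
            Xa = np.column_stack([Xs, ft])
            names = names + ["trend"]
            fit = (irls_fit(nv, Xa) if variance_function == "poisson"
                   else fit_nb(nv, Xa))
    except FitError as exc:
        return DifferentialRichnessResult(
            kind="genus_richness", terms=_wald_table(np.array([]), np.zeros((0, 0)), []),
            status=f"fit failed: {exc}", converged=False, genus=genus)
    terms = _wald_table(fit["beta"], fit["cov"], names)
    return DifferentialRichnessResult(
        kind="genus_richness", terms=terms,
        dispersion=float(fit.get("alpha", 0.0)),
        variance_function=fit.get("family", variance_function),
        converged=bool(fit["converged"]), n_obs=len(det),
        trend_coef=1.0 if offset_mode else float(terms.loc["trend", "estimate"]),
        status="ok" if fit["converged"] else "not converged", genus=genus)


def samplewide_trend_covariate(agg: GenusAggregate, trend: TrendFit,
                               genus_set=None) -> pd.Series:
    """Per-sample log sum over detected genera of exp(f_t_hat(g, log y_gj)).

    Samples where no genus in the set is detected get -inf (excluded by
    callers).
    """
    genera = list(agg.group_ids) if genus_set is None else list(genus_set)
    y = agg.y.loc[genera].to_numpy(dtype=float)
    gi, sj = np.nonzero(y > 0)
    total = np.zeros(y.shape[1])
    if gi.size:
        logy = np.log(y[gi, sj])
        eff = trend.retained_effects()
        offs = np.array([eff.get(genera[i], 0.0) for i in gi])
        vals = np.exp(trend.kappa + trend.f_R(logy) + offs)
        np.add.at(total, sj, vals)
    with np.errstate(divide="ignore"):
        return pd.Series(np.log(total), index=agg.sample_ids)


def _counts_per_level(X: DesignMatrix, sample_ids) -> pd.Series:
    rows = X.frame.loc[list(sample_ids)]
    return rows.groupby(list(rows.columns)).size()


def samplewide_differential_richness(agg: GenusAggregate, trend: TrendFit,
                                     X: DesignMatrix,
                                     variance_function: str = "negative_binomial",
                                     trend_mode: str = "auto",
                                     vif_threshold: float = 10.0) -> DifferentialRichnessResult:
    """Sample-wide model: NB GLM of n_+j on X plus gamma * log-sum-exp trend."""
    return collection_differential_richness(
        agg, trend, X, genus_set=None, variance_function=variance_function,
        trend_mode=trend_mode, vif_threshold=vif_threshold,
        kind="samplewide_richness")


def collection_differential_richness(agg: GenusAggregate, trend: TrendFit,
                                     X: DesignMatrix, genus_set=None,
                                     variance_function: str = "negative_binomial",
                                     trend_mode: str = "auto",
                                     vif_threshold: float = 10.0,
                                     kind: str = "collection_richness") -> DifferentialRichnessResult:
    """Collection model: NB GLM of n_kj = sum_{g in k} n_gj on X plus the
    collection-restricted log-sum-exp trend covariate.  With the full genus
    set this is exactly the sample-wide model.

    ``trend_mode`` handles the trend coefficient gamma_k exactly as
    ``nu_mode`` does in the genus model: free, pinned to 1 (offset), or
    chosen by the covariate's VIF against the design (default)."""
    genera = list(agg.group_ids) if genus_set is None else list(genus_set)
    if len(genera) == 0:
        raise ValueError("empty genus collection")
    unknown = [g for g in genera if g not in agg.n.index]
    if unknown:
        raise KeyError(f"unknown genera in collection: {unknown[:3]}")
    T = samplewide_trend_covariate(agg, trend, genus_set=genera)
    keep = np.isfinite(T.to_numpy())
    if not keep.any():
        raise FitError("collection never detected in any sample")
    samples = T.index[keep]
    per_level = _counts_per_level(X, samples)
    if (per_level < 2).any():
        logger.warning("some design cells have < 2 samples")
    X.check_full_rank(samples)
    Xs = X.values_for(samples)
    nk = agg.n.loc[genera, samples].sum(axis=0).to_numpy(dtype=float)
    Tv = T[samples].to_numpy()
    names = list(X.columns)
    if trend_mode not in {"auto", "free", "offset"}:
        raise ValueError(f"unknown trend_mode {trend_mode!r}")
    offset_mode = trend_mode == "offset" or (
        trend_mode == "auto" and trend_covariate_vif(Tv, Xs) > vif_threshold)
    try:
        if offset_mode:
            design, off = Xs, Tv
        else:
            design, off = np.column_stack([Xs, Tv]), None
            names = names + ["trend"]
        if variance_function == "negative_binomial":
            fit = fit_nb(nk, design, offset=off)
        else:
            fit = irls_fit(nk, design, offset=off)
            fit["alpha"], fit["family"] = 0.0, "poisson"
    except FitError as exc:
        return DifferentialRichnessResult(
            kind=kind, terms=_wald_table(np.array([]), np.zeros((0, 0)), []),
            status=f"fit failed: {exc}", converged=False)
    terms = _wald_table(fit["beta"], fit["cov"], names)
    return DifferentialRichnessResult(
        kind=kind, terms=terms, dispersion=float(fit.get("alpha", 0.0)),
        variance_function=fit.get("family", variance_function),
        converged=bool(fit["converged"]), n_obs=int(keep.sum()),
        trend_coef=1.0 if offset_mode else float(terms.loc["trend", "estimate"]),
        status="ok" if fit["converged"] else "not converged",
        n_dropped=int((~keep).sum()))


# ---------------------------------------------------------------------------
# bootstrap-t intervals


def bootstrap_t_ci(agg: GenusAggregate, X: DesignMatrix, B: int = 1000,
                   seed: int | None = None, genus_set=None, level: float = 0.95,
                   trend_method: str = "spline", trend_kwargs: dict | None = None,
                   interval: str = "symmetric",
                   max_fail_frac: float = 0.10) -> pd.DataFrame:
    """Bootstrap-t confidence intervals for the sample-wide / collection model.

    Samples are resampled with replacement, stratified by design cell (the
    unique rows of X), the trend is re-fitted on each resample (knots and
    smoothing parameter frozen at the original fit's values) and the GLM is
    re-fitted; the studentized pivot per resample uses the refit's Wald SE.
    The default ``interval='symmetric'`` uses the quantile of |t*| (better
    finite-sample coverage); ``'equal_tailed'`` uses the two one-sided
    pivot quantiles.  Fixed seeds give bit-identical intervals.
    """
    if interval not in {"symmetric", "equal_tailed"}:
        raise ValueError(f"unknown interval type {interval!r}")
    if B < 199:
        raise ValueError("bootstrap-t needs B >= 199")
    trend_kwargs = dict(trend_kwargs or {})
    rng = np.random.default_rng(seed)

    if trend_method == "spline":
        trend0 = fit_trend_spline(agg, **trend_kwargs)
        refit = lambda a: fit_trend_spline(a, lambda_=trend0.lambda_,
                                           knots=trend0.knots,
                                           **{k: v for k, v in trend_kwargs.items()
                                              if k not in {"lambda_", "knots"}})
    else:
        trend0 = fit_trend_loess(agg, **trend_kwargs)
        refit = lambda a: fit_trend_loess(a, **trend_kwargs)
    res0 = collection_differential_richness(agg, trend0, X, genus_set=genus_set)
    if res0.status != "ok":
        raise FitError(f"original fit failed: {res0.status}")

    cells = X.frame.loc[agg.sample_ids].groupby(list(X.frame.columns)).indices
    sample_arr = np.asarray(agg.sample_ids, dtype=object)
    for key, idx in cells.items():
        if len(idx) < 2:
            raise ValueError("bootstrap impossible: a design cell has a single sample")

    b_hat = res0.terms["estimate"].to_numpy()
    se_hat = res0.terms["se"].to_numpy()
    names = list(res0.terms.index)
    pivots = []
    failures = 0
    for _ in range(B):
        take = np.concatenate([rng.choice(idx, size=len(idx), replace=True)
                               for idx in cells.values()])
        ids = sample_arr[take]
        uniq = [f"{s}#bs{i}" for i, s in enumerate(ids)]
        sub = agg.subset_samples(ids)
        sub.n.columns = sub.y.columns = uniq
        sub.tau.index = uniq
        Xb = DesignMatrix(pd.DataFrame(
            X.frame.loc[ids].to_numpy()[:, 1:], index=uniq,
            columns=[c for c in X.columns if c != "Intercept"]))
        try:
            tb = refit(sub)
            rb = collection_differential_richness(sub, tb, Xb, genus_set=genus_set)
            if rb.status != "ok":
                raise FitError(rb.status)
        except (FitError, ValueError):
            failures += 1
            continue
        est = rb.terms["estimate"].to_numpy()
        se = rb.terms["se"].to_numpy()
        pivots.append((est - b_hat) / np.where(se > 0, se, np.inf))
    if failures > max_fail_frac * B:
        raise FitError(f"{failures}/{B} bootstrap resample fits failed")
    piv = np.asarray(pivots)
    if interval == "symmetric":
        q = np.quantile(np.abs(piv), level, axis=0)
        lo, hi = b_hat - q * se_hat, b_hat + q * se_hat
    else:
        a = (1.0 - level) / 2.0
        q_lo = np.quantile(piv, a, axis=0)
        q_hi = np.quantile(piv, 1.0 - a, axis=0)
        lo, hi = b_hat - q_hi * se_hat, b_hat - q_lo * se_hat
    return pd.DataFrame(
        {"estimate": b_hat,
         "ci_low": lo,
         "ci_high": hi,
         "n_fail": failures, "B": B},
        index=pd.Index(names, name="term"))


# ---------------------------------------------------------------------------
# inverse-variance weighted regression of asymptotic richness


def weighted_meta_regression(estimates, ses, X: DesignMatrix | np.ndarray,
                             log_scale: bool = True,
                             names=None) -> DifferentialRichnessResult:
    """Inverse-variance weighted regression of richness estimates on a design.

    With ``log_scale`` (default) the response is log(estimate) with
    delta-method SEs (se/estimate), putting coefficients on the same
    fold-change scale as the GLMs; zero or undefined estimates are dropped
    (count reported).  Weights are 1/SE^2; the coefficient covariance is
    (X'WX)^{-1} (variances treated as known).
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if isinstance(X, DesignMatrix):
        Xm = X.frame.to_numpy()
        names = list(X.columns)
    else:
        Xm = np.asarray(X, dtype=float)
        names = names or [f"x{j}" for j in range(Xm.shape[1])]
    ok = np.isfinite(est) & np.isfinite(se) & (se > 0)
    if log_scale:
        ok &= est > 0
    dropped = int((~ok).sum())
    if dropped:
        logger.debug("weighted_meta_regression dropped %d undefined cells", dropped)
    if not ok.any():
        raise FitError("all estimator cells undefined")
    yv = np.log(est[ok]) if log_scale else est[ok]
    sv = se[ok] / est[ok] if log_scale else se[ok]
    w = 1.0 / sv**2
    Xs = Xm[ok]
    A = Xs.T @ (Xs * w[:, None])
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular weighted design") from exc
    beta = cov @ (Xs.T @ (w * yv))
    terms = _wald_table(beta, cov, names)
    return DifferentialRichnessResult(
        kind="meta_regression", terms=terms, variance_function="gaussian",
        n_obs=int(ok.sum()), n_dropped=dropped)
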