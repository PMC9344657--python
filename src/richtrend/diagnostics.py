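"""Evidentiary diagnostics: confounding, model comparison, replicability.

Three questions about a survey (real or simulated):

* Do genus-level differential *richness* calls track differential
  *abundance* — the signature of abundance-driven spurious taxa leaking
  into richness comparisons?  (:func:`confounding_diagnostic`)
* How much of the variation in taxa accumulation does the technical trend
  alone explain, relative to a model that also knows the genus identity,
  sample depth and study design?  (:func:`accumulation_model_comparison`,
  McFadden pseudo-R^2 and AIC of nested NB regressions)
* How replicable are sub-genus taxa across samples?
  (:func:`replicability_summary`, per-genus fractions of low-prevalence
  member taxa)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, pearsonr, spearmanr

from .data_model import DesignMatrix, GenusAggregate, TaxaCountTable, TaxonomyMap
from .inference import (FitError, fit_nb, irls_fit, nb2_loglik,
                        samplewide_trend_covariate)
from .trend import TrendFit

logger = logging.getLogger("richtrend")


@dataclass
class ConfoundingReport:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n_pairs: int
    n_excluded: int
    method: str = "pearson"


@dataclass
class AccumulationModelComparison:
    label: str
    pseudo_r2: float
    aic: float
    loglik: float
    loglik_null: float
    n: int
    converged: bool = True


def differential_abundance_lfc(agg: GenusAggregate, X: DesignMatrix, genus,
                               min_nonzero: int = 5, term: str | None = None):
    """Genus differential-abundance LFC: NB GLM of y_gj on X with log tau offset.

    The depth offset puts the coefficient on the relative-abundance scale
    (natural log).  Returns (estimate, se) for ``term`` (default: the first
    non-intercept column), or (nan, nan) with a log message on failure or
    separation.
    """
    yv = agg.y.loc[genus]
    det = yv.index[yv > 0]
    if len(det) < min_nonzero:
        return np.nan, np.nan
    term = term or next(c for c in X.columns if c != "Intercept")
    # separation guard: genus entirely absent from a design level
    xcol = X.frame.loc[agg.sample_ids, term]
    for lev in np.unique(xcol):
        lev_samples = xcol.index[xcol == lev]
        if (yv[lev_samples] > 0).sum() == 0:
            logger.debug("genus %s absent from a design level; separation", genus)
            return np.nan, np.nan
    Xs = X.values_for(agg.sample_ids)
    yfull = yv.to_numpy(dtype=float)
    off = np.log(agg.tau[agg.sample_ids].to_numpy(dtype=float))
    try:
        fit = fit_nb(yfull, Xs, offset=off)
    except FitError:
        logger.debug("DA fit failed for genus %s", genus)
        return np.nan, np.nan
    k = list(X.columns).index(term)
    if not fit["converged"]:
        return np.nan, np.nan
    return float(fit["beta"][k]), float(np.sqrt(max(fit["cov"][k, k], 0.0)))


def differential_abundance_lfc_simple(agg: GenusAggregate, X: DesignMatrix, genus,
                                      term: str | None = None, pseudo: float = 0.5):
    """Sensitivity alternative: log ratio of group-mean relative abundances
    with a pseudo-count; SE by the delta method over sample means."""
    term = term or next(c for c in X.columns if c != "Intercept")
    xcol = X.frame.loc[agg.sample_ids, term].to_numpy()
    rel = (agg.y.loc[genus].to_numpy(dtype=float) + pseudo) / agg.tau.to_numpy(dtype=float)
    a, b = rel[xcol == 0], rel[xcol != 0]
    est = float(np.log(b.mean()) - np.log(a.mean()))
    se = float(np.sqrt(b.var(ddof=1) / (len(b) * b.mean() ** 2)
                       + a.var(ddof=1) / (len(a) * a.mean() ** 2)))
    return est, se


def confounding_diagnostic(dr_lfc, da_lfc, method: str = "pearson") -> ConfoundingReport:
    """Correlation between matched differential-richness and differential-
    abundance coefficients, with a Fisher-z CI and two-sided p.

    A strong positive correlation indicates the richness calls are driven
    by abundance changes (confounding); near zero indicates the control
    worked.
    """
    a = np.asarray(dr_lfc, dtype=float)
    b = np.asarray(da_lfc, dtype=float)
    if a.size != b.size:
        raise ValueError("DR and DA vectors must be matched")
    ok = np.isfinite(a) & np.isfinite(b)
    excl = int((~ok).sum())
    a, b = a[ok], b[ok]
    if a.size < 10:
        raise ValueError(f"need >= 10 matched genera, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in DR or DA coefficients")
    if method == "pearson":
        r, p = pearsonr(a, b)
    elif method == "spearman":
        r, p = spearmanr(a, b)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    hw = norm.ppf(0.975) / np.sqrt(a.size - 3)
    return ConfoundingReport(r=float(r), ci_low=float(np.tanh(z - hw)),
                             ci_high=float(np.tanh(z + hw)), p=float(p),
                             n_pairs=int(a.size), n_excluded=excl, method=method)


def _nb_null_loglik(y: np.ndarray) -> float:
    fit = fit_nb(y, np.ones((y.size, 1)))
    return fit["loglik"]


def accumulation_model_comparison(agg: GenusAggregate, trend: TrendFit,
                                  X: DesignMatrix, scope: str = "genus_specific",
                                  use_log_y: bool = False):
    """Nested NB regressions explaining taxa accumulations.

    Model (i): trend covariate only.  Model (ii): trend + genus identity
    (genus scope only) + log sample depth + design.  Reports McFadden
    pseudo-R^2 = 1 - ll_fit / ll_null (null: intercept-only NB with its own
    dispersion) and AIC for both.  ``use_log_y`` substitutes log recovered
    abundance for the fitted trend covariate.
    """
    if scope not in {"genus_specific", "sample_wide"}:
        raise ValueError(f"unknown scope {scope!r}")
    samples = agg.sample_ids
    logtau = np.log(agg.tau[samples].to_numpy(dtype=float))
    Xs = X.values_for(samples)[:, 1:]  # design w/o intercept; added explicitly

    if scope == "sample_wide":
        y = agg.n_plus.to_numpy(dtype=float)
        tcov = (np.log(agg.y.sum(axis=0).to_numpy(dtype=float)) if use_log_y
                else samplewide_trend_covariate(agg, trend).to_numpy())
        X1 = np.column_stack([np.ones(y.size), tcov])
        X2 = np.column_stack([np.ones(y.size), tcov, logtau, Xs])
    else:
        nmat = agg.n.to_numpy(dtype=float)
        ymat = agg.y.to_numpy(dtype=float)
        gi, sj = np.nonzero(nmat >= 1)
        y = nmat[gi, sj]
        logy = np.log(ymat[gi, sj])
        if use_log_y:
            tcov = logy
        else:
            eff = trend.retained_effects()
            ids = agg.group_ids
            tcov = (trend.kappa + trend.f_R(logy)
                    + np.array([eff.get(ids[g], 0.0) for g in gi]))
        genera = np.unique(gi)
        Gd = np.zeros((y.size, max(len(genera) - 1, 0)))
        for col, g in enumerate(genera[:-1]):
            Gd[gi == g, col] = 1.0
        X1 = np.column_stack([np.ones(y.size), tcov])
        X2 = np.column_stack([np.ones(y.size), tcov, Gd, logtau[sj], Xs[sj]])

    ll0 = _nb_null_loglik(y)
    out = []
    for label, Xm in (("trend_only", X1), ("trend_plus_covariates", X2)):
        try:
            fit = fit_nb(y, Xm)
            k = Xm.shape[1] + (1 if fit["family"] == "nb" else 0)
            pr2 = 1.0 - fit["loglik"] / ll0
            out.append(AccumulationModelComparison(
                label=label, pseudo_r2=float(max(pr2, 0.0)),
                aic=float(2 * k - 2 * fit["loglik"]),
                loglik=float(fit["loglik"]), loglik_null=float(ll0),
                n=int(y.size), converged=bool(fit["converged"])))
        except FitError:
            out.append(AccumulationModelComparison(
                label=label, pseudo_r2=np.nan, aic=np.nan, loglik=np.nan,
                loglik_null=float(ll0), n=int(y.size), converged=False))
    return tuple(out)


def replicability_summary(table: TaxaCountTable, taxmap: TaxonomyMap,
                          prevalence_cutoffs=(0.10, 0.50), rank: str = "genus"):
    """Per-genus fractions of member taxa at or below each prevalence cutoff.

    Prevalence is the fraction of samples where the taxon has a nonzero
    count.  Also reports, per cutoff, the study-level fraction of detected
    genera for which more than half their member taxa fall at or below the
    cutoff (the poor-replicability headline statistic).
    """
    if len(table.sample_ids) < 2:
        raise ValueError("replicability needs >= 2 samples")
    labels = taxmap.rank(rank).reindex(table.counts.index).copy()
    mask = labels == "unassigned"
    if mask.any():
        parents = taxmap.rank(taxmap.parent_of(rank)).reindex(table.counts.index)
        labels[mask] = "unassigned@" + parents[mask].astype(str)
    prevalence = (table.counts > 0).mean(axis=1)
    detected = prevalence > 0
    rows = []
    for g, idx in prevalence[detected].groupby(labels[detected]):
        row = {"group": g, "n_taxa": idx.size}
        for c in prevalence_cutoffs:
            row[f"frac_le_{c:g}"] = float((idx <= c).mean())
        rows.append(row)
    per_genus = pd.DataFrame(rows).set_index("group")
    study = {f"frac_genera_majority_le_{c:g}":
             float((per_genus[f"frac_le_{c:g}"] > 0.5).mean())
             for c in prevalence_cutoffs}
    return per_genus, study
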