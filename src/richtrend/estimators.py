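"""Classical richness estimators: observed, Chao1 and ACE.

These serve as comparison baselines.  Chao1 adds f1^2 / (2 f2) unobserved
taxa from the singleton/doubleton frequencies (bias-corrected variant when
no doubletons exist); ACE partitions taxa into rare (count <= cutoff) and
abundant classes and inflates the rare class by an estimated sample
coverage and coefficient of variation.  Standard errors follow the classic
asymptotic variance formulas (Chao1) and a delta-method over the rare
frequency counts (ACE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import TaxaCountTable, TaxonomyMap, aggregate_by_rank


@dataclass
class RichnessEstimate:
    estimator: str
    estimate: float
    se: float
    bias_corrected: bool = False
    undefined: bool = False


def observed_richness(v) -> int:
    """Number of detected taxa (length of the positive-count vector)."""
    v = _as_abundance(v)
    return int(v.size)


def _as_abundance(v) -> np.ndarray:
    v = np.asarray(list(v) if not isinstance(v, np.ndarray) else v)
    if v.size == 0:
        return np.array([], dtype=np.int64)
    v = v[v > 0]
    if not np.allclose(v, np.round(v.astype(float))):
        raise ValueError("abundance vector must hold integer counts")
    return v.astype(np.int64)


def chao1(v) -> RichnessEstimate:
    """Chao1 asymptotic richness with asymptotic SE.

    Classic form S_obs + f1^2/(2 f2) when doubletons exist; otherwise the
    bias-corrected form S_obs + f1 (f1 - 1) / (2 (f2 + 1)).  The variance
    expressions follow the matching variant.
    """
    v = _as_abundance(v)
    s_obs = v.size
    if s_obs == 0:
        return RichnessEstimate("chao1", 0.0, 0.0)
    f1 = int(np.sum(v == 1))
    f2 = int(np.sum(v == 2))
    if f2 > 0:
        est = s_obs + f1 * f1 / (2.0 * f2)
        G = f1 / f2
        var = f2 * (G**2 / 2.0 + G**3 + G**4 / 4.0)
        return RichnessEstimate("chao1", float(est), float(np.sqrt(max(var, 0.0))))
    # bias-corrected variant (f2 == 0)
    est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f1 > 0:
        var = (f1 * (f1 - 1) / 2.0
               + f1 * (2 * f1 - 1) ** 2 / 4.0
               - f1**4 / (4.0 * est))
    else:
        var = 0.0
    return RichnessEstimate("chao1", float(est), float(np.sqrt(max(var, 0.0))),
                            bias_corrected=True)


def _ace_point(freqs: np.ndarray, rare_cutoff: int) -> float:
    """ACE point estimate from a positive count vector; NaN when undefined."""
    rare = freqs[freqs <= rare_cutoff]
    s_abund = int(np.sum(freqs > rare_cutoff))
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int(np.sum(rare == 1))
    c_ace = 1.0 - f1 / n_rare
    if c_ace <= 0:
        return np.nan
    i = np.arange(1, rare_cutoff + 1)
    fi = np.array([np.sum(rare == k) for k in i])
    gamma2 = (s_rare / c_ace) * np.sum(i * (i - 1) * fi) / (n_rare * (n_rare - 1.0)) - 1.0 \
        if n_rare > 1 else 0.0
    gamma2 = max(gamma2, 0.0)
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def ace(v, rare_cutoff: int = 10) -> RichnessEstimate:
    """ACE asymptotic richness; SE by delta method over rare frequencies.

    The covariance of the rare frequency counts is approximated as
    cov(f_i, f_j) = delta_ij f_i - f_i f_j / S_hat and the gradient of the
    estimator with respect to (f_1..f_cutoff, S_abund) is taken numerically.
    Flagged undefined when all rare taxa are singletons (coverage zero).
    """
    v = _as_abundance(v)
    if v.size == 0:
        return RichnessEstimate("ace", 0.0, 0.0)
    est = _ace_point(v, rare_cutoff)
    if not np.isfinite(est):
        return RichnessEstimate("ace", float(v.size), 0.0, undefined=True)
    # delta method in the frequency-count coordinates
    i = np.arange(1, rare_cutoff + 1)
    fi = np.array([np.sum(v == k) for k in i], dtype=float)
    s_abund = float(np.sum(v > rare_cutoff))

    def from_freqs(fvec, sab):
        # same ACE formula, evaluated on fractional frequency counts
        s_rare = fvec.sum()
        if s_rare == 0:
            return sab
        n_rare = float(np.sum(i * fvec))
        f1 = fvec[0]
        c_ace = 1.0 - f1 / n_rare
        if c_ace <= 0:
            return np.nan
        gamma2 = (s_rare / c_ace) * np.sum(i * (i - 1) * fvec) / (n_rare * (n_rare - 1.0)) - 1.0 \
            if n_rare > 1 else 0.0
        gamma2 = max(gamma2, 0.0)
        return sab + s_rare / c_ace + (f1 / c_ace) * gamma2

    grad = np.zeros(rare_cutoff)
    h = 1e-5
    for k in range(rare_cutoff):
        up, dn = fi.copy(), fi.copy()
        up[k] += h
        dn[k] = max(dn[k] - h, 0.0)
        gu, gd = from_freqs(up, s_abund), from_freqs(dn, s_abund)
        if np.isfinite(gu) and np.isfinite(gd):
            grad[k] = (gu - gd) / (up[k] - dn[k])
    cov = np.diag(fi) - np.outer(fi, fi) / est
    var = float(grad @ cov @ grad)
    return RichnessEstimate("ace", float(est), float(np.sqrt(max(var, 0.0))))


_ESTIMATORS = {"observed": lambda v: RichnessEstimate("observed", float(observed_richness(v)), 0.0),
               "chao1": chao1, "ace": ace}


def sample_richness_table(table: TaxaCountTable, estimator: str = "chao1") -> pd.DataFrame:
    """Sample-wide richness estimates: one row per sample."""
    fn = _ESTIMATORS[estimator]
    rows = []
    for s in table.sample_ids:
        est = fn(table.counts[s].to_numpy())
        rows.append((s, est.estimator, est.estimate, est.se,
                     est.bias_corrected, est.undefined))
    return pd.DataFrame(rows, columns=["sample", "estimator", "estimate", "se",
                                       "bias_corrected", "undefined"])


def genus_asymptotic_table(table: TaxaCountTable, taxmap: TaxonomyMap,
                           estimator: str = "chao1", rank: str = "genus") -> pd.DataFrame:
    """Apply an asymptotic estimator within each genus's member taxa, per sample.

    Returns a long table (group, sample, estimate, se, flags); cells where
    the estimator is undefined are flagged, never imputed, and absent
    (genus, sample) cells get estimate 0.
    """
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    fn = _ESTIMATORS[estimator]
    agg = aggregate_by_rank(table, taxmap, rank=rank)
    labels = taxmap.rank(rank).reindex(table.counts.index).copy()
    mask = labels == "unassigned"
    if mask.any():
        parents = taxmap.rank(taxmap.parent_of(rank)).reindex(table.counts.index)
        labels[mask] = "unassigned@" + parents[mask].astype(str)
    rows = []
    counts = table.counts.to_numpy()
    sample_ids = table.sample_ids
    for g, idx in table.counts.groupby(labels, sort=True).indices.items():
        sub = counts[idx]
        for j, s in enumerate(sample_ids):
            v = sub[:, j]
            v = v[v > 0]
            if v.size == 0:
                rows.append((g, s, estimator, 0.0, 0.0, False, False))
                continue
            est = fn(v)
            rows.append((g, s, est.estimator, est.estimate, est.se,
                         est.bias_corrected, est.undefined))
    return pd.DataFrame(rows, columns=["group", "sample", "estimator", "estimate",
                                       "se", "bias_corrected", "undefined"])
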