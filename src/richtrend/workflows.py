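"""All-genus convenience loops shared by the CLI, tests and analyses."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import DesignMatrix, GenusAggregate, TaxaCountTable, TaxonomyMap
from .diagnostics import differential_abundance_lfc
from .estimators import genus_asymptotic_table
from .inference import (FitError, genus_differential_richness,
                        weighted_meta_regression)
from .trend import TrendFit
from statsmodels.stats.multitest import multipletests


def _bh(frame: pd.DataFrame) -> pd.DataFrame:
    ok = frame["p"].notna()
    frame["p_bh"] = np.nan
    if ok.any():
        frame.loc[ok, "p_bh"] = multipletests(frame.loc[ok, "p"], method="fdr_bh")[1]
    return frame


def all_genus_differential_richness(agg: GenusAggregate, trend: TrendFit,
                                    X: DesignMatrix, term: str | None = None,
                                    min_nonzero: int = 5, **kwargs) -> pd.DataFrame:
    """Fit the genus-specific model for every genus; one row per genus with
    the contrast coefficient for ``term`` (default first non-intercept
    column), BH-adjusted across genera."""
    term = term or next(c for c in X.columns if c != "Intercept")
    rows = []
    for g in agg.group_ids:
        res = genus_differential_richness(agg, trend, X, g,
                                          min_nonzero=min_nonzero, **kwargs)
        if res.status == "ok" and term in res.terms.index:
            t = res.terms.loc[term]
            rows.append((g, t["estimate"], t["se"], t["z"], t["p"],
                         res.trend_coef, res.n_obs, res.status))
        else:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, np.nan, res.n_obs, res.status))
    out = pd.DataFrame(rows, columns=["genus", "estimate", "se", "z", "p",
                                      "trend_coef", "n", "status"]).set_index("genus")
    return _bh(out)


def all_genus_differential_abundance(agg: GenusAggregate, X: DesignMatrix,
                                     term: str | None = None,
                                     min_nonzero: int = 5) -> pd.DataFrame:
    """Per-genus differential-abundance LFC table (NB with depth offset)."""
    rows = []
    for g in agg.group_ids:
        est, se = differential_abundance_lfc(agg, X, g, min_nonzero=min_nonzero,
                                             term=term)
        rows.append((g, est, se))
    out = pd.DataFrame(rows, columns=["genus", "estimate", "se"]).set_index("genus")
    out["z"] = out["estimate"] / out["se"]
    return out


def chao1_genus_differential_richness(table: TaxaCountTable, taxmap: TaxonomyMap,
                                      X: DesignMatrix, term: str | None = None,
                                      estimator: str = "chao1",
                                      min_defined: int = 5) -> pd.DataFrame:
    """The naive route: per-genus inverse-variance weighted regression of
    log asymptotic richness (Chao1/ACE) on the design."""
    term = term or next(c for c in X.columns if c != "Intercept")
    tbl = genus_asymptotic_table(table, taxmap, estimator=estimator)
    rows = []
    for g, sub in tbl.groupby("group"):
        sub = sub[(sub["estimate"] > 0) & ~sub["undefined"]]
        # SE 0 cells (estimate == observed exactly) get a small floor so
        # they stay usable in the weighted regression
        se = np.maximum(sub["se"].to_numpy(), 0.5)
        if len(sub) < min_defined:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, len(sub)))
            continue
        try:
            res = weighted_meta_regression(
                sub["estimate"].to_numpy(), se,
                DesignMatrix(X.frame.loc[sub["sample"], [c for c in X.columns
                                                         if c != "Intercept"]].copy()))
        except FitError:
            rows.append((g, np.nan, np.nan, np.nan, np.nan, len(sub)))
            continue
        t = res.terms.loc[term]
        rows.append((g, t["estimate"], t["se"], t["z"], t["p"], res.n_obs))
    out = pd.DataFrame(rows, columns=["genus", "estimate", "se", "z", "p",
                                      "n"]).set_index("genus")
    return _bh(out)
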