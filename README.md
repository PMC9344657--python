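# richtrend

Differential richness inference for 16S rRNA surveys with an
abundance-dependent spurious-taxa control.

## The problem

Clustering errors in amplicon sequencing create spurious OTUs/ASVs, and
they do so at a rate that **increases with the recovered abundance** of
the true source sequences.  Observed richness — and asymptotic estimators
built on rare-taxon frequencies (Chao1, ACE) — therefore grow with read
counts for purely technical reasons.  When two sample groups differ in the
*abundance* of their taxa, naive richness comparisons report spurious
*richness* differences.

`richtrend` addresses this in two steps:

1. **Trend estimation.** From within-genus accumulation data (observed
   sub-genus richness n_gj vs recovered genus abundance y_gj over detected
   (genus, sample) cells) it fits the semi-parametric model

       log n_gj = κ + f_R(log y_gj) + f_G(g) + ε_gj

   with a roughness-penalised cubic spline f_R (smoothing parameter by
   GCV), sum-to-zero genus offsets f_G tested and Benjamini–Hochberg
   filtered, giving the technical control f̂_t(g, log y).  A pooled loess
   smoother is available as an alternative.

2. **Trend-controlled regressions.** Group contrasts on richness come from
   log-link count GLMs that include f̂_t as a covariate (or offset):

   * genus-specific (Poisson):  log E[n_gj] = X_jᵀμ_g + ν_g f̂_t(g, log y_gj)
   * sample-wide (negative binomial): log E[n_+j] = X_jᵀζ + γ log Σ_{g det.} e^{f̂_t}
   * arbitrary genus collections, analogously.

   Wald tests, BH adjustment across genera, bootstrap-t intervals for the
   sample-wide model, and an inverse-variance weighted regression for
   running the same contrasts on Chao1/ACE estimates are included, as are
   confounding / model-comparison / replicability diagnostics and a
   mechanistic survey simulator with known ground truth.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a two-group survey in which **true richness is identical in both
groups** but genus abundances differ (per-genus log-fold-changes uniform
on ±ln 4), then compare the naive Chao1 route with the trend-controlled
route:

```python
import numpy as np
import richtrend as rt
from richtrend.workflows import (all_genus_differential_richness,
                                 all_genus_differential_abundance,
                                 chao1_genus_differential_richness)

b = rt.null_richness_confounding_scenario(seed=1)   # 60 genera, 30+30 samples
agg, X = b["aggregate"], b["design"]

trend = rt.fit_trend_spline(agg)
dr    = all_genus_differential_richness(agg, trend, X)      # trend-controlled
da    = all_genus_differential_abundance(agg, X)            # abundance LFCs
naive = chao1_genus_differential_richness(b["table"], b["taxonomy"], X)

print("naive Chao1 route:   r(DR, DA) = %.3f" %
      rt.confounding_diagnostic(naive["estimate"], da["estimate"]).r)
print("trend-controlled:    r(DR, DA) = %.3f" %
      rt.confounding_diagnostic(dr["estimate"], da["estimate"]).r)
print("false rejections at alpha=0.05: naive %.2f, controlled %.2f" %
      ((naive["p"] < 0.05).mean(), (dr["p"] < 0.05).mean()))

sw = rt.samplewide_differential_richness(agg, trend, X)
print(sw.terms.loc["group[B]", ["estimate", "se", "p"]].round(3))
```

Output:

```
naive Chao1 route:   r(DR, DA) = 0.904
trend-controlled:    r(DR, DA) = -0.014
false rejections at alpha=0.05: naive 0.93, controlled 0.02
estimate    0.021
se          0.117
p           0.857
Name: group[B], dtype: float64
```

The naive per-genus richness calls track the abundance changes almost
perfectly (r ≈ 0.9) and reject the true null for 93% of genera; the
trend-controlled calls are essentially uncorrelated with abundance and
reject 2%.  The sample-wide group effect (a log fold change; here truth
is 0) is correctly non-significant.

The same analyses are available from the shell:

```
richtrend simulate --seed 1 --out survey/
richtrend run --counts survey/counts.tsv --taxonomy survey/taxonomy.tsv \
              --design survey/design.csv --taxonomy-dialect rank_columns \
              --seed 1 --out results/
```

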