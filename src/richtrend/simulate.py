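"""Synthetic 16S survey generator with known truth.

The generator embodies the mechanism that motivates the trend control:
reads from true taxa are occasionally misclassified into spurious read
clusters ("false taxa"), and the *number* of distinct false taxa produced
for a genus grows with the genus's recovered abundance.  Concretely, per
sample j:

1. true-taxon counts are one multinomial draw of size tau_j over all true
   taxa (between-genus composition x within-genus profile, group-adjusted
   by per-genus abundance / richness log-fold-changes);
2. the recovered genus abundance y_gj is computed;
3. the number of false taxa is F_gj ~ Poisson(alpha * y_gj^beta);
4. false-taxon identities are drawn uniformly without replacement from a
   per-genus pool of size M_g (a small pool makes the same false taxa
   recur across samples; a large pool makes them sample-specific);
5. false counts start at one read each (plus a small binomial extra) and
   are *reassigned* from the genus's true taxa, so column sums stay
   exactly tau_j (reads are moved, never created).

Because each genus's probability of producing false taxa depends only on
its recovered abundance, between-group differential abundance of true taxa
induces apparent differential richness even when true richness is equal in
both groups — the confounding that the trend-controlled regressions are
designed to remove.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (DesignMatrix, GenusAggregate, TaxaCountTable,
                         TaxonomyMap, RANKS, aggregate_by_rank, build_design)

logger = logging.getLogger("richtrend")


@dataclass
class SurveyConfig:
    """Study conditions for one synthetic survey.

    Defaults describe a medium-sized two-group 16S survey: 60 genera,
    30 + 30 samples at mean depth 5e4, geometric within-genus abundance
    profiles (ratio 0.7), per-genus true richness uniform on 8..25, and
    false taxa generated at rate alpha * y^beta with alpha = 0.01,
    beta = 1 from per-genus identity pools of size 200.
    """

    n_genera: int = 60
    n_per_group: tuple[int, int] = (30, 30)
    depth_mean: float = 5e4
    depth_sigma: float = 0.0          # lognormal sd of depths; 0 = fixed
    richness_range: tuple[int, int] = (8, 25)
    true_richness: np.ndarray | None = None      # per-genus n_g^0, overrides range
    profile: str = "geometric"        # within-genus member profile
    profile_ratio: float = 0.7
    base_abundance: np.ndarray | None = None     # per-genus relative abundance
    base_abundance_sigma: float = 1.0            # lognormal spread when drawn
    abundance_lfc: np.ndarray | None = None      # per-genus, applied in group B
    richness_lfc: np.ndarray | None = None       # per-genus, applied in group B
    alpha: float = 0.01               # false-taxa rate scale (alpha >= 0)
    beta: float = 1.0                 # abundance exponent
    pool_size: int = 200              # M_g, false-identity pool per genus
    false_extra_p: float = 0.2        # extra reads per false taxon ~ Binomial(2, p)
    false_mode: str = "reassign"      # 'reassign' conserves depth; 'create' adds reads
    seed: int | None = None


@dataclass
class SurveyTruth:
    """Ground truth accompanying one simulated table."""

    true_detected: pd.DataFrame    # genus x sample, detected true taxa after reassignment
    false_count: pd.DataFrame      # genus x sample, F_gj (distinct false taxa emitted)
    y: pd.DataFrame                # genus x sample recovered abundance
    true_taxa: list[str]
    false_taxa: list[str]
    abundance_lfc: pd.Series
    richness_lfc: pd.Series
    n_truncated: int = 0


def _within_profile(k: int, profile: str, ratio: float) -> np.ndarray:
    if profile == "even":
        return np.full(k, 1.0 / k)
    w = ratio ** np.arange(k)
    return w / w.sum()


def simulate_survey(config: SurveyConfig, seed: int | None = None):
    """Generate (TaxaCountTable, TaxonomyMap, DesignMatrix, SurveyTruth)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    G = cfg.n_genera
    nA, nB = cfg.n_per_group
    J = nA + nB
    groups = np.r_[np.zeros(nA, dtype=int), np.ones(nB, dtype=int)]
    sample_ids = [f"S{j:03d}" for j in range(J)]
    genus_ids = [f"Genus{g:03d}" for g in range(G)]

    if cfg.true_richness is not None:
        n0 = np.asarray(cfg.true_richness, dtype=int)
        if n0.size != G:
            raise ValueError("true_richness length must equal n_genera")
    else:
        n0 = rng.integers(cfg.richness_range[0], cfg.richness_range[1] + 1, size=G)
    rlfc = np.zeros(G) if cfg.richness_lfc is None else np.asarray(cfg.richness_lfc, float)
    alfc = np.zeros(G) if cfg.abundance_lfc is None else np.asarray(cfg.abundance_lfc, float)
    if rlfc.size != G or alfc.size != G:
        raise ValueError("per-genus LFC arrays must have length n_genera")
    if cfg.alpha < 0 or cfg.beta < 0:
        raise ValueError("alpha and beta must be non-negative")

    # richness per group; the true-taxon pool covers the larger group
    n_by_group = np.column_stack([n0, np.maximum(1, np.round(n0 * np.exp(rlfc)).astype(int))])
    pool_n = n_by_group.max(axis=1)
    true_taxa = [f"{genus_ids[g]}_T{i:03d}" for g in range(G) for i in range(pool_n[g])]
    starts = np.r_[0, np.cumsum(pool_n)]

    if cfg.base_abundance is not None:
        base = np.asarray(cfg.base_abundance, dtype=float)
    else:
        base = rng.lognormal(0.0, cfg.base_abundance_sigma, size=G)
    base = base / base.sum()

    depths = (np.full(J, cfg.depth_mean) if cfg.depth_sigma == 0
              else rng.lognormal(np.log(cfg.depth_mean), cfg.depth_sigma, size=J))
    depths = np.maximum(1, np.round(depths)).astype(np.int64)

    # group-level probability vectors over the full true-taxon pool
    probs = []
    for x in (0, 1):
        p = np.zeros(len(true_taxa))
        gw = base * np.exp(alfc * x)
        gw = gw / gw.sum()
        for g in range(G):
            k = n_by_group[g, x]
            w = _within_profile(k, cfg.profile, cfg.profile_ratio)
            p[starts[g]: starts[g] + k] = gw[g] * w
        probs.append(p)

    counts = np.zeros((len(true_taxa), J), dtype=np.int64)
    false_rows: dict[str, np.ndarray] = {}
    y_mat = np.zeros((G, J), dtype=np.int64)
    F_mat = np.zeros((G, J), dtype=np.int64)
    n_trunc = 0

    for j in range(J):
        counts[:, j] = rng.multinomial(depths[j], probs[groups[j]])
        for g in range(G):
            seg = slice(starts[g], starts[g + 1])
            y = int(counts[seg, j].sum())
            y_mat[g, j] = y
            if y == 0 or cfg.alpha == 0:
                continue
            F = rng.poisson(cfg.alpha * y ** cfg.beta)
            F = min(F, cfg.pool_size)
            if F == 0:
                continue
            # per-false-taxon read counts, low by construction
            fcounts = 1 + rng.binomial(2, cfg.false_extra_p, size=F)
            budget = y // 2
            while F > 0 and fcounts[:F].sum() > budget:
                F -= 1
                n_trunc += 1
            if F == 0:
                logger.debug("false taxa truncated to 0 for genus %d sample %d", g, j)
                continue
            fcounts = fcounts[:F]
            ids = rng.choice(cfg.pool_size, size=F, replace=False)
            total_false = int(fcounts.sum())
            if cfg.false_mode == "reassign":
                # move reads off the genus's true taxa, conserving y_gj
                removed = rng.multivariate_hypergeometric(counts[seg, j], total_false)
                counts[seg, j] -= removed
            F_mat[g, j] = F
            for fid, fc in zip(ids, fcounts):
                name = f"{genus_ids[g]}_F{fid:04d}"
                row = false_rows.get(name)
                if row is None:
                    row = np.zeros(J, dtype=np.int64)
                    false_rows[name] = row
                row[j] += int(fc)

    false_taxa = sorted(false_rows)
    all_ids = true_taxa + false_taxa
    mat = np.vstack([counts] + [false_rows[t][None, :] for t in false_taxa]) \
        if false_taxa else counts
    table = TaxaCountTable(pd.DataFrame(mat, index=all_ids, columns=sample_ids))

    lineage = {}
    for t in all_ids:
        g = t.split("_")[0]
        gi = int(g.replace("Genus", ""))
        lineage[t] = ["Bacteria", f"Phylum{gi % 4}", f"Class{gi % 8}",
                      f"Order{gi % 12}", f"Family{gi % 15}", g]
    taxmap = TaxonomyMap(pd.DataFrame.from_dict(lineage, orient="index",
                                                columns=list(RANKS)))

    design_tbl = pd.DataFrame({"sample_id": sample_ids,
                               "group": np.where(groups == 0, "A", "B")})
    X = build_design(design_tbl)

    det = pd.DataFrame((counts > 0), index=true_taxa, columns=sample_ids)
    genus_of = np.repeat(np.arange(G), pool_n)
    true_det = np.zeros((G, J), dtype=np.int64)
    cmat = counts > 0
    for g in range(G):
        true_det[g] = cmat[genus_of == g].sum(axis=0)
    truth = SurveyTruth(
        true_detected=pd.DataFrame(true_det, index=genus_ids, columns=sample_ids),
        false_count=pd.DataFrame(F_mat, index=genus_ids, columns=sample_ids),
        y=pd.DataFrame(y_mat, index=genus_ids, columns=sample_ids),
        true_taxa=true_taxa, false_taxa=false_taxa,
        abundance_lfc=pd.Series(alfc, index=genus_ids),
        richness_lfc=pd.Series(rlfc, index=genus_ids),
        n_truncated=n_trunc)
    if n_trunc:
        logger.debug("%d false taxa dropped by the read-reassignment budget", n_trunc)
    return table, taxmap, X, truth


def null_richness_confounding_scenario(n_per_group: int = 30, depth: float = 5e4,
                                       fold_changes: str = "heterogeneous",
                                       n_genera: int = 60, alpha: float = 0.01,
                                       beta: float = 1.0, depth_sigma: float = 0.0,
                                       seed: int | None = None,
                                       **overrides) -> dict:
    """Convenience scenario: equal true richness in both groups, per-genus
    abundance fold changes drawn per ``fold_changes``:

    - 'heterogeneous': uniform on [-ln 4, ln 4] (wide, mean zero);
    - 'symmetric': normal(0, ln 2);
    - 'asymmetric': normal(ln 2, 0.5) — all-shifted, nonzero mean, the case
      where naive sample-wide comparisons break;
    - 'none': all zero.

    Returns a dict with the table, taxonomy, design, truth, genus aggregate
    and config; any apparent sample-wide richness difference is technical.
    """
    rng = np.random.default_rng(seed)
    G = n_genera
    if fold_changes == "heterogeneous":
        lfc = rng.uniform(-np.log(4), np.log(4), size=G)
    elif fold_changes == "symmetric":
        lfc = rng.normal(0.0, np.log(2), size=G)
    elif fold_changes == "asymmetric":
        lfc = rng.normal(np.log(2), 0.5, size=G)
    elif fold_changes == "none":
        lfc = np.zeros(G)
    else:
        raise ValueError(f"unknown fold_changes mode {fold_changes!r}")
    cfg = SurveyConfig(n_genera=G, n_per_group=(n_per_group, n_per_group),
                       depth_mean=depth, depth_sigma=depth_sigma,
                       abundance_lfc=lfc, alpha=alpha, beta=beta, **overrides)
    table, taxmap, X, truth = simulate_survey(cfg, seed=int(rng.integers(2**31)))
    agg = aggregate_by_rank(table, taxmap, rank="genus")
    return {"table": table, "taxonomy": taxmap, "design": X, "truth": truth,
            "aggregate": agg, "config": cfg}
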