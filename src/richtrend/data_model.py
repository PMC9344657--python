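"""Count tables, taxonomy maps, genus-level aggregation and design matrices.

The central object downstream of ingestion is the :class:`GenusAggregate`:
for every (genus g, sample j) it records the observed sub-genus richness
``n[g, j]`` (number of member taxa with a nonzero count) and the recovered
genus abundance ``y[g, j]`` (total reads assigned to the genus), together
with the per-sample depth ``tau[j]`` and total observed richness
``n_plus[j]``.  These four quantities drive both trend estimation and the
differential richness regressions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("richtrend")

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"

_QIIME_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")


class ParseError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class TaxaCountTable:
    """Integer count matrix, taxa (rows) x samples (columns).

    ``counts`` is a pandas DataFrame indexed by taxon id with sample ids as
    columns.  Validation enforces unique identifiers and non-negative
    integral counts; the per-sample depth is the column sum.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ParseError(f"duplicate taxon id: {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id: {dup!r}")
        vals = c.to_numpy()
        if vals.size == 0:
            raise ParseError("count table is empty")
        if not np.issubdtype(vals.dtype, np.number):
            raise ParseError("count table contains non-numeric entries")
        if np.isnan(vals.astype(float)).any():
            r, s = np.argwhere(np.isnan(vals.astype(float)))[0]
            raise ParseError(f"NaN count at taxon {c.index[r]!r}, sample {c.columns[s]!r}")
        if (vals < 0).any():
            r, s = np.argwhere(vals < 0)[0]
            raise ParseError(f"negative count at taxon {c.index[r]!r}, sample {c.columns[s]!r}")
        if not np.allclose(vals, np.round(vals.astype(float))):
            r, s = np.argwhere(~np.isclose(vals.astype(float), np.round(vals.astype(float))))[0]
            raise ParseError(
                f"non-integer count at taxon {c.index[r]!r}, sample {c.columns[s]!r}; "
                "relative abundances are not accepted (richness is undefined on them)"
            )
        self.counts = c.astype(np.int64)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        """Sample depth tau_j: total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="taxon_id")


def read_count_table(path, format: str = "tsv") -> TaxaCountTable:
    """Read a taxa-by-sample count matrix from TSV, CSV or BIOM v1 JSON."""
    if format not in {"tsv", "csv", "biom-json"}:
        raise ValueError(f"unknown count table format: {format!r}")
    if format == "biom-json":
        return _read_biom_json(path)
    sep = "\t" if format == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty count table: {path}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"count table has no sample columns: {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return TaxaCountTable(df)


def _read_biom_json(path) -> TaxaCountTable:
    # BIOM v1 is plain JSON: rows/columns metadata plus a dense or sparse
    # (row, col, value) data payload.
    with open(path) as fh:
        doc = json.load(fh)
    try:
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for r, c, v in doc["data"]:
                mat[r, c] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed BIOM-JSON file: {path}") from exc
    return TaxaCountTable(pd.DataFrame(mat, index=taxa, columns=samples))


@dataclass
class TaxonomyMap:
    """Taxon id -> six-rank lineage (kingdom..genus), 'unassigned' where absent."""

    lineages: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise ParseError(f"taxonomy table missing ranks: {missing}")
        self.lineages = self.lineages[list(RANKS)].astype(str)
        # a rank below an unassigned rank must itself be unassigned
        vals = self.lineages.to_numpy()
        for i in range(len(RANKS) - 1):
            bad = (vals[:, i] == UNASSIGNED) & (vals[:, i + 1] != UNASSIGNED)
            if bad.any():
                tax = self.lineages.index[np.argmax(bad)]
                raise ParseError(
                    f"taxon {tax!r} has rank {RANKS[i + 1]} assigned below an unassigned {RANKS[i]}"
                )

    def rank(self, rank: str) -> pd.Series:
        return self.lineages[rank]

    def parent_of(self, rank: str) -> str:
        i = RANKS.index(rank)
        return RANKS[i - 1] if i > 0 else RANKS[0]


def parse_qiime_lineage(s: str) -> list[str]:
    """Split a QIIME-style 'k__X;p__Y;...' string into six rank tokens."""
    toks = [t.strip() for t in str(s).split(";")]
    if len(toks) > 6:
        logger.debug("lineage has %d tokens; ranks below genus ignored: %r", len(toks), s)
        toks = toks[:6]
    out = []
    for i in range(6):
        tok = toks[i] if i < len(toks) else ""
        for pref in _QIIME_PREFIXES:
            if tok.startswith(pref):
                tok = tok[len(pref):]
                break
        tok = tok.strip()
        out.append(tok if tok else UNASSIGNED)
    # enforce downward consistency: once unassigned, everything below is too
    seen_gap = False
    for i in range(6):
        if out[i] == UNASSIGNED:
            seen_gap = True
        elif seen_gap:
            out[i] = UNASSIGNED
    return out


def parse_taxonomy(path_or_frame, dialect: str = "qiime_string",
                   taxon_ids=None, strict: bool = True) -> TaxonomyMap:
    """Build a TaxonomyMap from a 2-column (id, lineage string) or
    7-column (id + six ranks) table.

    Parameters
    ----------
    path_or_frame : path or DataFrame
        TSV path or an equivalent in-memory frame.
    dialect : {'qiime_string', 'rank_columns'}
    taxon_ids : optional iterable
        Taxa that must be covered (typically the count table's).  Missing
        taxa raise in strict mode, otherwise become all-unassigned.
    """
    if dialect not in {"qiime_string", "rank_columns"}:
        raise ValueError(f"unknown taxonomy dialect: {dialect!r}")
    if isinstance(path_or_frame, pd.DataFrame):
        raw = path_or_frame.copy()
    else:
        try:
            raw = pd.read_csv(path_or_frame, sep="\t", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise ParseError(f"empty taxonomy table: {path_or_frame}") from exc
    raw = raw.set_index(raw.columns[0])
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ParseError(f"duplicate taxon id in taxonomy: {dup!r}")

    if dialect == "qiime_string":
        if raw.shape[1] < 1:
            raise ParseError("qiime_string taxonomy needs a lineage column")
        rows = [parse_qiime_lineage(s) for s in raw.iloc[:, 0]]
        lin = pd.DataFrame(rows, index=raw.index, columns=list(RANKS))
    else:
        if raw.shape[1] < 6:
            raise ParseError("rank_columns taxonomy needs six rank columns")
        lin = raw.iloc[:, :6].copy()
        lin.columns = list(RANKS)
        lin = lin.fillna(UNASSIGNED)
        lin = lin.map(lambda t: t.strip() if isinstance(t, str) and t.strip() else UNASSIGNED)

    if taxon_ids is not None:
        missing = [t for t in taxon_ids if t not in lin.index]
        if missing and strict:
            raise ParseError(f"{len(missing)} taxa absent from taxonomy, e.g. {missing[0]!r}")
        if missing:
            logger.warning("%d taxa absent from taxonomy; treated as all-unassigned", len(missing))
            pad = pd.DataFrame(UNASSIGNED, index=missing, columns=list(RANKS))
            lin = pd.concat([lin, pad])
    return TaxonomyMap(lin)


@dataclass
class GenusAggregate:
    """Per-(group, sample) richness/abundance summaries at a taxonomic rank.

    ``n`` and ``y`` are group-by-sample DataFrames; ``tau`` holds the frozen
    per-sample depth computed from the *full* input table.  Invariants:
    n <= y elementwise, n == 0 iff y == 0 and, with unassigned pooling on,
    the columns of ``y`` sum to ``tau``.
    """

    n: pd.DataFrame
    y: pd.DataFrame
    tau: pd.Series
    rank: str = "genus"
    group_sizes: pd.Series | None = None  # member taxa per group

    @property
    def group_ids(self) -> list[str]:
        return list(self.n.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.n.columns)

    @property
    def n_plus(self) -> pd.Series:
        """Per-sample total observed richness n_+j."""
        return self.n.sum(axis=0)

    def subset_samples(self, sample_ids) -> "GenusAggregate":
        ids = list(sample_ids)
        return GenusAggregate(
            n=self.n[ids].copy(), y=self.y[ids].copy(),
            tau=self.tau[ids].copy(), rank=self.rank,
            group_sizes=self.group_sizes,
        )


def aggregate_by_rank(table: TaxaCountTable, taxmap: TaxonomyMap,
                      rank: str = "genus", pool_unassigned: bool = True) -> GenusAggregate:
    """Aggregate taxon counts to genus (or higher-rank) richness/abundance.

    Taxa whose rank is unassigned are pooled into one pseudo-group per
    parent-rank value, named ``unassigned@<parent>``, so that read depth is
    conserved; with ``pool_unassigned=False`` they are dropped instead.
    """
    if rank not in RANKS[1:]:
        raise ValueError(f"rank must be one of {RANKS[1:]}, got {rank!r}")
    labels = taxmap.rank(rank).reindex(table.counts.index)
    if labels.isna().any():
        miss = labels.index[labels.isna()][0]
        raise ParseError(f"taxon {miss!r} missing from taxonomy map")
    labels = labels.copy()
    mask = labels == UNASSIGNED
    if mask.any():
        if pool_unassigned:
            parent = taxmap.parent_of(rank)
            parents = taxmap.rank(parent).reindex(table.counts.index)
            labels[mask] = "unassigned@" + parents[mask].astype(str)
        else:
            labels = labels[~mask]
    tau = table.depths  # frozen before any filtering
    counts = table.counts.loc[labels.index]
    y = counts.groupby(labels, sort=True).sum()
    n = (counts > 0).groupby(labels, sort=True).sum()
    sizes = labels.groupby(labels).size()
    empty = tau.index[tau == 0]
    for s in empty:
        logger.warning("sample %r has zero total count", s)
    return GenusAggregate(n=n.astype(np.int64), y=y.astype(np.int64),
                          tau=tau, rank=rank, group_sizes=sizes)


@dataclass
class DesignMatrix:
    """Samples-by-covariates real design matrix with an intercept column."""

    frame: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        if "Intercept" not in self.frame.columns:
            self.frame.insert(0, "Intercept", 1.0)
        self.frame = self.frame.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, sample_ids) -> np.ndarray:
        return self.frame.loc[list(sample_ids)].to_numpy()

    def check_full_rank(self, sample_ids=None) -> None:
        X = self.frame if sample_ids is None else self.frame.loc[list(sample_ids)]
        r = np.linalg.matrix_rank(X.to_numpy())
        if r < X.shape[1]:
            raise ValueError(
                f"design matrix is rank deficient (rank {r} < {X.shape[1]} columns: "
                f"{list(X.columns)})"
            )


def build_design(samples: pd.DataFrame, sample_id_col: str = "sample_id",
                 reference: dict | None = None) -> DesignMatrix:
    """Expand a sample covariate table into a treatment-coded design matrix.

    Categorical (object / categorical dtype) columns are expanded to
    indicator columns against the lexicographically first level, unless a
    different reference level is given in ``reference[column]``.
    """
    reference = reference or {}
    df = samples.set_index(sample_id_col) if sample_id_col in samples.columns else samples.copy()
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise ParseError("duplicate sample ids in design table")
    cols = {}
    for name in df.columns:
        col = df[name]
        if col.dtype.kind in "if":
            cols[name] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            ref = reference.get(name, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in column {name!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{name}[{lev}]"] = (col.astype(str) == lev).astype(float)
    out = pd.DataFrame(cols, index=df.index)
    return DesignMatrix(out)


def read_design(path, sample_id_col: str = "sample_id",
                reference: dict | None = None) -> DesignMatrix:
    """Read a CSV design table and expand it (see :func:`build_design`)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"empty design table: {path}") from exc
    if sample_id_col not in df.columns:
        raise ParseError(f"design table lacks a {sample_id_col!r} column: {path}")
    return build_design(df, sample_id_col=sample_id_col, reference=reference)
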