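"""From per-sample CpG read counts to a filtered, imputed methylation matrix.

The pipeline mirrors standard RRBS clock preprocessing: strand pooling,
technical-replicate merging, exclusion of shallow samples, a Jeffreys-prior
binomial confidence mask, a per-site sample-fraction filter, iterative
removal of gap-heavy samples, and k-nearest-neighbor imputation.

A methylation level is the raw frequency k/n of methylated over total mapped
reads; the Beta(0.5, 0.5) posterior is used only to decide whether that
frequency is *confident* (equal-tailed 95% credible interval narrower than
0.50), never to shrink the value itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist
from sklearn.impute import KNNImputer

from .io import SiteKey, site_id

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceCall",
    "MethylationMatrix",
    "pool_strands",
    "merge_replicates",
    "jeffreys_interval",
    "jeffreys_bounds",
    "methylation_frequency",
    "exclude_low_coverage_samples",
    "filter_sites",
    "reduce_missingness",
    "knn_impute",
    "build_matrix",
]


@dataclass(frozen=True)
class ConfidenceCall:
    lower: float
    upper: float
    confident: bool


@dataclass
class MethylationMatrix:
    """Complete samples x sites frequency matrix joined to its metadata."""

    values: pd.DataFrame          # float in [0,1], no NaN after imputation
    metadata: pd.DataFrame        # aligned to values.index
    pre_impute_mask: pd.DataFrame = None  # True where a cell was imputed

    def __post_init__(self):
        self.metadata = self.metadata.loc[self.values.index]


# ---------------------------------------------------------------------------
# Count-table manipulation

def pool_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Pool forward/reverse cytosine counts of each CpG into one measurement.

    A reverse-strand record at position p belongs to the CpG whose
    forward-strand C sits at p-1. Returns a DataFrame indexed by
    (chrom, pos) with summed ``meth``/``total`` columns.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["meth", "total"],
                            index=pd.MultiIndex.from_arrays([[], []],
                                                            names=["chrom", "pos"]))
    rev = records["strand"].to_numpy() == "-"
    pos = records["pos"].to_numpy(dtype=int)
    if np.any(rev & (pos <= 1)):
        bad = int(np.flatnonzero(rev & (pos <= 1))[0])
        raise ValueError(
            f"reverse-strand record at position {pos[bad]} has no forward C"
        )
    fwd_pos = np.where(rev, pos - 1, pos)
    pooled = (
        pd.DataFrame(
            {
                "chrom": records["chrom"].to_numpy(),
                "pos": fwd_pos,
                "meth": records["meth"].to_numpy(dtype=int),
                "total": records["total"].to_numpy(dtype=int),
            }
        )
        .groupby(["chrom", "pos"], sort=True)[["meth", "total"]]
        .sum()
    )
    return pooled


def merge_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Merge technical replicates of one sample by summing read counts."""
    if len(tables) == 0:
        raise ValueError("merge_replicates needs at least one table")
    if len(tables) == 1:
        return tables[0].copy()
    merged = pd.concat(tables).groupby(level=["chrom", "pos"], sort=True).sum()
    return merged


# ---------------------------------------------------------------------------
# Jeffreys confidence machinery

def jeffreys_bounds(k, n, level: float = 0.95):
    """Vectorized equal-tailed Beta(k+1/2, n-k+1/2) credible bounds.

    Returns (lower, upper) arrays; cells with n == 0 are NaN. Quantiles are
    evaluated once per distinct (k, n) pair, which makes full-matrix calls
    cheap on sequencing data where coverage values repeat heavily.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(k > n):
        raise ValueError("methylated count k exceeds total count n")
    if np.any(k < 0):
        raise ValueError("negative methylated count")
    tail = (1.0 - level) / 2.0
    pairs = np.stack([k.ravel(), n.ravel()], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    uk, un = uniq[:, 0], uniq[:, 1]
    lo_u = np.full(len(uniq), np.nan)
    hi_u = np.full(len(uniq), np.nan)
    pos = un > 0
    lo_u[pos] = beta_dist.ppf(tail, uk[pos] + 0.5, un[pos] - uk[pos] + 0.5)
    hi_u[pos] = beta_dist.ppf(1.0 - tail, uk[pos] + 0.5, un[pos] - uk[pos] + 0.5)
    return lo_u[inverse].reshape(k.shape), hi_u[inverse].reshape(k.shape)


def jeffreys_interval(k: int, n: int, level: float = 0.95,
                      max_width: float = 0.50) -> ConfidenceCall:
    """Jeffreys-prior credible interval and its confidence verdict.

    Confident means the interval is strictly narrower than ``max_width`` and
    at least one read was observed.
    """
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if n == 0:
        return ConfidenceCall(np.nan, np.nan, False)
    lo, hi = jeffreys_bounds(float(k), float(n), level=level)
    lo, hi = float(lo), float(hi)
    return ConfidenceCall(lo, hi, bool(hi - lo < max_width))


def methylation_frequency(k, n):
    """Raw methylation frequency k/n; NaN where no reads were mapped."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(n > 0, k / np.where(n > 0, n, 1.0), np.nan)
    if f.ndim == 0:
        return float(f)
    return f


# ---------------------------------------------------------------------------
# Filters

def exclude_low_coverage_samples(
    tables: Mapping[str, pd.DataFrame], min_sites: int = 500_000
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Drop samples measuring fewer than ``min_sites`` CpGs (total reads > 0).

    Returns (retained tables, dropped sample ids). Raises if nothing
    survives.
    """
    kept: dict[str, pd.DataFrame] = {}
    dropped: list[str] = []
    for sample, tab in tables.items():
        measured = int((tab["total"] > 0).sum())
        if measured < min_sites:
            dropped.append(sample)
            logger.info("dropping %s: %d measured CpGs < %d",
                        sample, measured, min_sites)
        else:
            kept[sample] = tab
    if not kept:
        raise ValueError(
            f"all {len(tables)} samples fall below the {min_sites}-site floor"
        )
    return kept, dropped


def filter_sites(confident: pd.DataFrame, sample_fraction: float = 0.95) -> list:
    """Sites confidently measured in at least ``sample_fraction`` of samples.

    ``confident`` is a samples x sites boolean frame; returns the retained
    column labels in column order.
    """
    frac = confident.to_numpy(dtype=bool).mean(axis=0)
    keep = frac >= sample_fraction
    return [c for c, k in zip(confident.columns, keep) if k]


def reduce_missingness(
    values: pd.DataFrame, target: float = 0.02
) -> tuple[pd.DataFrame, list[str]]:
    """Iteratively drop the gap-heaviest sample until missingness <= target.

    Ties go to the earliest sample in row order; the loop stops once the
    global missing fraction reaches the target or a single sample remains.
    Returns (reduced matrix, removal order).
    """
    vals = values.copy()
    removed: list[str] = []
    while len(vals) > 1:
        mask = vals.isna().to_numpy()
        if mask.mean() <= target:
            break
        per_sample = mask.sum(axis=1)
        worst = int(np.argmax(per_sample))  # argmax takes the first tie
        removed.append(str(vals.index[worst]))
        vals = vals.drop(index=vals.index[worst])
    return vals, removed


def knn_impute(values: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Fill missing cells with the unweighted mean of the k nearest samples.

    Distance between samples is Euclidean over the sites observed in both,
    normalized by the number of shared sites, so samples with different
    missingness patterns are comparable. Donors for a cell are the samples
    observed at that site; if fewer than k exist, all are used. Observed
    cells are returned untouched.
    """
    empty = values.isna().all(axis=0)
    if empty.any():
        bad = list(values.columns[empty])[:5]
        raise ValueError(f"site(s) with zero observed values: {bad}")
    if not values.isna().to_numpy().any():
        return values.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    out = imputer.fit_transform(values.to_numpy(dtype=float))
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# Orchestration

@dataclass
class BuildConfig:
    min_sites: int = 500_000
    sample_fraction: float = 0.95
    ci_level: float = 0.95
    max_ci_width: float = 0.50
    target_missing: float = 0.02
    knn: int = 5


def _counts_to_wide(tables: Mapping[str, pd.DataFrame]):
    """Align per-sample (chrom,pos)->(meth,total) tables into K, N matrices."""
    all_sites = None
    for tab in tables.values():
        idx = tab.index
        all_sites = idx if all_sites is None else all_sites.union(idx)
    all_sites = all_sites.sort_values()
    samples = list(tables)
    K = np.zeros((len(samples), len(all_sites)))
    N = np.zeros((len(samples), len(all_sites)))
    for i, s in enumerate(samples):
        tab = tables[s].reindex(all_sites)
        K[i] = tab["meth"].fillna(0).to_numpy()
        N[i] = tab["total"].fillna(0).to_numpy()
    cols = [site_id(c, p) for c, p in all_sites]
    return samples, cols, K, N


def build_matrix(
    tables: Mapping[str, pd.DataFrame | Sequence[pd.DataFrame]],
    metadata: pd.DataFrame,
    config: BuildConfig | None = None,
) -> tuple[MethylationMatrix, dict]:
    """Run the full preprocessing pipeline and return matrix + manifest.

    ``tables`` maps sample id to a pooled count table (indexed by
    (chrom, pos)) or to a list of technical-replicate tables, which are
    merged by summing counts. The pipeline order is fixed: replicate merge,
    low-coverage sample exclusion, Jeffreys confidence calls, site filter,
    confidence masking, missingness reduction, KNN imputation.
    """
    cfg = config or BuildConfig()
    merged: dict[str, pd.DataFrame] = {}
    for sample, tab in tables.items():
        if isinstance(tab, pd.DataFrame):
            merged[sample] = tab
        else:
            merged[sample] = merge_replicates(list(tab))
    unknown = [s for s in merged if s not in metadata.index]
    if unknown:
        raise ValueError(f"samples missing from metadata: {unknown[:5]}")

    manifest: dict = {"n_samples_input": len(merged)}
    kept, dropped = exclude_low_coverage_samples(merged, cfg.min_sites)
    manifest["samples_dropped_low_coverage"] = dropped
    manifest["n_samples_after_coverage"] = len(kept)

    samples, cols, K, N = _counts_to_wide(kept)
    manifest["n_sites_union"] = len(cols)

    lo, hi = jeffreys_bounds(K, N, level=cfg.ci_level)
    with np.errstate(invalid="ignore"):
        confident = (hi - lo < cfg.max_ci_width) & (N > 0)
    conf_df = pd.DataFrame(confident, index=samples, columns=cols)
    retained_sites = filter_sites(conf_df, cfg.sample_fraction)
    if not retained_sites:
        raise ValueError("no site is confidently measured in enough samples")
    manifest["n_sites_after_filter"] = len(retained_sites)

    freq = methylation_frequency(K, N)
    values = pd.DataFrame(freq, index=samples, columns=cols)[retained_sites]
    values = values.where(conf_df[retained_sites])  # non-confident -> NaN
    manifest["missing_fraction_before_reduction"] = float(
        values.isna().to_numpy().mean()
    )

    values, removed = reduce_missingness(values, cfg.target_missing)
    manifest["samples_dropped_missingness"] = removed
    manifest["n_samples_final"] = len(values)
    manifest["missing_fraction_before_impute"] = float(
        values.isna().to_numpy().mean()
    )

    still_empty = values.isna().all(axis=0)
    if still_empty.any():
        # a site can lose all its observed cells when samples are dropped
        values = values.loc[:, ~still_empty]
        manifest["n_sites_after_filter"] = values.shape[1]
    mask = values.isna()
    complete = knn_impute(values, cfg.knn)
    manifest["n_cells_imputed"] = int(mask.to_numpy().sum())

    matrix = MethylationMatrix(
        values=complete,
        metadata=metadata.loc[complete.index],
        pre_impute_mask=mask,
    )
    return matrix, manifest
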