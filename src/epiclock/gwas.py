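"""Mixed-model GWAS of epigenetic age across inbred mouse strains.

The association model for a candidate SNP s is

    y = X b + g_s b_s + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with K the standardized-genotype kinship matrix. Following the EMMA lineage
of LMM solvers, K is eigendecomposed once, the variance ratio
delta = se2/sg2 is profiled by maximum likelihood on the null model, and
every SNP is then tested by generalized least squares in the rotated space
with a 1-df Wald chi-square on b_s. Peaks are thinned greedily to a minimum
genomic spacing and annotated with genes inside a +/- 500 kbp window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GWASResult",
    "maf_filter",
    "kinship",
    "lmm_assoc",
    "MixedModelGWAS",
    "select_peaks",
    "nearest_genes",
    "allele_group_test",
]


@dataclass
class GWASResult:
    table: pd.DataFrame          # per SNP: beta, stat, p (+ chrom/pos if mapped)
    sigma_g2: float
    sigma_e2: float
    delta: float
    kinship: np.ndarray
    bonferroni: float            # 0.05 / n_snps significance line


def maf_filter(G: pd.DataFrame, min_maf: float = 0.05) -> pd.DataFrame:
    """Keep SNPs with minor allele frequency strictly above ``min_maf``.

    Missing genotypes are excluded from the frequency computation.
    """
    vals = G.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        f = np.nanmean(vals, axis=0)
    maf = np.minimum(f, 1.0 - f)
    keep = maf > min_maf
    return G.loc[:, keep]


def _mean_impute(vals: np.ndarray) -> np.ndarray:
    out = vals.copy()
    if np.isnan(out).any():
        mean = np.nanmean(out, axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = mean[idx[1]]
    return out


def kinship(G: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Standardized-genotype kinship K = W W' / p, unit mean diagonal.

    Missing genotypes are mean-imputed per SNP; monomorphic SNPs drop out of
    the standardization.
    """
    vals = G.to_numpy(dtype=float) if isinstance(G, pd.DataFrame) else np.asarray(G, float)
    if vals.shape[1] == 0:
        raise ValueError("no SNPs from which to build a kinship matrix")
    W = _mean_impute(vals)
    mu = W.mean(axis=0)
    sd = W.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("all SNPs monomorphic")
    W = (W[:, poly] - mu[poly]) / sd[poly]
    K = W @ W.T / poly.sum()
    K = (K + K.T) / 2.0
    K /= np.diag(K).mean()
    return K


def _null_loglik(delta: float, eigvals: np.ndarray, yr: np.ndarray,
                 Xr: np.ndarray) -> float:
    """Profile log-likelihood of the null model at variance ratio delta."""
    n = len(yr)
    d = eigvals + delta
    w = 1.0 / d
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    beta = np.linalg.solve(XtWX, XtWy)
    res = yr - Xr @ beta
    sg2 = float((res * res * w).sum() / n)
    return -0.5 * (n * np.log(2 * np.pi * sg2) + np.log(d).sum() + n)


def lmm_assoc(y, G, K: np.ndarray, covariates=None) -> GWASResult:
    """Per-SNP mixed-model association with kinship correction.

    ``y`` are DNAm ages per strain, ``G`` a strains x SNPs 0/1 matrix
    (missing entries mean-imputed), ``K`` the kinship. The variance ratio is
    estimated once on the null model (ML over log-delta in [-10, 10]); each
    SNP is then a 1-df Wald chi-square from weighted least squares in the
    eigenbasis of K, with the residual variance re-estimated per SNP.
    """
    yv = np.asarray(y, dtype=float)
    if np.ptp(yv) == 0.0:
        raise ValueError("phenotype is constant")
    snp_ids = list(G.columns) if isinstance(G, pd.DataFrame) else list(range(np.shape(G)[1]))
    Gv = _mean_impute(G.to_numpy(dtype=float) if isinstance(G, pd.DataFrame)
                      else np.asarray(G, dtype=float))
    n = len(yv)
    if Gv.shape[0] != n or K.shape != (n, n):
        raise ValueError("y, G and K dimensions disagree")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix is not symmetric")
    eigvals, U = np.linalg.eigh(K)
    if eigvals.min() < -1e-8:
        raise ValueError("kinship matrix is not positive semidefinite")
    eigvals = np.clip(eigvals, 0.0, None)

    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)])
    yr = U.T @ yv
    Xr = U.T @ X

    # ML profile of delta: coarse grid then local refinement (EMMA-style)
    grid = np.linspace(-10.0, 10.0, 81)
    lls = np.array([_null_loglik(np.exp(g), eigvals, yr, Xr) for g in grid])
    g0 = grid[int(np.argmax(lls))]
    res = optimize.minimize_scalar(
        lambda g: -_null_loglik(np.exp(g), eigvals, yr, Xr),
        bounds=(g0 - 0.5, g0 + 0.5), method="bounded",
    )
    delta = float(np.exp(res.x))

    w = 1.0 / (eigvals + delta)
    Gr = U.T @ Gv
    q = X.shape[1] + 1
    betas = np.empty(len(snp_ids))
    stats_ = np.empty(len(snp_ids))
    for j in range(Gr.shape[1]):
        A = np.column_stack([Xr, Gr[:, j]])
        AtW = A.T * w
        AtWA = AtW @ A
        try:
            cov = np.linalg.inv(AtWA)
        except np.linalg.LinAlgError:
            betas[j], stats_[j] = np.nan, 0.0
            continue
        beta = cov @ (AtW @ yr)
        resid = yr - A @ beta
        sigma2 = float((resid * resid * w).sum() / max(n - q, 1))
        var_s = sigma2 * cov[-1, -1]
        betas[j] = beta[-1]
        stats_[j] = beta[-1] ** 2 / var_s if var_s > 0 else 0.0
    pvals = stats.chi2.sf(stats_, df=1)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)

    # variance components at the null for reporting
    d = eigvals + delta
    XtWX = Xr.T @ (Xr / d[:, None])
    beta0 = np.linalg.solve(XtWX, Xr.T @ (yr / d))
    res0 = yr - Xr @ beta0
    sg2 = float((res0 * res0 / d).sum() / n)

    table = pd.DataFrame(
        {"snp": snp_ids, "beta": betas, "stat": stats_, "p": pvals}
    ).set_index("snp", drop=False)
    return GWASResult(
        table=table,
        sigma_g2=sg2,
        sigma_e2=sg2 * delta,
        delta=delta,
        kinship=K,
        bonferroni=0.05 / len(snp_ids),
    )


class MixedModelGWAS:
    """Fit-shaped wrapper: MAF filter, kinship, association, peak calling.

    Parameters mirror the method defaults: MAF > 0.05, 2 Mbp peak spacing,
    top 10 peaks, +/- 500 kbp gene window.
    """

    def __init__(self, min_maf: float = 0.05, peak_distance: int = 2_000_000,
                 top_n: int = 10, gene_window: int = 500_000):
        self.min_maf = min_maf
        self.peak_distance = peak_distance
        self.top_n = top_n
        self.gene_window = gene_window

    def fit(self, G: pd.DataFrame, y, snp_map: pd.DataFrame | None = None):
        self.genotypes_ = maf_filter(G, self.min_maf)
        self.kinship_ = kinship(self.genotypes_)
        self.result_ = lmm_assoc(y, self.genotypes_, self.kinship_)
        if snp_map is not None:
            tab = self.result_.table.join(snp_map[["chrom", "pos"]])
            self.result_.table = tab
            self.peaks_ = select_peaks(tab, self.peak_distance, self.top_n)
        return self


def select_peaks(results: pd.DataFrame, min_distance: int = 2_000_000,
                 top_n: int = 10) -> pd.DataFrame:
    """Greedy peak thinning: best p first, enforcing per-chromosome spacing."""
    needed = {"chrom", "pos", "p"}
    if not needed.issubset(results.columns):
        raise ValueError(f"results must carry columns {sorted(needed)}")
    ranked = results.sort_values("p", kind="stable")
    accepted: list = []
    for _, row in ranked.iterrows():
        ok = all(
            row["chrom"] != a["chrom"] or abs(row["pos"] - a["pos"]) >= min_distance
            for a in accepted
        )
        if ok:
            accepted.append(row)
            if len(accepted) >= top_n:
                break
    return pd.DataFrame(accepted)


def nearest_genes(snp_chrom: str, snp_pos: int, annotation: pd.DataFrame,
                  window: int = 500_000) -> pd.DataFrame:
    """Genes overlapping the closed +/- window around a SNP, nearest first.

    ``annotation`` needs columns gene, chrom, start, end (1-based inclusive).
    Distance is 0 for genes containing the SNP, else the gap to the nearest
    interval edge.
    """
    ann = annotation[annotation["chrom"] == snp_chrom]
    lo, hi = snp_pos - window, snp_pos + window
    hits = ann[(ann["end"] >= lo) & (ann["start"] <= hi)].copy()
    dist = np.where(
        (hits["start"] <= snp_pos) & (hits["end"] >= snp_pos),
        0,
        np.minimum(np.abs(hits["start"] - snp_pos), np.abs(hits["end"] - snp_pos)),
    )
    hits["distance"] = dist
    return hits.sort_values(["distance", "start"], kind="stable").reset_index(drop=True)


def allele_group_test(y, genotypes, direction: str = "greater") -> tuple[float, float]:
    """One-sided Welch t-test of DNAm age between the two allele groups.

    ``direction='greater'`` tests whether carriers of allele 1 have greater
    DNAm age than carriers of allele 0. Returns (t, p).
    """
    yv = np.asarray(y, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    g0, g1 = yv[g == 0.0], yv[g == 1.0]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("both allele groups need at least 2 strains")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    t, p = stats.ttest_ind(g1, g0, equal_var=False, alternative=direction)
    return float(t), float(p)
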