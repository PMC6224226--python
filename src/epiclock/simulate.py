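"""Synthetic RRBS-like methylation datasets and inbred genotype panels.

The methylome generator emulates the statistical regime the pipeline is built
for: per-CpG binomial read counts with negative-binomial (overdispersed)
coverage split across the two strands, a logit-linear age drift at a minority
of sites, per-batch (tissue x study) methylation offsets, and optional
intervention arms whose *effective* age is decelerated by a fixed number of
months. Missing measurements arise mechanistically — a strand with zero
sampled reads emits no record, and shallow cells fail the Jeffreys
confidence filter downstream — rather than by masking at random.

The genotype generator produces a cluster-structured inbred panel
(Balding-Nichols-style allele-frequency divergence) with an optional causal
SNP and a polygenic phenotype component, so kinship correction in the GWAS
module is exercised against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import site_id

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_methylomes",
    "simulate_genotypes",
]


@dataclass(frozen=True)
class InterventionArm:
    label: str                  # treatment group label, e.g. "CR"
    deceleration: float         # months subtracted from effective age
    n_per_group: int = 20
    age_range: tuple[float, float] = (10.0, 25.0)
    tissue: str = "liver"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the default synthetic dataset.

    300 baseline samples over 5000 CpGs, of which 200 drift linearly with
    age on the logit scale; four batches (2 tissues x 2 studies) with
    per-site batch offsets; lifespan-wide ages; RRBS-like mean coverage of
    40 pooled reads per CpG with negative-binomial overdispersion, matching
    the post-filter high-quality regime the clocks are trained on.
    """

    n_samples: int = 300
    n_sites: int = 5000
    n_age_sites: int = 200
    age_range: tuple[float, float] = (1.0, 32.0)
    tissues: tuple[str, ...] = ("liver", "blood")
    studies: tuple[str, ...] = ("study1", "study2")
    batch_sd: float = 1.0             # SD of per-(batch, site) logit offsets
    slope_range: tuple[float, float] = (0.02, 0.10)   # |slope|, logit/month
    baseline_sd: float = 1.5          # SD of per-site logit baselines
    coverage_mean: float = 40.0       # reads per CpG (both strands)
    coverage_dispersion: float = 5.0  # negative-binomial size per strand
    interventions: tuple[InterventionArm, ...] = ()
    conserved_fraction: float = 0.1
    seed: int = 1

    def with_interventions(self, *arms: InterventionArm) -> "SyntheticConfig":
        return replace(self, interventions=tuple(arms))


@dataclass
class SyntheticTruth:
    baselines: np.ndarray             # per-site logit baseline
    slopes: np.ndarray                # per-site logit slope (0 off age sites)
    age_sites: list                   # site ids with non-zero slope
    batch_offsets: dict               # batch -> per-site logit offset array
    effective_ages: pd.Series         # chronological minus deceleration
    conserved_sites: list


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _negbin(rng, mean: float, size_param: float, shape) -> np.ndarray:
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=shape)


def simulate_methylomes(config: SyntheticConfig | None = None):
    """Generate per-sample count tables, metadata, truth and conserved list.

    Returns ``(tables, metadata, truth, conserved)`` where ``tables`` maps
    sample id to a native-dialect record DataFrame (chrom, pos, strand,
    meth, total; forward and reverse strand rows per CpG), ``metadata``
    matches the sample sheet schema, and ``conserved`` is a BED-like
    DataFrame of the sites flagged as evolutionarily conserved. Fully
    deterministic given ``config.seed``.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # site coordinates: CpGs every 50 bp on two chromosomes
    per_chrom = int(np.ceil(cfg.n_sites / 2))
    chroms = np.array(["chr1"] * per_chrom + ["chr2"] * (cfg.n_sites - per_chrom))
    positions = np.concatenate([
        100 + 50 * np.arange(per_chrom),
        100 + 50 * np.arange(cfg.n_sites - per_chrom),
    ])
    sites = [site_id(c, p) for c, p in zip(chroms, positions)]

    baselines = rng.normal(0.0, cfg.baseline_sd, cfg.n_sites)
    slopes = np.zeros(cfg.n_sites)
    age_idx = rng.choice(cfg.n_sites, size=cfg.n_age_sites, replace=False)
    lo, hi = cfg.slope_range
    mags = rng.uniform(lo, hi, cfg.n_age_sites)
    signs = rng.choice([-1.0, 1.0], cfg.n_age_sites)
    slopes[age_idx] = mags * signs
    # keep age sites in a responsive methylation range at mid-life
    mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])
    baselines[age_idx] = rng.normal(0.0, 0.75, cfg.n_age_sites) - slopes[age_idx] * mid_age

    batches = [(t, s) for t in cfg.tissues for s in cfg.studies]
    batch_offsets = {
        f"{t}|{s}": rng.normal(0.0, cfg.batch_sd, cfg.n_sites) for t, s in batches
    }

    rows = []
    for i in range(cfg.n_samples):
        t, s = batches[i % len(batches)]
        age = rng.uniform(*cfg.age_range)
        rows.append((f"S{i:04d}", t, s, age, "C57BL/6", "control", age))
    for arm in cfg.interventions:
        study = f"exp_{arm.label}"
        if f"{arm.tissue}|{study}" not in batch_offsets:
            batch_offsets[f"{arm.tissue}|{study}"] = rng.normal(
                0.0, cfg.batch_sd, cfg.n_sites
            )
        for grp, shift in ((arm.label, arm.deceleration), (f"{arm.label}_control", 0.0)):
            for j in range(arm.n_per_group):
                age = rng.uniform(*arm.age_range)
                rows.append((
                    f"S_{arm.label}_{grp}_{j:03d}", arm.tissue, study, age,
                    "C57BL/6", grp, age - shift,
                ))
    metadata = pd.DataFrame(
        rows,
        columns=["sample_id", "tissue", "study", "age", "strain", "group", "_eff"],
    )
    effective = pd.Series(metadata.pop("_eff").to_numpy(),
                          index=metadata["sample_id"], name="effective_age")
    metadata = metadata.set_index("sample_id", drop=False)

    tables: dict[str, pd.DataFrame] = {}
    for sid in metadata.index:
        t, s = metadata.loc[sid, "tissue"], metadata.loc[sid, "study"]
        off = batch_offsets[f"{t}|{s}"]
        mu = _invlogit(baselines + slopes * effective[sid] + off)
        n_f = _negbin(rng, cfg.coverage_mean / 2, cfg.coverage_dispersion, cfg.n_sites)
        n_r = _negbin(rng, cfg.coverage_mean / 2, cfg.coverage_dispersion, cfg.n_sites)
        k_f = rng.binomial(n_f, mu)
        k_r = rng.binomial(n_r, mu)
        rec = pd.DataFrame({
            "chrom": np.concatenate([chroms, chroms]),
            "pos": np.concatenate([positions, positions + 1]),
            "strand": np.array(["+"] * cfg.n_sites + ["-"] * cfg.n_sites),
            "meth": np.concatenate([k_f, k_r]),
            "total": np.concatenate([n_f, n_r]),
        })
        tables[sid] = rec[rec["total"] > 0].reset_index(drop=True)

    n_cons = int(round(cfg.conserved_fraction * cfg.n_sites))
    cons_idx = np.sort(rng.choice(cfg.n_sites, size=n_cons, replace=False))
    conserved = pd.DataFrame({
        "chrom": chroms[cons_idx],
        "start": positions[cons_idx] - 1,   # BED 0-based
        "end": positions[cons_idx] + 1,     # CpG dinucleotide
    })
    truth = SyntheticTruth(
        baselines=baselines,
        slopes=slopes,
        age_sites=[sites[j] for j in np.sort(age_idx)],
        batch_offsets=batch_offsets,
        effective_ages=effective,
        conserved_sites=[sites[j] for j in cons_idx],
    )
    return tables, metadata, truth, conserved


def simulate_genotypes(
    n_strains: int = 80,
    n_snps: int = 2000,
    n_clusters: int = 4,
    fst_like: float = 0.15,
    causal: tuple[int, float] | None = None,
    h2_poly: float = 0.3,
    mean_pheno: float = 4.2,
    seed: int = 1,
):
    """Cluster-structured inbred genotypes with a phenotype of known origin.

    Allele frequencies diverge between clusters Balding-Nichols style with
    divergence parameter ``fst_like`` (0 gives an unstructured panel). The
    phenotype (months of DNAm age) is mean + causal-SNP effect + polygenic
    term of heritability ``h2_poly`` + residual noise, with the non-causal
    variance scaled to 1 month^2. Returns
    ``(G, snp_map, phenotype, truth)``.
    """
    if not 0.0 < h2_poly < 1.0:
        raise ValueError("h2_poly must lie strictly between 0 and 1")
    if not 0.0 <= fst_like < 1.0:
        raise ValueError("fst_like must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    p0 = rng.uniform(0.1, 0.9, n_snps)
    if fst_like > 0.0:
        a = p0 * (1.0 - fst_like) / fst_like
        b = (1.0 - p0) * (1.0 - fst_like) / fst_like
        freqs = rng.beta(a, b, size=(n_clusters, n_snps))
    else:
        freqs = np.tile(p0, (n_clusters, 1))
    cluster = rng.integers(0, n_clusters, n_strains)
    G = (rng.random((n_strains, n_snps)) < freqs[cluster]).astype(float)

    strains = [f"strain{i:03d}" for i in range(n_strains)]
    snps = [f"snp{j:05d}" for j in range(n_snps)]
    per_chrom = int(np.ceil(n_snps / 2))
    chroms = ["chr1"] * per_chrom + ["chr2"] * (n_snps - per_chrom)
    positions = np.concatenate([
        1_000_000 + 100_000 * np.arange(per_chrom),
        1_000_000 + 100_000 * np.arange(n_snps - per_chrom),
    ])
    snp_map = pd.DataFrame({"snp": snps, "chrom": chroms, "pos": positions}
                           ).set_index("snp", drop=False)

    sd = G.std(axis=0)
    W = (G - G.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    weights = rng.normal(0.0, 1.0, n_snps) / np.sqrt(n_snps)
    poly_raw = W @ weights
    poly_sd = poly_raw.std()
    poly = poly_raw / (poly_sd if poly_sd > 0 else 1.0) * np.sqrt(h2_poly)
    noise = rng.normal(0.0, np.sqrt(1.0 - h2_poly), n_strains)
    y = mean_pheno + poly + noise
    causal_idx, causal_effect = (None, 0.0)
    if causal is not None:
        causal_idx, causal_effect = int(causal[0]), float(causal[1])
        y = y + causal_effect * G[:, causal_idx]

    Gdf = pd.DataFrame(G, index=pd.Index(strains, name="strain"), columns=snps)
    pheno = pd.Series(y, index=Gdf.index, name="dnam_age")
    truth = {
        "cluster": dict(zip(strains, cluster.tolist())),
        "causal_snp": snps[causal_idx] if causal_idx is not None else None,
        "causal_effect": causal_effect,
        "h2_poly": h2_poly,
    }
    return Gdf, snp_map, pheno, truth
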