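"""Readers and writers for every on-disk artifact of the pipeline.

All genomic coordinates are 1-based internally; a CpG site is identified by
the position of its forward-strand cytosine and written as ``"chrom:pos"``.
BED input (0-based, half-open) is converted at the boundary. Matrix TSVs use
the literal string ``NA`` for missing cells and 10 significant digits for
real values; clock-model files store coefficients at full float precision so
that write/read round-trips are exact.
"""

from __future__ import annotations

import hashlib
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SiteKey",
    "FormatError",
    "site_id",
    "parse_site_id",
    "read_counts",
    "read_metadata",
    "read_site_list",
    "read_matrix",
    "write_matrix",
    "read_clock",
    "write_clock",
    "read_genotypes",
    "write_gwas_results",
]


class SiteKey(NamedTuple):
    """A CpG site: chromosome plus 1-based forward-strand C position."""

    chrom: str
    pos: int


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


def site_id(chrom: str, pos: int) -> str:
    return f"{chrom}:{int(pos)}"


def parse_site_id(s: str) -> SiteKey:
    chrom, _, pos = s.rpartition(":")
    if not chrom:
        raise FormatError(f"malformed site id {s!r}")
    return SiteKey(chrom, int(pos))


# ---------------------------------------------------------------------------
# CpG count tables

_NATIVE_COLS = ["chrom", "pos", "strand", "meth", "total"]
_BISMARK_COLS = ["chrom", "start", "end", "pct", "meth", "unmeth"]


def read_counts(path, dialect: str = "native") -> pd.DataFrame:
    """Read a per-sample CpG count table.

    ``native`` dialect: chrom, pos (1-based), strand, methylated count,
    total count. ``bismark_cov`` dialect: chrom, start, end, percent,
    methylated, unmethylated — position taken as ``start``, strand assumed
    "+", total = methylated + unmethylated.

    Returns a DataFrame with columns chrom, pos, strand, meth, total.
    """
    if dialect == "native":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if raw.shape[1] != len(_NATIVE_COLS):
            raise FormatError(
                f"{path}: expected {len(_NATIVE_COLS)} native columns "
                f"(chrom, pos, strand, meth, total), found {raw.shape[1]}"
            )
        raw.columns = _NATIVE_COLS
        df = raw
    elif dialect == "bismark_cov":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if raw.shape[1] != len(_BISMARK_COLS):
            raise FormatError(
                f"{path}: expected {len(_BISMARK_COLS)} Bismark-coverage "
                f"columns, found {raw.shape[1]}"
            )
        raw.columns = _BISMARK_COLS
        df = pd.DataFrame(
            {
                "chrom": raw["chrom"],
                "pos": raw["start"],
                "strand": "+",
                "meth": raw["meth"],
                "total": "",  # filled below
            }
        )
        meth = _to_int(raw["meth"], path, "meth")
        unmeth = _to_int(raw["unmeth"], path, "unmeth")
        df["meth"] = meth
        df["total"] = meth + unmeth
    else:
        raise ValueError(f"unknown count dialect {dialect!r}")

    df = df.copy()
    df["pos"] = _to_int(df["pos"], path, "pos")
    df["meth"] = _to_int(df["meth"], path, "meth")
    df["total"] = _to_int(df["total"], path, "total")
    _reject(df["pos"] < 1, path, "position < 1")
    _reject(df["meth"] < 0, path, "negative methylated count")
    _reject(df["meth"] > df["total"], path, "methylated count exceeds total")
    bad_strand = ~df["strand"].isin(["+", "-"])
    _reject(bad_strand, path, "strand not in {+,-}")
    df["chrom"] = df["chrom"].astype(str)
    return df.reset_index(drop=True)


def _to_int(col: pd.Series, path, name: str) -> pd.Series:
    out = pd.to_numeric(col, errors="coerce")
    _reject(out.isna() | (out != np.floor(out.fillna(0))), path,
            f"non-integer value in column {name!r}")
    return out.astype(int)


def _reject(bad: pd.Series, path, what: str) -> None:
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
        shown = ", ".join(map(str, lines[:5]))
        more = "" if len(lines) <= 5 else f" (+{len(lines) - 5} more)"
        raise FormatError(f"{path}: {what} at line(s) {shown}{more}")


# ---------------------------------------------------------------------------
# Sample metadata

METADATA_COLUMNS = ["sample_id", "tissue", "study", "age", "strain", "group"]


def read_metadata(path) -> pd.DataFrame:
    """Read the sample sheet; returns a DataFrame indexed by sample_id.

    Age is chronological age in months. Slightly negative (embryonic) ages
    are accepted down to -1 month exclusive.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    age = pd.to_numeric(df["age"], errors="coerce")
    _reject(age.isna(), path, "unparsable age")
    _reject(age <= -1.0, path, "age not > -1 month")
    df["age"] = age.astype(float)
    dup = df["sample_id"].duplicated(keep=False)
    if dup.any():
        dups = sorted(df.loc[dup, "sample_id"].unique())
        raise FormatError(f"{path}: duplicate sample_id(s): {dups}")
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# Conserved-site BED lists

def read_site_list(path) -> set[SiteKey]:
    """Read a BED file of CpG sites into forward-strand SiteKeys.

    Intervals must have length 1 (the C) or 2 (the CpG dinucleotide); the
    0-based start maps to the 1-based C position.
    """
    sites: set[SiteKey] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: fewer than 3 BED fields at line {lineno}")
            chrom, start, end = fields[0], fields[1], fields[2]
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}: non-integer interval at line {lineno}")
            if e - s not in (1, 2) or s < 0:
                raise FormatError(
                    f"{path}: interval length {e - s} at line {lineno} is not a CpG"
                )
            sites.add(SiteKey(chrom, s + 1))
    return sites


# ---------------------------------------------------------------------------
# Methylation matrix TSV

def write_matrix(values: pd.DataFrame, path) -> None:
    """Write a samples x sites matrix; NaN cells become the literal "NA"."""
    out = values.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    """Read a samples x sites matrix TSV (missing cells = "NA")."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0.0) | (vals > 1.0)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: methylation value {vals[i, j]} outside [0,1] "
            f"(sample {df.index[i]!r}, site {df.columns[j]!r})"
        )
    for c in df.columns:  # validate site ids early
        parse_site_id(c)
    return df.astype(float)


# ---------------------------------------------------------------------------
# Clock model files

def training_hash(sample_ids: Iterable[str]) -> str:
    h = hashlib.sha256("\n".join(sorted(map(str, sample_ids))).encode())
    return h.hexdigest()[:16]


def write_clock(model, path) -> None:
    """Serialize a fitted ClockModel with a '#'-prefixed header block."""
    with open(path, "w") as fh:
        fh.write(f"# alpha\t{float(model.alpha)!r}\n")
        fh.write(f"# lambda\t{float(model.lam)!r}\n")
        fh.write(f"# intercept\t{float(model.intercept)!r}\n")
        fh.write(f"# training_hash\t{model.training_hash}\n")
        fh.write(f"# n_sites\t{len(model.training_sites)}\n")
        fh.write("chrom\tpos\tcoefficient\n")
        for site in model.training_sites:
            chrom, pos = parse_site_id(site)
            fh.write(f"{chrom}\t{pos}\t{float(model.coefficients[site])!r}\n")


def read_clock(path):
    """Read a clock-model file back into a ClockModel (exact round trip)."""
    from .clock import ClockModel  # local import: clock does not import io

    header: dict[str, str] = {}
    rows: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                header[key.strip()] = value
            elif line and not line.startswith("chrom\t"):
                chrom, pos, coef = line.split("\t")
                rows.append((chrom, int(pos), float(coef)))
    for key in ("alpha", "lambda", "intercept"):
        if key not in header:
            raise FormatError(f"{path}: clock header missing {key!r}")
    sites = [site_id(c, p) for c, p, _ in rows]
    coefs = pd.Series([v for _, _, v in rows], index=sites, dtype=float)
    n_sites = int(header.get("n_sites", len(sites)))
    if n_sites != len(sites):
        raise FormatError(f"{path}: header n_sites={n_sites} but {len(sites)} rows")
    return ClockModel(
        intercept=float(header["intercept"]),
        coefficients=coefs,
        alpha=float(header["alpha"]),
        lam=float(header["lambda"]),
        training_sites=sites,
        training_hash=header.get("training_hash", ""),
    )


# ---------------------------------------------------------------------------
# Genotypes

_MISSING_GENO = {"H", "N", "NA", ""}


def read_genotypes(geno_path, map_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an inbred-panel genotype table plus its SNP map.

    Genotype TSV: first column ``strain``, one column per SNP, entries 0/1
    (homozygous major/minor); ``H``/``N`` are heterozygous/unknown and are
    returned as NaN. Map TSV: columns snp, chrom, pos (1-based). SNP columns
    are reordered by (chrom, pos).
    """
    geno = pd.read_csv(geno_path, sep="\t", dtype=str).set_index("strain")
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"snp": str, "chrom": str})
    for col in ("snp", "chrom", "pos"):
        if col not in snp_map.columns:
            raise FormatError(f"{map_path}: missing map column {col!r}")
    snp_map["pos"] = snp_map["pos"].astype(int)
    if set(snp_map["snp"]) != set(geno.columns) or len(snp_map) != geno.shape[1]:
        raise FormatError(
            f"{map_path}: map lists {len(snp_map)} SNPs but genotype table "
            f"has {geno.shape[1]} columns (sets must match exactly)"
        )
    G = geno.replace(dict.fromkeys(_MISSING_GENO, np.nan))
    G = G.apply(pd.to_numeric)
    vals = G.to_numpy(dtype=float)
    ok = np.isnan(vals) | (vals == 0.0) | (vals == 1.0)
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise FormatError(
            f"{geno_path}: genotype {vals[i, j]} for strain {G.index[i]!r}, "
            f"SNP {G.columns[j]!r} not in {{0,1,H,N}}"
        )
    snp_map = snp_map.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    G = G.loc[:, snp_map["snp"].tolist()].astype(float)
    return G, snp_map.set_index("snp", drop=False)


def write_gwas_results(results: pd.DataFrame, path) -> None:
    cols = ["snp", "chrom", "pos", "beta", "stat", "p"]
    results.loc[:, cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
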