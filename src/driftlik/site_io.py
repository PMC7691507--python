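"""Read, validate, orient and filter pooled-sequencing site tables.

The working representation of a site table is a pandas DataFrame with one
row per site x population x generation x DNA sample, columns::

    chrom  pos  ref  alt  population  generation  sample  ref_count  alt_count  maxqual

Coordinates are 1-based (VCF convention).  A :class:`SiteRecord` dataclass
and ``to_records``/``from_records`` converters are provided for callers
that prefer typed records.

Orientation follows the founder convention: the minor allele of a site is
the allele least frequent in the founding (generation 0) population, fixed
once per site, and every later frequency is expressed for that allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SCHEMA",
    "DEFAULT_CHROMOSOMES",
    "SiteRecord",
    "SiteTableError",
    "read_site_table",
    "read_sync",
    "read_vcf",
    "write_site_table",
    "to_records",
    "from_records",
    "combine_samples",
    "coverage_filter",
    "orient_to_founder_minor",
    "hpd_interval",
]

SCHEMA = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "population",
    "generation",
    "sample",
    "ref_count",
    "alt_count",
    "maxqual",
]

DEFAULT_CHROMOSOMES = ("2L", "2R", "3L", "3R", "X", "4")


class SiteTableError(ValueError):
    """Raised for malformed site tables; message lists offending rows."""


@dataclass(frozen=True)
class SiteRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    population: str
    generation: int
    sample: str
    ref_count: int
    alt_count: int
    maxqual: float | None = None

    @property
    def coverage(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_frequency(self) -> float:
        return self.alt_count / self.coverage if self.coverage else np.nan


def _validate(df: pd.DataFrame, chromosomes, strict: bool) -> pd.DataFrame:
    missing = [c for c in SCHEMA if c not in df.columns and c != "maxqual"]
    if missing:
        raise SiteTableError(f"missing required columns: {missing}")
    if "maxqual" not in df.columns:
        df["maxqual"] = np.nan
    bad = pd.Series(False, index=df.index)
    reasons = {}

    def flag(mask, reason):
        idx = df.index[mask & ~bad]
        for i in idx:
            reasons.setdefault(i, reason)
        return mask

    bad |= flag(df["pos"].astype("Int64").isna() | (df["pos"] < 1), "position < 1")
    bad |= flag(
        (df["ref_count"] < 0) | (df["alt_count"] < 0), "negative read count"
    )
    if chromosomes is not None:
        bad |= flag(~df["chrom"].isin(chromosomes), "unknown chromosome")
    if bad.any():
        # report 1-based data-row numbers (header is row 0)
        rows = ", ".join(
            f"row {i + 1}: {reasons[i]}" for i in df.index[bad][:20]
        )
        if strict:
            raise SiteTableError(f"{int(bad.sum())} malformed rows ({rows})")
        warnings.warn(f"dropping {int(bad.sum())} malformed rows ({rows})")
        df = df[~bad]
    out = df.copy()
    out["pos"] = out["pos"].astype(np.int64)
    out["generation"] = out["generation"].astype(np.int64)
    out["ref_count"] = out["ref_count"].astype(np.int64)
    out["alt_count"] = out["alt_count"].astype(np.int64)
    out["sample"] = out["sample"].astype(str)
    out["maxqual"] = out["maxqual"].astype(float)
    return out.reset_index(drop=True)


def read_site_table(
    path,
    fmt: str = "tsv",
    chromosomes=DEFAULT_CHROMOSOMES,
    strict: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Read and validate a site table.

    ``fmt='tsv'`` expects the native schema; ``fmt='sync'`` delegates to
    :func:`read_sync`.  Malformed rows raise :class:`SiteTableError` with
    row numbers (``strict=False`` drops them with a warning instead).
    """
    if fmt == "sync":
        return read_sync(path, chromosomes=chromosomes, **kwargs)
    if fmt != "tsv":
        raise ValueError(f"unknown format {fmt!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    if df.empty:
        warnings.warn(f"{path}: empty site table")
        for c in SCHEMA:
            if c not in df.columns:
                df[c] = pd.Series(dtype=object)
        return df[SCHEMA]
    return _validate(df, chromosomes, strict)


_SYNC_BASES = ("A", "T", "C", "G")


def read_sync(
    path,
    populations,
    generation: int,
    chromosomes=DEFAULT_CHROMOSOMES,
    strict: bool = True,
) -> pd.DataFrame:
    """Import a SYNC-style count file (chrom, pos, ref, A:T:C:G:N:del per pool).

    The alternate allele is the most frequent non-reference base summed over
    pools; sites with no non-reference reads are dropped.
    """
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    n_pools = raw.shape[1] - 3
    if n_pools != len(populations):
        raise SiteTableError(
            f"{n_pools} count columns but {len(populations)} population labels"
        )
    counts = np.zeros((len(raw), n_pools, 6), dtype=np.int64)
    for j in range(n_pools):
        counts[:, j, :] = np.array(
            [list(map(int, v.split(":"))) for v in raw.iloc[:, 3 + j]]
        )
    ref = raw.iloc[:, 2].str.upper().to_numpy()
    base_idx = {b: i for i, b in enumerate(_SYNC_BASES)}
    rows = []
    for i in range(len(raw)):
        ri = base_idx.get(ref[i])
        if ri is None:
            continue
        tot = counts[i].sum(axis=0)
        nonref = [(b, tot[base_idx[b]]) for b in _SYNC_BASES if b != ref[i]]
        alt, alt_tot = max(nonref, key=lambda t: t[1])
        if alt_tot == 0:
            continue
        for j, popn in enumerate(populations):
            rows.append(
                (
                    raw.iat[i, 0],
                    int(raw.iat[i, 1]),
                    ref[i],
                    alt,
                    popn,
                    generation,
                    "1",
                    int(counts[i, j, base_idx[ref[i]]]),
                    int(counts[i, j, base_idx[alt]]),
                    np.nan,
                )
            )
    df = pd.DataFrame(rows, columns=SCHEMA)
    return _validate(df, chromosomes, strict) if len(df) else df


def read_vcf(
    path,
    generation: int,
    chromosomes=DEFAULT_CHROMOSOMES,
    strict: bool = True,
) -> pd.DataFrame:
    """Import biallelic records from a VCF with per-sample AD fields.

    Each VCF sample column becomes one population (sample label "1").
    Requires the optional ``cyvcf2`` dependency.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    rows = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        for s, name in enumerate(vcf.samples):
            rows.append(
                (
                    var.CHROM,
                    var.POS,
                    var.REF,
                    var.ALT[0],
                    name,
                    generation,
                    "1",
                    int(ad[s][0]),
                    int(ad[s][1]),
                    float(var.QUAL) if var.QUAL is not None else np.nan,
                )
            )
    df = pd.DataFrame(rows, columns=SCHEMA)
    return _validate(df, chromosomes, strict) if len(df) else df


def write_site_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def to_records(df: pd.DataFrame) -> list[SiteRecord]:
    return [
        SiteRecord(
            chrom=r.chrom,
            pos=int(r.pos),
            ref=r.ref,
            alt=r.alt,
            population=r.population,
            generation=int(r.generation),
            sample=str(r.sample),
            ref_count=int(r.ref_count),
            alt_count=int(r.alt_count),
            maxqual=None if pd.isna(r.maxqual) else float(r.maxqual),
        )
        for r in df.itertuples(index=False)
    ]


def from_records(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=SCHEMA)


def combine_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate DNA samples into one count pair per site x population.

    ``maxqual`` keeps the per-site maximum.  Pool-level frequencies (as
    plotted per population) are computed from the summed counts.
    """
    grouped = (
        df.groupby(
            ["chrom", "pos", "ref", "alt", "population", "generation"],
            as_index=False,
            sort=True,
        )
        .agg(
            ref_count=("ref_count", "sum"),
            alt_count=("alt_count", "sum"),
            maxqual=("maxqual", "max"),
        )
    )
    grouped["sample"] = "combined"
    return grouped[SCHEMA]


def coverage_filter(
    df: pd.DataFrame, min_total: int = 10, max_total: int = 226
) -> pd.DataFrame:
    """Keep rows with min_total <= coverage < max_total (default 10..225).

    The upper bound is exclusive: 226 is the 99.5% point of the coverage
    distribution and is itself removed.  Idempotent.
    """
    cov = df["ref_count"] + df["alt_count"]
    return df[(cov >= min_total) & (cov < max_total)].reset_index(drop=True)


def orient_to_founder_minor(
    df: pd.DataFrame,
    founder: pd.DataFrame | None = None,
    founder_generation: int = 0,
) -> pd.DataFrame:
    """Orient every row's frequency to the founder-generation minor allele.

    The minor allele is the least frequent allele at the founder generation
    (counts summed over all founder samples/populations), fixed per site.
    Exact 50/50 founder ties break deterministically to the alternate
    allele and are flagged in ``founder_tie``.  Re-orienting an oriented
    table is a no-op (all columns are recomputed from counts).
    """
    if founder is None:
        founder = df[df["generation"] == founder_generation]
    else:
        founder = founder[founder["generation"] == founder_generation]
    if founder.empty:
        raise SiteTableError("no founder-generation rows available")
    f = (
        founder.groupby(["chrom", "pos"], as_index=False)[
            ["ref_count", "alt_count"]
        ].sum()
    )
    cov = f["ref_count"] + f["alt_count"]
    if (cov == 0).any():
        raise SiteTableError("founder coverage is zero at some sites")
    alt_freq = f["alt_count"] / cov
    f["minor_is_alt"] = alt_freq <= 0.5  # tie -> alt, flagged below
    f["founder_tie"] = alt_freq == 0.5
    f["founder_minor_freq"] = np.where(f["minor_is_alt"], alt_freq, 1 - alt_freq)
    merged = df.drop(
        columns=[
            c
            for c in (
                "minor_is_alt",
                "founder_tie",
                "founder_minor_freq",
                "minor_allele",
                "oriented_frequency",
            )
            if c in df.columns
        ]
    ).merge(
        f[["chrom", "pos", "minor_is_alt", "founder_tie", "founder_minor_freq"]],
        on=["chrom", "pos"],
        how="left",
    )
    if merged["minor_is_alt"].isna().any():
        missing = merged.loc[
            merged["minor_is_alt"].isna(), ["chrom", "pos"]
        ].drop_duplicates()
        raise SiteTableError(
            f"{len(missing)} sites absent from the founder table, e.g. "
            f"{missing.head(3).to_dict('records')}"
        )
    cov = merged["ref_count"] + merged["alt_count"]
    with np.errstate(invalid="ignore"):
        alt_freq = np.where(cov > 0, merged["alt_count"] / cov, np.nan)
    merged["minor_allele"] = np.where(
        merged["minor_is_alt"], merged["alt"], merged["ref"]
    )
    merged["oriented_frequency"] = np.where(
        merged["minor_is_alt"], alt_freq, 1 - alt_freq
    )
    return merged


def hpd_interval(
    successes: int,
    total: int,
    mass: float = 0.95,
    prior: tuple[float, float] = (0.5, 0.5),
) -> tuple[float, float]:
    """Highest-posterior-density interval for a binomial read proportion.

    Posterior is Beta(successes + a, total - successes + b) with a Jeffreys
    Beta(1/2, 1/2) prior by default.  When the posterior mode sits at a
    boundary the interval is one-sided from that boundary; otherwise the
    shortest interval containing ``mass`` is found by minimising the width
    of [ppf(q), ppf(q + mass)] over the lower tail probability q.
    """
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= successes <= total:
        raise ValueError("successes must be in [0, total]")
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    a = successes + prior[0]
    b = total - successes + prior[1]
    post = stats.beta(a, b)
    if a <= 1.0:  # mode at 0
        return 0.0, float(post.ppf(mass))
    if b <= 1.0:  # mode at 1
        return float(post.ppf(1.0 - mass)), 1.0
    res = optimize.minimize_scalar(
        lambda q: post.ppf(q + mass) - post.ppf(q),
        bounds=(0.0, 1.0 - mass),
        method="bounded",
        options={"xatol": 1e-12},
    )
    q = float(res.x)
    return float(post.ppf(q)), float(post.ppf(q + mass))
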