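"""Filter cascade for putative de novo mutations.

A candidate variant is called de novo only if it

1. is absent from the known-variant catalog (``exclude_known``),
2. passes the quality gates (``quality_filters``): caller quality score
   >= 124, total reads within [40, 226], and a MaxQual score >= 426,
3. is private to one replicate population — present in *both* DNA samples
   of exactly one population and in no sample of any other
   (``privacy_filter``), and
4. never appeared in any generation of the prior selection phase
   (``prior_study_filter``).

Each filter is a pure predicate on the candidate, so the four commute:
any application order yields the same surviving set.  For attrition
accounting a removed candidate is charged to the first failing filter in
the order above, while its reason codes list every failing filter.

Note the read-count bounds here are inclusive [40, 226], following the
stated de novo thresholds; the biallelic analysis coverage filter uses an
exclusive upper bound (10 <= cov < 226) per its own definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_POPULATIONS",
    "DEFAULT_SAMPLES",
    "FilterThresholds",
    "DenovoCandidate",
    "CascadeResult",
    "candidates_from_table",
    "catalog_keys",
    "exclude_known",
    "quality_filters",
    "privacy_filter",
    "prior_study_filter",
    "run_cascade",
]

DEFAULT_POPULATIONS = (
    "short1",
    "short2",
    "long1",
    "long2",
    "control1",
    "control2",
)
DEFAULT_SAMPLES = ("1", "2")

FILTER_ORDER = ("known_in_catalog", "quality", "privacy", "prior_study")


@dataclass(frozen=True)
class FilterThresholds:
    """Configurable gates of the quality filter."""

    min_quality: float = 124.0
    min_reads: int = 40
    max_reads: int = 226  # inclusive
    min_maxqual: float = 426.0
    min_alt_reads_presence: int = 1


@dataclass
class DenovoCandidate:
    chrom: str
    pos: int
    ref: str
    alt: str
    presence: dict  # (population, sample) -> bool
    total_reads: int
    quality_score: float
    maxqual: float

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1

    def carrier_population(
        self, populations=DEFAULT_POPULATIONS, samples=DEFAULT_SAMPLES
    ) -> str | None:
        """The unique population carrying the variant in both samples, if any."""
        full, partial = [], []
        for p in populations:
            flags = [self.presence.get((p, s), False) for s in samples]
            if all(flags):
                full.append(p)
            elif any(flags):
                partial.append(p)
        if len(full) == 1 and not partial:
            return full[0]
        return None


def catalog_keys(df: pd.DataFrame) -> set:
    """Site keys (chrom, pos, ref, alt) of a catalog or prior-study table."""
    return set(
        zip(df["chrom"], df["pos"].astype(int), df["ref"], df["alt"])
    )


def candidates_from_table(
    df: pd.DataFrame,
    populations=DEFAULT_POPULATIONS,
    samples=DEFAULT_SAMPLES,
    min_alt_reads: int = 1,
) -> list[DenovoCandidate]:
    """Build candidates from a per-sample site table.

    Presence in a (population, sample) means >= ``min_alt_reads``
    supporting alternate reads.  ``total_reads`` is the coverage summed
    over the samples of populations where the variant is present at all.
    ``quality_score``/``maxqual`` take the per-candidate maximum.
    """
    out = []
    qual_col = "quality_score" if "quality_score" in df.columns else None
    for key, grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        presence = {}
        total_reads = 0
        present_pops = set()
        for r in grp.itertuples(index=False):
            here = r.alt_count >= min_alt_reads
            presence[(r.population, str(r.sample))] = here
            if here:
                present_pops.add(r.population)
        for r in grp.itertuples(index=False):
            if r.population in present_pops:
                total_reads += int(r.ref_count + r.alt_count)
        out.append(
            DenovoCandidate(
                chrom=key[0],
                pos=int(key[1]),
                ref=key[2],
                alt=key[3],
                presence=presence,
                total_reads=total_reads,
                quality_score=float(grp[qual_col].max()) if qual_col else np.nan,
                maxqual=float(grp["maxqual"].max()),
            )
        )
    return out


def _fails_known(c: DenovoCandidate, catalog: set) -> bool:
    return c.key in catalog


def _fails_quality(c: DenovoCandidate, th: FilterThresholds) -> bool:
    if any(
        pd.isna(v) for v in (c.quality_score, c.maxqual)
    ):
        return True  # missing quality fields reject the candidate
    return not (
        c.quality_score >= th.min_quality
        and th.min_reads <= c.total_reads <= th.max_reads
        and c.maxqual >= th.min_maxqual
    )


def _fails_privacy(c: DenovoCandidate, populations, samples) -> bool:
    return c.carrier_population(populations, samples) is None


def _fails_prior(c: DenovoCandidate, prior_keys: set) -> bool:
    return c.key in prior_keys


def exclude_known(candidates, catalog: set) -> list[DenovoCandidate]:
    """Remove exact (chrom, pos, ref, alt) catalog matches."""
    return [c for c in candidates if not _fails_known(c, catalog)]


def quality_filters(
    candidates, thresholds: FilterThresholds = FilterThresholds()
) -> list[DenovoCandidate]:
    """Keep candidates passing quality >= 124, reads in [40, 226], maxqual >= 426."""
    return [c for c in candidates if not _fails_quality(c, thresholds)]


def privacy_filter(
    candidates,
    populations=DEFAULT_POPULATIONS,
    samples=DEFAULT_SAMPLES,
) -> list[DenovoCandidate]:
    """Keep candidates present in both samples of exactly one population."""
    return [
        c for c in candidates if not _fails_privacy(c, populations, samples)
    ]


def prior_study_filter(candidates, prior_tables) -> list[DenovoCandidate]:
    """Remove candidates found in any prior-generation table.

    ``prior_tables`` is an iterable of key sets (or DataFrames with the
    site-key columns).
    """
    prior_keys = set()
    for t in prior_tables:
        prior_keys |= t if isinstance(t, set) else catalog_keys(t)
    return [c for c in candidates if not _fails_prior(c, prior_keys)]


@dataclass
class CascadeResult:
    survivors: list
    removed: dict  # candidate key -> list of failing filter names
    attrition: dict  # filter name -> count charged (first-failure order)
    n_input: int
    by_population: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_survivors": len(self.survivors),
            "attrition": dict(self.attrition),
            "by_population": self.by_population,
        }


def run_cascade(
    candidates,
    catalog: set,
    prior_tables=(),
    thresholds: FilterThresholds = FilterThresholds(),
    populations=DEFAULT_POPULATIONS,
    samples=DEFAULT_SAMPLES,
) -> CascadeResult:
    """Apply all four filters; survivors plus per-filter attrition.

    Reason codes list every failing filter per removed candidate; the
    attrition table charges each removal to the first failing filter so
    counts removed plus survivors equal the input count.
    """
    candidates = list(candidates)
    prior_keys = set()
    for t in prior_tables:
        prior_keys |= t if isinstance(t, set) else catalog_keys(t)
    survivors, removed = [], {}
    attrition = {name: 0 for name in FILTER_ORDER}
    by_pop: dict = {}
    for c in candidates:
        fails = []
        if _fails_known(c, catalog):
            fails.append("known_in_catalog")
        if _fails_quality(c, thresholds):
            fails.append("quality")
        if _fails_privacy(c, populations, samples):
            fails.append("privacy")
        if _fails_prior(c, prior_keys):
            fails.append("prior_study")
        if fails:
            removed[c.key] = fails
            attrition[fails[0]] += 1
        else:
            survivors.append(c)
            pop = c.carrier_population(populations, samples)
            kind = "indel" if c.is_indel else "snp"
            by_pop.setdefault(pop, {"snp": 0, "indel": 0})[kind] += 1
    return CascadeResult(
        survivors=survivors,
        removed=removed,
        attrition=attrition,
        n_input=len(candidates),
        by_population=by_pop,
    )
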