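"""Resampling null distributions from putatively neutral sites.

The observed statistic is the mean drift log-likelihood of a fixed set of
variants of interest (126 sites in the default design).  Its null
distribution is built by repeatedly drawing random sets of background
("putatively neutral") sites with the same size and the same per-chromosome
composition as the variant set, and recomputing the set-mean log-likelihood
for each draw.  A variant-set mean far in the lower tail of that null is
evidence that the observed shifts are too improbable for pure drift.

Sampling is without replacement within a set and independent across sets;
sets are chromosome-matched exactly.  Direction-stratified means
(towards-major / towards-minor) are computed per set alongside the overall
mean so that each direction class can be located in its own null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import Direction, compute_logliks
from .wf import PopulationSpec

__all__ = [
    "NullDistribution",
    "LocationReport",
    "LikelihoodRatio",
    "sample_null_sets",
    "locate_observed",
    "likelihood_ratio",
]


@dataclass
class NullDistribution:
    """Set-mean log-likelihoods from resampled neutral site sets."""

    set_size: int
    n_sets: int
    means: np.ndarray
    chromosome_profile: dict
    seed: int | None
    direction_means: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.means) != self.n_sets:
            raise ValueError("means length must equal n_sets")
        if sum(self.chromosome_profile.values()) != self.set_size:
            raise ValueError("chromosome profile must sum to set_size")

    def to_frame(self) -> pd.DataFrame:
        cols = {"mean_loglik": self.means}
        for d, v in self.direction_means.items():
            cols[f"mean_loglik_{d}"] = v
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class LocationReport:
    """Where an observed set mean sits within its resampling null."""

    observed_mean: float
    lower_tail_fraction: float
    z_like_offset: float
    inside_95pct: bool
    degenerate: bool
    n_sets: int

    def to_dict(self) -> dict:
        return {
            "observed_mean": self.observed_mean,
            "lower_tail_fraction": self.lower_tail_fraction,
            "z_like_offset": self.z_like_offset,
            "inside_95pct": self.inside_95pct,
            "degenerate": self.degenerate,
            "n_sets": self.n_sets,
        }


@dataclass(frozen=True)
class LikelihoodRatio:
    """Total-likelihood ratio of two equally sized site sets."""

    ratio: float
    log_ratio: float


def sample_null_sets(
    background_sites: pd.DataFrame,
    target_profile: dict,
    n_sets: int,
    spec: PopulationSpec,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    frequency_match: bool = False,
    frequency_bins: int = 10,
) -> NullDistribution:
    """Draw chromosome-matched random site sets and compute set-mean logliks.

    Parameters
    ----------
    background_sites:
        Site-shift table (columns ``chrom``, ``p_start``, ``p_end``; a
        precomputed ``loglik`` column is reused if present) that must
        already exclude the variants of interest.
    target_profile:
        Mapping chromosome -> number of sites, matching the variant set.
    frequency_match:
        Optionally also match the start-frequency composition of the
        variant set (requires a ``p_start_bin`` column on both sides); off
        by default — the study design matches number and chromosome only.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if "loglik" not in background_sites.columns:
        background_sites = compute_logliks(background_sites, spec)
    set_size = int(sum(target_profile.values()))
    if set_size <= 0:
        raise ValueError("target profile is empty")

    lls = background_sites["loglik"].to_numpy(dtype=float)
    dirs = background_sites["direction"].to_numpy()
    groups: list[tuple[np.ndarray, int]] = []
    if frequency_match:
        bins = np.minimum(
            (background_sites["p_start"].to_numpy() * frequency_bins).astype(int),
            frequency_bins - 1,
        )
        strata = background_sites.groupby(
            [background_sites["chrom"].to_numpy(), bins]
        ).indices
        raise_missing = "chromosome x frequency stratum"
        wanted = target_profile.items()  # profile keys must be (chrom, bin)
        for key, count in wanted:
            idx = strata.get(key)
            if idx is None or len(idx) < count:
                raise ValueError(f"insufficient background sites in {raise_missing} {key}")
            groups.append((np.asarray(idx), int(count)))
    else:
        by_chrom = background_sites.groupby(
            background_sites["chrom"].to_numpy()
        ).indices
        for chrom, count in target_profile.items():
            if count == 0:
                continue
            idx = by_chrom.get(chrom)
            if idx is None or len(idx) < count:
                raise ValueError(
                    f"insufficient background sites on chromosome {chrom}: "
                    f"need {count}, have {0 if idx is None else len(idx)}"
                )
            groups.append((np.asarray(idx), int(count)))

    means = np.empty(n_sets)
    dir_means = {
        Direction.TOWARDS_MAJOR.value: np.full(n_sets, np.nan),
        Direction.TOWARDS_MINOR.value: np.full(n_sets, np.nan),
    }
    for i in range(n_sets):
        chosen = np.concatenate(
            [rng.choice(idx, size=count, replace=False) for idx, count in groups]
        )
        set_ll = lls[chosen]
        set_dir = dirs[chosen]
        means[i] = set_ll.mean()
        for d in dir_means:
            sel = set_dir == d
            if sel.any():
                dir_means[d][i] = set_ll[sel].mean()
    return NullDistribution(
        set_size=set_size,
        n_sets=n_sets,
        means=means,
        chromosome_profile=dict(target_profile),
        seed=seed,
        direction_means=dir_means,
    )


def locate_observed(
    observed_mean: float,
    null: NullDistribution | np.ndarray,
    n_sets: int | None = None,
) -> LocationReport:
    """Locate an observed set-mean log-likelihood within its null.

    The lower-tail fraction is the proportion of null means at or below the
    observed mean: small values indicate shifts too unlikely for drift.
    ``inside_95pct`` uses the empirical 2.5-97.5 percentile band.
    """
    means = null.means if isinstance(null, NullDistribution) else np.asarray(null)
    means = means[np.isfinite(means)]
    if len(means) < 100:
        raise ValueError("null distribution needs at least 100 finite sets")
    sd = means.std()
    degenerate = sd == 0.0
    lower_tail = float(np.mean(means <= observed_mean))
    z = 0.0 if degenerate else float((observed_mean - means.mean()) / sd)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return LocationReport(
        observed_mean=float(observed_mean),
        lower_tail_fraction=lower_tail,
        z_like_offset=z,
        inside_95pct=bool(lo <= observed_mean <= hi),
        degenerate=bool(degenerate),
        n_sets=len(means),
    )


def likelihood_ratio(
    mean_a: float, mean_b: float, set_size: int
) -> LikelihoodRatio:
    """Total-likelihood ratio exp(set_size * (mean_a - mean_b)).

    The log-ratio is always exact; the ratio itself saturates to inf/0 on
    overflow or underflow.
    """
    if not (np.isfinite(mean_a) and np.isfinite(mean_b)):
        raise ValueError("set means must be finite")
    log_ratio = set_size * (mean_a - mean_b)
    with np.errstate(over="ignore"):
        ratio = float(np.exp(log_ratio))
    return LikelihoodRatio(ratio=ratio, log_ratio=float(log_ratio))
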