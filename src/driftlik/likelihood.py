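"""Neutral-drift likelihoods of observed allele-frequency shifts.

Each site contributes one observation: its oriented minor-allele frequency
at the start of relaxed selection (generation 12) and at the end
(generation 75).  The likelihood of the shift under pure drift is the mass
that the exact Wright-Fisher compound distribution, started from the copy
count nearest the start frequency, places on the copy count nearest the
end frequency after G transitions.

Boundary rules
--------------
* A site exactly fixed or lost at the start that does not move has
  probability one of staying the same: log-likelihood 0.
* A site that *appears* fixed or lost (read frequency within 0.005 of a
  boundary) but shifted cannot truly have been absorbed — sequencing noise
  hides low-frequency variation — so its start frequency is reset to the
  closest interior grid value (0.01 or 0.99) and the result flagged
  ``boundary_adjusted``.
* Zero or underflowing masses are floored at log(1e-300) so set means stay
  finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .wf import PopulationSpec, compound_pmf_matrix, nearest_count

__all__ = [
    "Direction",
    "ShiftObservation",
    "LikelihoodResult",
    "LOGLIK_FLOOR",
    "classify_direction",
    "shift_loglikelihood",
    "compute_logliks",
    "population_mean_loglik",
    "change_significance",
]

LOGLIK_FLOOR = float(np.log(1e-300))

# Read-frequency band treated as apparent fixation/loss, and the interior
# frequencies such starts are reset to.
APPARENT_FIXATION_TOL = 0.005
BOUNDARY_RESET_LOW = 0.01
BOUNDARY_RESET_HIGH = 0.99


class Direction(str, Enum):
    """Direction of a frequency shift on the founder-minor orientation."""

    TOWARDS_MAJOR = "towards_major"  # minor-allele frequency decreased
    TOWARDS_MINOR = "towards_minor"  # minor-allele frequency increased
    UNCHANGED = "unchanged"


def classify_direction(p_start: float, p_end: float) -> Direction:
    """Classify a shift of the oriented minor-allele frequency."""
    if p_end < p_start:
        return Direction.TOWARDS_MAJOR
    if p_end > p_start:
        return Direction.TOWARDS_MINOR
    return Direction.UNCHANGED


@dataclass(frozen=True)
class ShiftObservation:
    """One site's oriented frequency at the start and end of relaxation."""

    site_id: str
    chromosome: str
    p_start: float
    p_end: float

    def __post_init__(self):
        for name in ("p_start", "p_end"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def x_linked(self) -> bool:
        return self.chromosome == "X"

    @property
    def direction(self) -> Direction:
        return classify_direction(self.p_start, self.p_end)


@dataclass(frozen=True)
class LikelihoodResult:
    site_id: str
    loglik: float
    boundary_adjusted: bool
    n_steps: int
    copies: int
    direction: Direction


@lru_cache(maxsize=None)
def loglik_table(copies: int, n_steps: int) -> np.ndarray:
    """log of the G-step drift kernel, floored at log(1e-300); read-only."""
    table = np.log(np.maximum(compound_pmf_matrix(copies, n_steps), 1e-300))
    table.flags.writeable = False
    return table


def _effective_start(p_start: np.ndarray, p_end: np.ndarray):
    """Apply the apparent-fixation reset; returns (p_eff, adjusted mask)."""
    near_high = p_start >= 1.0 - APPARENT_FIXATION_TOL
    near_low = p_start <= APPARENT_FIXATION_TOL
    moved = p_end != p_start
    adjusted = (near_high | near_low) & moved
    p_eff = np.where(
        adjusted,
        np.where(near_high, BOUNDARY_RESET_HIGH, BOUNDARY_RESET_LOW),
        p_start,
    )
    return p_eff, adjusted


def shift_loglikelihood(
    obs: ShiftObservation, spec: PopulationSpec
) -> LikelihoodResult:
    """Log-likelihood of one observed shift under pure drift."""
    M = spec.copies(obs.x_linked)
    p_eff, adjusted = _effective_start(
        np.asarray(obs.p_start), np.asarray(obs.p_end)
    )
    k_start = nearest_count(float(p_eff), M)
    k_end = nearest_count(obs.p_end, M)
    ll = float(loglik_table(M, spec.n_steps)[k_start, k_end])
    return LikelihoodResult(
        site_id=obs.site_id,
        loglik=ll,
        boundary_adjusted=bool(adjusted),
        n_steps=spec.n_steps,
        copies=M,
        direction=obs.direction,
    )


def compute_logliks(
    df: pd.DataFrame,
    spec: PopulationSpec,
    chrom_col: str = "chrom",
    p_start_col: str = "p_start",
    p_end_col: str = "p_end",
) -> pd.DataFrame:
    """Vectorised per-site log-likelihoods for a site-shift table.

    Returns a copy of ``df`` with ``loglik``, ``boundary_adjusted`` and
    ``direction`` columns appended.  X-linked rows use ``spec.copies_x``.
    """
    out = df.copy()
    p_start = out[p_start_col].to_numpy(dtype=float)
    p_end = out[p_end_col].to_numpy(dtype=float)
    p_eff, adjusted = _effective_start(p_start, p_end)
    ll = np.empty(len(out))
    x_mask = (out[chrom_col] == "X").to_numpy()
    for mask, x_linked in ((~x_mask, False), (x_mask, True)):
        if not mask.any():
            continue
        M = spec.copies(x_linked)
        table = loglik_table(M, spec.n_steps)
        ks = nearest_count(p_eff[mask], M)
        ke = nearest_count(p_end[mask], M)
        ll[mask] = table[ks, ke]
    out["loglik"] = ll
    out["boundary_adjusted"] = adjusted
    out["direction"] = np.where(
        p_end < p_start,
        Direction.TOWARDS_MAJOR.value,
        np.where(
            p_end > p_start,
            Direction.TOWARDS_MINOR.value,
            Direction.UNCHANGED.value,
        ),
    )
    return out


def population_mean_loglik(
    results: Sequence[LikelihoodResult] | pd.DataFrame | Iterable,
    direction: Direction | str | None = None,
) -> float:
    """Mean log-likelihood of a site set, optionally restricted by direction.

    Raises ``ValueError`` if the (filtered) set is empty.
    """
    if isinstance(results, pd.DataFrame):
        lls = results["loglik"].to_numpy(dtype=float)
        dirs = results["direction"].to_numpy()
    else:
        results = list(results)
        lls = np.array([r.loglik for r in results], dtype=float)
        dirs = np.array([Direction(r.direction).value for r in results])
    if direction is not None:
        wanted = Direction(direction).value
        lls = lls[dirs == wanted]
    if lls.size == 0:
        raise ValueError(
            "no sites left after direction filtering; cannot average"
        )
    return float(lls.mean())


def change_significance(
    counts_start: tuple[int, int], counts_end: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p-value on the 2x2 read-count table.

    Annotation only — the drift test itself never uses this.
    """
    table = np.array([counts_start, counts_end], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("read counts must be non-negative")
    if table.sum(axis=1).min() == 0:
        raise ValueError("zero total coverage at one generation")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)
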