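"""Exact and simulated Wright-Fisher drift for a biallelic locus.

The population is modelled as a constant pool of ``M`` allele copies
(``M = 2Ne`` for autosomal sites, ``Ne`` for X-linked sites).  Each
generation the next pool is a binomial sample of size ``M`` with success
probability equal to the current allele frequency ``k/M``.  Iterating the
binomial transition over ``G`` generations yields a compound (mixture)
distribution over the copy-count states ``0..M``; states 0 (loss) and M
(fixation) are absorbing.

Two routes to that distribution are provided and must agree:

* :func:`compound_distribution` — the exact probability mass, computed by
  iterated matrix-vector products of the one-step binomial transition
  (mathematically identical to the nested-sum recursion, but O(G·M²)).
* :func:`simulate_trajectories` — Monte-Carlo replicate trajectories whose
  final-state histogram converges to the exact mass.

The default effective size is 2Ne = 84 copies, the variance effective
population size estimated for the fly populations this model was built
for (25 pairs of parents per generation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PopulationSpec",
    "DriftDistribution",
    "TrajectorySet",
    "nearest_count",
    "transition_pmf",
    "transition_matrix",
    "compound_pmf_matrix",
    "compound_distribution",
    "drift_variance",
    "simulate_trajectories",
    "grid_scan",
]


def nearest_count(freq, copies: int):
    """Map frequencies onto the integer copy-count lattice 0..copies.

    Ties (x.5) round half up, e.g. ``nearest_count(0.5, 3) == 2``.
    Accepts scalars or arrays.
    """
    arr = np.floor(np.asarray(freq, dtype=float) * copies + 0.5)
    arr = np.clip(arr, 0, copies).astype(np.int64)
    return int(arr) if np.isscalar(freq) or arr.ndim == 0 else arr


@dataclass(frozen=True)
class PopulationSpec:
    """Effective copy numbers and the number of generation transitions.

    Parameters
    ----------
    copies_autosome:
        Number of allele copies for autosomal sites (2Ne).  Default 84.
    copies_x:
        Copies for X-linked sites (Ne).  Defaults to ``copies_autosome // 2``.
    n_steps:
        Number of binomial generation transitions G.  Default 63, the
        number of transitions between the sequenced time points
        (generation 12 through generation 75).
    """

    copies_autosome: int = 84
    copies_x: int | None = None
    n_steps: int = 63

    def __post_init__(self):
        if self.copies_autosome < 2:
            raise ValueError("copies_autosome must be >= 2")
        if self.copies_x is None:
            object.__setattr__(self, "copies_x", self.copies_autosome // 2)
        if self.copies_x < 1:
            raise ValueError("copies_x must be >= 1")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    def copies(self, x_linked: bool = False) -> int:
        return self.copies_x if x_linked else self.copies_autosome


@dataclass(frozen=True)
class DriftDistribution:
    """Exact drift probability mass over copy counts 0..copies after n_steps."""

    copies: int
    pmf: np.ndarray
    origin_frequency: float
    n_steps: int

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.copies + 1) / self.copies

    def mean_frequency(self) -> float:
        return float(np.dot(self.pmf, self.frequencies))

    def variance_frequency(self) -> float:
        f = self.frequencies
        m = np.dot(self.pmf, f)
        return float(np.dot(self.pmf, (f - m) ** 2))

    @property
    def loss_mass(self) -> float:
        return float(self.pmf[0])

    @property
    def fixation_mass(self) -> float:
        return float(self.pmf[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": np.arange(self.copies + 1), "probability": self.pmf}
        )

    def metadata(self) -> dict:
        return {
            "copies": self.copies,
            "n_steps": self.n_steps,
            "origin_frequency": self.origin_frequency,
        }


@dataclass(frozen=True)
class TrajectorySet:
    """Replicate simulated copy-count trajectories from a common start."""

    copies: int
    n_reps: int
    n_steps: int
    trajectories: np.ndarray  # (n_reps, n_steps + 1) integer copy counts
    seed: int | None
    origin_frequency: float = field(default=0.0)

    @property
    def final_counts(self) -> np.ndarray:
        return self.trajectories[:, -1]

    @property
    def final_frequencies(self) -> np.ndarray:
        return self.final_counts / self.copies

    def final_histogram(self) -> np.ndarray:
        """Empirical pmf of the final state over 0..copies."""
        return (
            np.bincount(self.final_counts, minlength=self.copies + 1)
            / self.n_reps
        )


def transition_pmf(p_prev: float, copies: int) -> np.ndarray:
    """One-generation binomial transition: Binomial(copies, p_prev) pmf."""
    if not 0.0 <= p_prev <= 1.0:
        raise ValueError(f"p_prev must be in [0, 1], got {p_prev}")
    if copies < 1:
        raise ValueError(f"copies must be positive, got {copies}")
    return stats.binom.pmf(np.arange(copies + 1), copies, p_prev)


@lru_cache(maxsize=None)
def transition_matrix(copies: int) -> np.ndarray:
    """(copies+1) x (copies+1) matrix T[j, k] = P(k next copies | j now)."""
    k = np.arange(copies + 1)
    T = stats.binom.pmf(k[None, :], copies, (k / copies)[:, None])
    T.flags.writeable = False
    return T


@lru_cache(maxsize=None)
def compound_pmf_matrix(copies: int, n_steps: int) -> np.ndarray:
    """G-step drift kernel: row k0 holds the pmf over copy counts after G steps.

    Built by sequential multiplication with the one-step transition, i.e. the
    iterated-mixture form of the nested-sum recursion.
    """
    T = transition_matrix(copies)
    P = np.eye(copies + 1)
    for _ in range(n_steps):
        P = P @ T
    P.flags.writeable = False
    return P


def compound_distribution(
    k0: int, spec: PopulationSpec, x_linked: bool = False
) -> DriftDistribution:
    """Exact allele copy-count distribution after ``spec.n_steps`` generations.

    ``n_steps == 0`` returns the point mass at ``k0``; loss/fixation starts
    stay put (absorbing boundaries).
    """
    M = spec.copies(x_linked)
    if not 0 <= k0 <= M:
        raise ValueError(f"k0 must be in [0, {M}], got {k0}")
    pmf = compound_pmf_matrix(M, spec.n_steps)[k0].copy()
    return DriftDistribution(
        copies=M, pmf=pmf, origin_frequency=k0 / M, n_steps=spec.n_steps
    )


def drift_variance(
    p0: float, spec: PopulationSpec, x_linked: bool = False
) -> float:
    """Closed-form variance of the allele frequency after G generations.

    ``Var(p_G) = p0 (1 - p0) (1 - (1 - 1/M)^G)`` — the classical recursion
    for pure drift at constant size, in closed form.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    M = spec.copies(x_linked)
    return p0 * (1.0 - p0) * (1.0 - (1.0 - 1.0 / M) ** spec.n_steps)


def simulate_trajectories(
    k0: int,
    spec: PopulationSpec,
    n_reps: int,
    seed: int | None = None,
    x_linked: bool = False,
    rng: np.random.Generator | None = None,
) -> TrajectorySet:
    """Simulate replicate drift trajectories by repeated binomial sampling."""
    M = spec.copies(x_linked)
    if not 0 <= k0 <= M:
        raise ValueError(f"k0 must be in [0, {M}], got {k0}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    traj = np.empty((n_reps, spec.n_steps + 1), dtype=np.int64)
    traj[:, 0] = k0
    k = np.full(n_reps, k0, dtype=np.int64)
    for g in range(1, spec.n_steps + 1):
        k = rng.binomial(M, k / M)
        traj[:, g] = k
    return TrajectorySet(
        copies=M,
        n_reps=n_reps,
        n_steps=spec.n_steps,
        trajectories=traj,
        seed=seed,
        origin_frequency=k0 / M,
    )


def grid_scan(
    spec: PopulationSpec,
    p0_start: float = 0.01,
    p0_end: float = 0.5,
    p0_step: float = 0.01,
    n_reps: int = 10_000,
    seed: int | None = None,
    x_linked: bool = False,
) -> list[TrajectorySet]:
    """Simulate trajectory sets across a grid of initial frequencies.

    Default grid 0.01..0.5 in 0.01 increments with 10,000 replicates each;
    each grid frequency is mapped to the nearest integer copy count.
    """
    n_points = int(round((p0_end - p0_start) / p0_step)) + 1
    if p0_step <= 0 or n_points < 1:
        raise ValueError("empty initial-frequency grid")
    freqs = p0_start + p0_step * np.arange(n_points)
    if freqs[-1] > 1.0 + 1e-12:
        raise ValueError("grid frequencies exceed 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_points)
    out = []
    for f, child in zip(freqs, children):
        k0 = nearest_count(f, spec.copies(x_linked))
        out.append(
            simulate_trajectories(
                k0,
                spec,
                n_reps,
                seed=seed,
                x_linked=x_linked,
                rng=np.random.default_rng(child),
            )
        )
    return out
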