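"""Synthetic evolve-and-resequence experiments with known ground truth.

The generator emulates the downstream products of a relaxed-selection
experiment on fly sleep: six populations (two previously selected for
short sleep, two for long sleep, two unselected controls) founded from a
common outbred pool, with pooled sequencing of two 30-fly DNA samples per
population at generations 0 (founder), 12 (end of artificial selection)
and 75 (end of relaxed selection).  126 "variant of interest" sites plus
thousands of background sites are placed on chromosome arms 2L/2R/3L/3R/X
in proportion to arm length; X-linked sites drift with half the autosomal
copy number.

Allele frequencies evolve by a per-generation deterministic genic
(haploid-equivalent) selection update ``p' = p(1+s) / (1 + p s)`` on the
founder-minor allele followed by binomial resampling of the allele copies;
``s = 0`` reduces exactly to the pure Wright-Fisher drift of
:mod:`driftlik.wf`.  Read counts are sampled per DNA sample with a
negative-binomial depth model.  De novo mutations with attributes
straddling every filter threshold are injected at generation 75 and
recorded in a truth table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import site_io
from .wf import PopulationSpec

__all__ = [
    "POPULATIONS",
    "POP_SCHEME",
    "CHROM_PROPORTIONS",
    "CHROM_LENGTHS",
    "ExperimentConfig",
    "SyntheticExperiment",
    "selection_update",
    "evolve",
    "simulate_population_sites",
    "sample_reads",
    "inject_denovo",
    "build_experiment_frames",
    "build_experiment",
]

POPULATIONS = ("short1", "short2", "long1", "long2", "control1", "control2")
POP_SCHEME = {
    "short1": "short",
    "short2": "short",
    "long1": "long",
    "long2": "long",
    "control1": "control",
    "control2": "control",
}
SAMPLES = ("1", "2")

# Chromosome-arm proportions by dm6 arm length (2L/2R/3L/3R/X).
CHROM_LENGTHS = {
    "2L": 23_513_712,
    "2R": 25_286_936,
    "3L": 28_110_227,
    "3R": 32_079_331,
    "X": 23_542_271,
}
_total = sum(CHROM_LENGTHS.values())
CHROM_PROPORTIONS = {c: v / _total for c, v in CHROM_LENGTHS.items()}

_BASES = np.array(["A", "C", "G", "T"])


def _default_selection() -> dict:
    # Artificial phase: directional selection raising the minor allele in
    # short sleepers and depressing it in long sleepers.  Relaxed phase:
    # natural selection pushes the short-sleeper variants back toward the
    # major allele; long/control shifts are pure drift.
    return {
        "artificial": {"short": 0.25, "long": -0.25, "control": 0.0},
        "relaxed": {"short": -0.1, "long": 0.0, "control": 0.0},
    }


@dataclass
class ExperimentConfig:
    """Study-design parameters of one synthetic experiment."""

    n_variant_sites: int = 126
    n_background_sites: int = 5000
    chromosome_proportions: dict = field(
        default_factory=lambda: dict(CHROM_PROPORTIONS)
    )
    copies_autosome: int = 84
    copies_x: int = 42
    n_steps_artificial: int = 12
    n_steps_relaxed: int = 63
    selection: dict = field(default_factory=_default_selection)
    founder_maf_range: tuple = (0.05, 0.5)
    depth_mean: float = 100.0
    depth_dispersion: float = 20.0
    error_rate: float = 0.0
    n_denovo_injected: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_variant_sites < 1 or self.n_background_sites < 0:
            raise ValueError("site counts must be positive")
        for phase, by_scheme in self.selection.items():
            for scheme, s in by_scheme.items():
                if not abs(s) < 1:
                    raise ValueError(f"|s| must be < 1, got {s} ({phase}/{scheme})")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")

    @classmethod
    def neutral(cls, **kwargs) -> "ExperimentConfig":
        """Default design with every selection coefficient set to zero."""
        sel = {
            phase: {k: 0.0 for k in d}
            for phase, d in _default_selection().items()
        }
        return cls(selection=sel, **kwargs)

    def population_spec(self) -> PopulationSpec:
        return PopulationSpec(
            copies_autosome=self.copies_autosome,
            copies_x=self.copies_x,
            n_steps=self.n_steps_relaxed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["founder_maf_range"] = list(self.founder_maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "founder_maf_range" in d:
            d["founder_maf_range"] = tuple(d["founder_maf_range"])
        return cls(**d)


def selection_update(p: np.ndarray, s) -> np.ndarray:
    """One generation of deterministic genic selection on the focal allele."""
    p = np.asarray(p, dtype=float)
    return p * (1.0 + s) / (1.0 + p * s)


def evolve(
    freqs: np.ndarray,
    copies: np.ndarray,
    s: np.ndarray | float,
    n_steps: int,
    rng: np.random.Generator,
    record: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Evolve frequencies by selection + binomial drift for n_steps.

    ``freqs``: (n_sites, n_pops) current frequencies of the focal allele;
    ``copies``: per-site copy number (broadcast against freqs);
    ``s``: selection coefficient per (site, pop), broadcastable.
    Returns final frequencies (and the full (n_steps+1)-generation
    trajectory stack if ``record``).
    """
    p = np.asarray(freqs, dtype=float).copy()
    M = np.broadcast_to(np.asarray(copies)[:, None], p.shape)
    traj = [p.copy()] if record else None
    for _ in range(n_steps):
        p = selection_update(p, s)
        p = rng.binomial(M, p) / M
        if record:
            traj.append(p.copy())
    if record:
        return p, np.stack(traj)  # (n_steps+1, n_sites, n_pops)
    return p


def _site_metadata(config: ExperimentConfig, rng: np.random.Generator):
    """Place variant + background sites on chromosome arms; draw alleles."""
    chroms = list(config.chromosome_proportions)
    props = np.array([config.chromosome_proportions[c] for c in chroms])
    props = props / props.sum()
    n_sites = config.n_variant_sites + config.n_background_sites
    counts_var = rng.multinomial(config.n_variant_sites, props)
    counts_bg = rng.multinomial(config.n_background_sites, props)
    rows = []
    reserve = {}  # spare unique positions per chromosome for injections
    for c, nv, nb in zip(chroms, counts_var, counts_bg):
        n = nv + nb
        length = CHROM_LENGTHS.get(c, 25_000_000)
        pos = rng.choice(length - 1, size=n + 64, replace=False) + 1
        reserve[c] = np.sort(pos[n:])
        pos = np.sort(pos[:n])
        is_var = np.zeros(n, dtype=bool)
        is_var[rng.choice(n, size=nv, replace=False)] = True
        for p, v in zip(pos, is_var):
            rows.append((c, int(p), v))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "is_variant"])
    sites = sites.sort_values(["chrom", "pos"]).reset_index(drop=True)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = _BASES[alt_idx]
    sites["site_id"] = sites["chrom"] + ":" + sites["pos"].astype(str)
    sites["x_linked"] = sites["chrom"] == "X"
    return sites, reserve


def _selection_matrix(
    config: ExperimentConfig,
    phase: str,
    is_variant: np.ndarray,
    minor_is_alt_sign: np.ndarray,
) -> np.ndarray:
    """(n_sites, n_pops) selection coefficients acting on the alt allele.

    Selection is defined on the founder-minor allele; background sites are
    always neutral.
    """
    by_scheme = config.selection[phase]
    s_pop = np.array([by_scheme[POP_SCHEME[p]] for p in POPULATIONS])
    return is_variant[:, None] * minor_is_alt_sign[:, None] * s_pop[None, :]


def simulate_population_sites(
    config: ExperimentConfig, rng: np.random.Generator | None = None
):
    """Simulate true alt-allele frequencies through both phases.

    Returns ``(sites, freqs, variant_traj, reserve)`` where ``freqs`` maps
    generation label -> (n_sites, n_pops) true frequencies and
    ``variant_traj`` is the full per-generation trajectory stack of the
    variant sites.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites, reserve = _site_metadata(config, rng)
    n_sites = len(sites)
    # Founder minor-allele frequency, assigned to ref or alt at random so
    # orientation logic is exercised.
    maf = rng.uniform(*config.founder_maf_range, size=n_sites)
    minor_is_alt = rng.random(n_sites) < 0.5
    f_alt0 = np.where(minor_is_alt, maf, 1.0 - maf)
    sites = sites.assign(
        founder_alt_freq=f_alt0, founder_minor_is_alt=minor_is_alt
    )
    copies = np.where(
        sites["x_linked"], config.copies_x, config.copies_autosome
    ).astype(np.int64)
    sign = np.where(minor_is_alt, 1.0, -1.0)
    is_var = sites["is_variant"].to_numpy()

    p0 = np.tile(f_alt0[:, None], (1, len(POPULATIONS)))
    s_art = _selection_matrix(config, "artificial", is_var, sign)
    p12 = evolve(p0, copies, s_art, config.n_steps_artificial, rng)
    s_rel = _selection_matrix(config, "relaxed", is_var, sign)
    # record the relaxed-phase trajectories of the variant sites only
    p75 = p12.copy()
    var_idx = np.flatnonzero(is_var)
    p75_var, traj_var = evolve(
        p12[var_idx],
        copies[var_idx],
        s_rel[var_idx],
        config.n_steps_relaxed,
        rng,
        record=True,
    )
    bg_idx = np.flatnonzero(~is_var)
    p75[bg_idx] = evolve(
        p12[bg_idx], copies[bg_idx], s_rel[bg_idx], config.n_steps_relaxed, rng
    )
    p75[var_idx] = p75_var
    freqs = {0: p0, config.n_steps_artificial: p12,
             config.n_steps_artificial + config.n_steps_relaxed: p75}
    return sites, freqs, traj_var, reserve


def sample_reads(
    true_frequency: np.ndarray,
    depth_mean: float,
    depth_dispersion: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one DNA sample's (ref_count, alt_count) per site.

    Depth is negative binomial with the given mean and dispersion (size)
    parameter; alternate reads are binomial in the error-adjusted
    frequency ``f (1-e) + (1-f) e``.
    """
    f = np.asarray(true_frequency, dtype=float)
    r = depth_dispersion
    depth = rng.negative_binomial(r, r / (r + depth_mean), size=f.shape)
    f_eff = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    alt = rng.binomial(depth, f_eff)
    return depth - alt, alt


def _reads_table(
    sites: pd.DataFrame,
    freqs: np.ndarray,
    populations,
    generation: int,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long-format site table for one generation (all pops x 2 samples)."""
    frames = []
    for j, popn in enumerate(populations):
        for smp in SAMPLES:
            ref_c, alt_c = sample_reads(
                freqs[:, j] if freqs.ndim == 2 else freqs,
                config.depth_mean,
                config.depth_dispersion,
                config.error_rate,
                rng,
            )
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": sites["chrom"],
                        "pos": sites["pos"],
                        "ref": sites["ref"],
                        "alt": sites["alt"],
                        "population": popn,
                        "generation": generation,
                        "sample": smp,
                        "ref_count": ref_c,
                        "alt_count": alt_c,
                        "maxqual": 1000.0,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[site_io.SCHEMA]


# --- de novo injection -----------------------------------------------------

# (case name, attribute overrides, filters expected to remove it)
_DENOVO_CASES = [
    ("clean_snp", {}, []),
    ("clean_indel", {"indel": True}, []),
    ("quality_at_threshold", {"quality": 124.0}, []),
    ("quality_below_threshold", {"quality": 123.0}, ["quality"]),
    ("maxqual_at_threshold", {"maxqual": 426.0}, []),
    ("maxqual_below_threshold", {"maxqual": 425.0}, ["quality"]),
    ("reads_at_lower_bound", {"reads": 40}, []),
    ("reads_below_lower_bound", {"reads": 39}, ["quality"]),
    ("reads_at_upper_bound", {"reads": 226}, []),
    ("reads_above_upper_bound", {"reads": 227}, ["quality"]),
    ("present_in_one_sample_only", {"privacy": "one_sample"}, ["privacy"]),
    ("shared_by_two_populations", {"privacy": "two_pops"}, ["privacy"]),
    ("known_in_catalog", {"in_catalog": True}, ["known_in_catalog"]),
    ("arose_in_prior_study", {"in_prior": True}, ["prior_study"]),
]


def inject_denovo(
    config: ExperimentConfig,
    sites: pd.DataFrame,
    reserve: dict,
    rng: np.random.Generator,
):
    """Build injected de novo candidates straddling every filter threshold.

    Returns ``(candidate_rows, prior_rows, truth)``: per-sample rows of the
    candidate table (site_io schema + ``quality_score``), rows for the
    prior-study site list, and the truth records with expected fate.
    """
    chroms = list(reserve)
    specs = []
    for i, (name, over, fails) in enumerate(_DENOVO_CASES):
        specs.append((name, over, fails, POPULATIONS[i % len(POPULATIONS)]))
    for popn in POPULATIONS:
        for j in range(config.n_denovo_injected):
            specs.append((f"extra_clean_{popn}_{j}", {}, [], popn))

    used = {c: 0 for c in chroms}
    cand_rows, prior_rows, truth = [], [], []
    for name, over, fails, carrier in specs:
        chrom = chroms[sum(used.values()) % len(chroms)]
        if used[chrom] >= len(reserve[chrom]):
            raise ValueError("ran out of reserved injection coordinates")
        pos = int(reserve[chrom][used[chrom]])
        used[chrom] += 1
        if over.get("in_catalog"):
            row = sites.iloc[int(rng.integers(0, len(sites)))]
            chrom, pos, ref, alt = row["chrom"], int(row["pos"]), row["ref"], row["alt"]
        else:
            ref = str(_BASES[rng.integers(0, 4)])
            alt = ref + "T" if over.get("indel") else str(
                _BASES[(list(_BASES).index(ref) + 1) % 4]
            )
        quality = float(over.get("quality", 500.0))
        maxqual = float(over.get("maxqual", 600.0))
        reads = int(over.get("reads", 100))
        privacy = over.get("privacy", "private")
        if privacy == "two_pops":
            other = POPULATIONS[(POPULATIONS.index(carrier) + 1) % 6]
            present = {(p, s): True for p in (carrier, other) for s in SAMPLES}
        elif privacy == "one_sample":
            present = {(carrier, SAMPLES[0]): True}
        else:
            present = {(carrier, s): True for s in SAMPLES}
        n_present_pops = len({p for p, _ in present})
        cov_per_row = max(reads // (2 * n_present_pops), 1)
        remainder = reads - cov_per_row * (2 * n_present_pops - 1)
        row_i = 0
        for popn in POPULATIONS:
            for smp in SAMPLES:
                if (popn, smp) in present:
                    cov = remainder if row_i == 2 * n_present_pops - 1 else cov_per_row
                    row_i += 1
                    alt_c = max(1, int(round(cov * 0.3)))
                    ref_c = max(cov - alt_c, 0)
                elif popn in {p for p, _ in present}:
                    # carrier population, absent sample: covered, no alt reads
                    cov = cov_per_row
                    row_i += 1
                    alt_c, ref_c = 0, cov
                else:
                    alt_c, ref_c = 0, 100
                cand_rows.append(
                    (chrom, pos, ref, alt, popn, 75, smp, ref_c, alt_c,
                     maxqual, quality)
                )
        if over.get("in_prior"):
            prior_rows.append((chrom, pos, ref, alt))
        truth.append(
            {
                "case": name,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "carrier": carrier if privacy == "private" else None,
                "is_indel": len(ref) != 1 or len(alt) != 1,
                "expected_removed_by": fails,
                "survives": not fails,
            }
        )
    candidates = pd.DataFrame(
        cand_rows, columns=site_io.SCHEMA + ["quality_score"]
    )
    prior = pd.DataFrame(prior_rows, columns=["chrom", "pos", "ref", "alt"])
    return candidates, prior, truth


# --- whole experiments -----------------------------------------------------


@dataclass
class SyntheticExperiment:
    """In-memory bundle of one synthetic experiment."""

    config: ExperimentConfig
    sites: pd.DataFrame
    founder: pd.DataFrame
    gen12: pd.DataFrame
    gen75: pd.DataFrame
    variants: pd.DataFrame  # site keys of the variants of interest
    catalog: pd.DataFrame
    denovo_candidates: pd.DataFrame
    prior_sites: pd.DataFrame
    truth: dict

    @property
    def variant_keys(self) -> set:
        return set(zip(self.variants["chrom"], self.variants["pos"]))


def build_experiment_frames(config: ExperimentConfig) -> SyntheticExperiment:
    """Generate a full experiment in memory (deterministic in config.seed)."""
    rng = np.random.default_rng(config.seed)
    sites, freqs, traj_var, reserve = simulate_population_sites(config, rng)
    g12 = config.n_steps_artificial
    g75 = g12 + config.n_steps_relaxed

    founder = _reads_table(sites, freqs[0][:, 0], ["SAIP"], 0, config, rng)
    gen12 = _reads_table(sites, freqs[g12], POPULATIONS, g12, config, rng)
    gen75 = _reads_table(sites, freqs[g75], POPULATIONS, g75, config, rng)
    candidates, prior_extra, denovo_truth = inject_denovo(
        config, sites, reserve, rng
    )
    variants = sites.loc[
        sites["is_variant"], ["site_id", "chrom", "pos", "ref", "alt"]
    ].reset_index(drop=True)
    catalog = sites[["chrom", "pos", "ref", "alt"]].copy()

    var_ids = sites.loc[sites["is_variant"], "site_id"].to_numpy()
    truth = {
        "config": config.to_dict(),
        "generations": [0, g12, g75],
        "populations": list(POPULATIONS),
        "sites": {
            sid: {
                "chrom": c,
                "pos": int(p),
                "is_variant": bool(v),
                "founder_alt_freq": round(float(f), 6),
                "founder_minor_is_alt": bool(m),
                "alt_freqs": {
                    str(g): [round(float(x), 6) for x in freqs[g][i]]
                    for g in (0, g12, g75)
                },
            }
            for i, (sid, c, p, v, f, m) in enumerate(
                zip(
                    sites["site_id"],
                    sites["chrom"],
                    sites["pos"],
                    sites["is_variant"],
                    sites["founder_alt_freq"],
                    sites["founder_minor_is_alt"],
                )
            )
        },
        "variant_trajectories": {
            str(sid): np.round(traj_var[:, i, :], 6).T.tolist()
            for i, sid in enumerate(var_ids)
        },
        "denovo": denovo_truth,
    }
    return SyntheticExperiment(
        config=config,
        sites=sites,
        founder=founder,
        gen12=gen12,
        gen75=gen75,
        variants=variants,
        catalog=catalog,
        denovo_candidates=candidates,
        prior_sites=prior_extra,
        truth=truth,
    )


def build_experiment(config: ExperimentConfig, outdir) -> Path:
    """Materialise an experiment directory of TSV tables plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = build_experiment_frames(config)
    site_io.write_site_table(exp.founder, outdir / "founder.tsv")
    site_io.write_site_table(exp.gen12, outdir / "gen12.tsv")
    site_io.write_site_table(exp.gen75, outdir / "gen75.tsv")
    exp.variants.to_csv(outdir / "variants.tsv", sep="\t", index=False)
    exp.catalog.to_csv(outdir / "catalog.tsv", sep="\t", index=False)
    exp.prior_sites.to_csv(outdir / "prior_sites.tsv", sep="\t", index=False)
    exp.denovo_candidates.to_csv(
        outdir / "denovo_candidates.tsv", sep="\t", index=False,
        float_format="%.6g",
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(exp.truth, fh, sort_keys=True, indent=None)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return outdir
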