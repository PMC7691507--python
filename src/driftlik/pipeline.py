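"""End-to-end drift-vs-selection analysis and de novo cascade runners.

``run_drift_test`` implements the full chain: load site tables, apply the
per-sample coverage filter, pool the two DNA samples per population,
orient every frequency to the founder minor allele, compute per-site drift
log-likelihoods between the two sequenced generations, split by shift
direction, build chromosome-matched resampling nulls from the background
sites, and locate each population's observed mean in its null.

``run_denovo`` runs the four-filter de novo cascade on a candidate table.

Both write TSV/JSON outputs plus a run manifest (config snapshot, input
checksums, seeds, version, per-stage record counts, timestamp).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .denovo import (
    FilterThresholds,
    candidates_from_table,
    catalog_keys,
    run_cascade,
)
from .likelihood import Direction, change_significance, compute_logliks
from .resampling import NullDistribution, locate_observed, sample_null_sets
from .site_io import (
    combine_samples,
    coverage_filter,
    orient_to_founder_minor,
    read_site_table,
    write_site_table,
)
from .wf import PopulationSpec

__all__ = [
    "PopulationDriftResult",
    "DriftTestResult",
    "drift_test_frames",
    "run_drift_test",
    "run_denovo",
    "write_manifest",
]

DIRECTION_KEYS = (
    "all",
    Direction.TOWARDS_MAJOR.value,
    Direction.TOWARDS_MINOR.value,
)


@dataclass
class PopulationDriftResult:
    population: str
    n_variant_sites: int
    observed_means: dict
    null: NullDistribution
    reports: dict
    sites: pd.DataFrame

    def summary(self) -> dict:
        return {
            "population": self.population,
            "n_variant_sites": self.n_variant_sites,
            "n_null_sets": self.null.n_sets,
            "chromosome_profile": {
                str(k): int(v) for k, v in self.null.chromosome_profile.items()
            },
            "observed_means": self.observed_means,
            "reports": self.reports,
        }


@dataclass
class DriftTestResult:
    populations: dict
    spec: PopulationSpec
    n_sets: int
    seed: int | None
    stage_counts: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "spec": {
                "copies_autosome": self.spec.copies_autosome,
                "copies_x": self.spec.copies_x,
                "n_steps": self.spec.n_steps,
            },
            "n_sets": self.n_sets,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "populations": {
                p: r.summary() for p, r in self.populations.items()
            },
        }


def _prepare_generation(
    df: pd.DataFrame, min_cov: int, max_cov: int, counts: dict, label: str
) -> pd.DataFrame:
    counts[f"{label}_rows_in"] = len(df)
    filtered = coverage_filter(df, min_cov, max_cov)
    counts[f"{label}_rows_coverage_pass"] = len(filtered)
    combined = combine_samples(filtered)
    counts[f"{label}_site_population_pairs"] = len(combined)
    return combined


def drift_test_frames(
    founder: pd.DataFrame,
    gen12: pd.DataFrame,
    gen75: pd.DataFrame,
    variant_keys: set,
    spec: PopulationSpec,
    n_sets: int = 1000,
    seed: int | None = None,
    min_cov: int = 10,
    max_cov: int = 226,
    annotate_significance: bool = False,
) -> DriftTestResult:
    """Run the drift test on in-memory site tables.

    ``variant_keys`` is the set of (chrom, pos) keys of the variants of
    interest; every other site passing the filters is background.
    """
    counts: dict = {}
    founder_c = _prepare_generation(founder, min_cov, max_cov, counts, "founder")
    g12 = _prepare_generation(gen12, min_cov, max_cov, counts, "gen12")
    g75 = _prepare_generation(gen75, min_cov, max_cov, counts, "gen75")

    ori12 = orient_to_founder_minor(g12, founder=founder_c)
    ori75 = orient_to_founder_minor(g75, founder=founder_c)
    key_cols = ["chrom", "pos", "population"]
    paired = ori12[
        key_cols + ["ref", "alt", "ref_count", "alt_count", "oriented_frequency"]
    ].merge(
        ori75[key_cols + ["ref_count", "alt_count", "oriented_frequency"]],
        on=key_cols,
        suffixes=("_12", "_75"),
        how="inner",
    )
    paired = paired.rename(
        columns={
            "oriented_frequency_12": "p_start",
            "oriented_frequency_75": "p_end",
        }
    )
    paired["site_id"] = paired["chrom"] + ":" + paired["pos"].astype(str)
    counts["paired_site_population_pairs"] = len(paired)
    paired = compute_logliks(paired, spec)
    site_key = list(zip(paired["chrom"], paired["pos"]))
    paired["is_variant"] = [k in variant_keys for k in site_key]

    ss = np.random.SeedSequence(seed)
    results = {}
    pops = sorted(paired["population"].unique())
    for popn, child in zip(pops, ss.spawn(len(pops))):
        sub = paired[paired["population"] == popn]
        var = sub[sub["is_variant"]].copy()
        bg = sub[~sub["is_variant"]]
        if var.empty:
            raise ValueError(f"no variant sites left for population {popn}")
        if annotate_significance:
            var["p_change"] = [
                change_significance(
                    (r.ref_count_12, r.alt_count_12),
                    (r.ref_count_75, r.alt_count_75),
                )
                for r in var.itertuples(index=False)
            ]
        profile = var["chrom"].value_counts().to_dict()
        null = sample_null_sets(
            bg, profile, n_sets, spec, rng=np.random.default_rng(child)
        )
        observed, reports = {}, {}
        for key in DIRECTION_KEYS:
            if key == "all":
                sel = var
                null_means = null.means
            else:
                sel = var[var["direction"] == key]
                null_means = null.direction_means[key]
            if sel.empty:
                observed[key] = None
                reports[key] = None
                continue
            obs = float(sel["loglik"].mean())
            observed[key] = obs
            finite = null_means[np.isfinite(null_means)]
            reports[key] = (
                locate_observed(obs, finite).to_dict()
                if len(finite) >= 100
                else None
            )
        results[popn] = PopulationDriftResult(
            population=popn,
            n_variant_sites=len(var),
            observed_means=observed,
            null=null,
            reports=reports,
            sites=var,
        )
    return DriftTestResult(
        populations=results,
        spec=spec,
        n_sets=n_sets,
        seed=seed,
        stage_counts=counts,
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    outdir: Path,
    config: dict,
    inputs: dict,
    seed,
    stage_counts: dict | None = None,
) -> Path:
    manifest = {
        "package": "driftlik",
        "version": __version__,
        "config": config,
        "inputs": {str(k): _sha256(v) for k, v in inputs.items()},
        "seed": seed,
        "stage_counts": stage_counts or {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
    return path


def run_drift_test(
    founder_path,
    gen12_path,
    gen75_path,
    variants_path,
    outdir,
    spec: PopulationSpec | None = None,
    n_sets: int = 1000,
    seed: int | None = None,
    min_cov: int = 10,
    max_cov: int = 226,
    make_figure: bool = False,
    annotate_significance: bool = False,
) -> DriftTestResult:
    """File-level drift test: read tables, analyse, write report bundle."""
    spec = spec or PopulationSpec()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    founder = read_site_table(founder_path)
    gen12 = read_site_table(gen12_path)
    gen75 = read_site_table(gen75_path)
    variants = pd.read_csv(variants_path, sep="\t")
    variant_keys = set(zip(variants["chrom"], variants["pos"].astype(int)))
    result = drift_test_frames(
        founder,
        gen12,
        gen75,
        variant_keys,
        spec,
        n_sets=n_sets,
        seed=seed,
        min_cov=min_cov,
        max_cov=max_cov,
        annotate_significance=annotate_significance,
    )
    all_sites = pd.concat(
        [r.sites for r in result.populations.values()], ignore_index=True
    )
    write_site_table_cols = [
        "site_id",
        "chrom",
        "pos",
        "population",
        "p_start",
        "p_end",
        "loglik",
        "direction",
        "boundary_adjusted",
    ]
    if annotate_significance:
        write_site_table_cols.append("p_change")
    all_sites[write_site_table_cols].to_csv(
        outdir / "site_logliks.tsv", sep="\t", index=False, float_format="%.10g"
    )
    for popn, r in result.populations.items():
        r.null.to_frame().to_csv(
            outdir / f"null_means_{popn}.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary(), fh, sort_keys=True, indent=2)
    write_manifest(
        outdir,
        config={
            "n_sets": n_sets,
            "min_cov": min_cov,
            "max_cov": max_cov,
            "spec": result.summary()["spec"],
        },
        inputs={
            "founder": founder_path,
            "gen12": gen12_path,
            "gen75": gen75_path,
            "variants": variants_path,
        },
        seed=seed,
        stage_counts=result.stage_counts,
    )
    if make_figure:
        try:
            _figure(result, outdir / "nulltest.png")
        except Exception as exc:  # figures must never block the numbers
            (outdir / "figure_error.txt").write_text(str(exc))
    return result


def _figure(result: DriftTestResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pops = list(result.populations)
    directions = [Direction.TOWARDS_MAJOR.value, Direction.TOWARDS_MINOR.value]
    fig, axes = plt.subplots(
        len(pops), 2, figsize=(9, 2.2 * len(pops)), squeeze=False
    )
    for i, popn in enumerate(pops):
        r = result.populations[popn]
        for j, d in enumerate(directions):
            ax = axes[i][j]
            means = r.null.direction_means[d]
            means = means[np.isfinite(means)]
            if len(means):
                ax.hist(means, bins=40, color="grey", alpha=0.7)
            if r.observed_means.get(d) is not None:
                ax.axvline(r.observed_means[d], color="red")
            ax.set_title(f"{popn} — {d}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_denovo(
    candidates_path,
    catalog_path,
    outdir,
    prior_paths=(),
    thresholds: FilterThresholds = FilterThresholds(),
):
    """Run the de novo filter cascade on a candidate table; write reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not Path(catalog_path).exists():
        raise FileNotFoundError(f"known-variant catalog not found: {catalog_path}")
    cand_df = read_site_table(candidates_path)
    catalog = catalog_keys(pd.read_csv(catalog_path, sep="\t"))
    priors = [
        catalog_keys(pd.read_csv(p, sep="\t"))
        for p in prior_paths
        if Path(p).exists() and Path(p).stat().st_size > 0
    ]
    candidates = (
        candidates_from_table(
            cand_df, min_alt_reads=thresholds.min_alt_reads_presence
        )
        if len(cand_df)
        else []
    )
    result = run_cascade(candidates, catalog, priors, thresholds)
    rows = []
    for c in candidates:
        fate = result.removed.get(c.key)
        rows.append(
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref,
                "alt": c.alt,
                "is_indel": c.is_indel,
                "carrier_population": c.carrier_population() or "",
                "total_reads": c.total_reads,
                "quality_score": c.quality_score,
                "maxqual": c.maxqual,
                "status": "removed" if fate else "survivor",
                "reasons": ";".join(fate) if fate else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "is_indel",
            "carrier_population",
            "total_reads",
            "quality_score",
            "maxqual",
            "status",
            "reasons",
        ],
    ).to_csv(outdir / "denovo_calls.tsv", sep="\t", index=False)
    with open(outdir / "denovo_summary.json", "w") as fh:
        json.dump(result.summary(), fh, sort_keys=True, indent=2)
    write_manifest(
        outdir,
        config={
            "thresholds": {
                "min_quality": thresholds.min_quality,
                "min_reads": thresholds.min_reads,
                "max_reads": thresholds.max_reads,
                "min_maxqual": thresholds.min_maxqual,
            }
        },
        inputs={
            "candidates": candidates_path,
            "catalog": catalog_path,
            **{f"prior_{i}": p for i, p in enumerate(prior_paths)},
        },
        seed=None,
    )
    return result
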