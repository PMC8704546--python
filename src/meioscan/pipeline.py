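"""End-to-end pipeline: simulate/load genotypes, call crossovers, detect
hotspots, compute population statistics, map QTLs, and render a consolidated
report.  Every stage's outputs land in one directory with a manifest
recording inputs, parameters, versions and the seed."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .calling import call_crossovers, count_matrix
from .genotypes import (
    ChromosomeDef,
    GenotypeMatrix,
    read_genome,
    read_genotype_table,
    write_events_bed,
    write_genome,
    write_genotype_table,
)
from .hotspots import (
    Hotspot,
    WindowModel,
    detect_hotspots,
    fit_window_model,
    hco_per_isolate,
    hotspot_genome_share,
    snp_density_test,
    window_counts,
    write_hotspots_bed,
)
from .popstats import (
    length_co_correlation,
    mating_type_compare,
    pearson,
    population_summary,
    segregation_test,
)
from .qtl import (
    associate_hotspots,
    count_genes_in_interval,
    extract_peaks,
    peaks_table,
    permutation_threshold,
    scan_trait,
)
from .simulate import demo_config, simulate_population, write_truth_bed


class PipelineError(RuntimeError):
    """A stage failure, named after the stage that raised it."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    genome: str | None = None  # path; None with simulate=True uses the demo genome
    genotype: str | None = None  # path; None simulates a population
    phenotype: str | None = None  # optional TSV: isolate, mat_allele
    annotation: str | None = None  # optional GFF3 for gene counts in QTL CIs
    simulate: dict = field(default_factory=dict)  # overrides for the demo simulation
    min_run: int = 5
    window_size: int = 10_000
    alpha: float = 1e-4
    step_cM: float = 1.0
    n_perm: int = 1000
    qtl_alpha: float = 0.05
    max_gap_bp: int = 50_000
    cim: bool = False
    traits: list[str] | None = None  # None = TCO, HCO and every COchr

    def validate(self) -> None:
        checks = [
            (self.min_run >= 1, "min_run must be >= 1"),
            (self.window_size > 0, "window_size must be positive"),
            (0 < self.alpha < 1, "alpha must be in (0,1)"),
            (self.step_cM > 0, "step_cM must be positive"),
            (self.n_perm >= 100, "n_perm must be >= 100"),
            (0 < self.qtl_alpha < 1, "qtl_alpha must be in (0,1)"),
            (self.max_gap_bp >= 0, "max_gap_bp must be non-negative"),
        ]
        for ok, msg in checks:
            if not ok:
                raise PipelineError(f"config: {msg}")


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path, "rt", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def _trait_name(chrom: str) -> str:
    return "COchr" + chrom.removeprefix("chr")


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute call -> hotspots -> stats -> qtl and write the report bundle.

    Returns the bundle: in-memory results plus the paths of every artifact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"out_dir": str(out), "seed": config.seed}

    # -- inputs -------------------------------------------------------------
    matrix, genome, mat_alleles, truth = _load_inputs(config, out)
    bundle["n_isolates"] = matrix.n_isolates
    bundle["n_markers"] = matrix.n_markers

    # -- crossover calling ---------------------------------------------------
    events, counts = _stage_call(config, matrix, genome, out)
    bundle["events"] = events
    bundle["counts_path"] = str(out / "counts.tsv")

    # -- hotspot scan --------------------------------------------------------
    model, hotspots, counts, hotspot_summary = _stage_hotspots(
        config, events, counts, matrix, genome, out
    )
    bundle["window_model"] = model
    bundle["hotspots"] = hotspots
    bundle["hotspot_summary"] = hotspot_summary

    # -- population statistics ----------------------------------------------
    stats_report = _stage_stats(config, counts, genome, mat_alleles, out)
    bundle["stats"] = stats_report
    bundle["counts"] = counts

    # -- QTL mapping ---------------------------------------------------------
    qtl_peaks, thresholds = _stage_qtl(config, matrix, counts, genome, hotspots, out)
    bundle["qtl_peaks"] = qtl_peaks
    bundle["qtl_thresholds"] = thresholds

    # -- manifest + report ----------------------------------------------------
    manifest = {
        "package": {"name": "meioscan", "version": __version__},
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("out_dir", "simulate") or not isinstance(v, dict)
        },
        "inputs": {
            "genome": config.genome or "simulated (demo genome)",
            "genotype": config.genotype or "simulated",
            "phenotype": config.phenotype,
            "annotation": config.annotation,
        },
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.md").write_text(render_report(bundle))
    bundle["report_path"] = str(out / "report.md")
    return bundle


@_stage("inputs")
def _load_inputs(config: PipelineConfig, out: Path):
    truth = None
    mat_alleles = None
    if config.genotype is None:
        sim_cfg = demo_config(seed=config.seed, **config.simulate)
        if config.genome is not None:
            sim_cfg.genome = read_genome(config.genome)
        sim = simulate_population(sim_cfg)
        matrix, truth, mat_alleles = sim.matrix, sim.truth, sim.mat_alleles
        genome = sim_cfg.genome
        write_genotype_table(matrix, out / "genotype.tsv")
        write_genome(genome, out / "genome.tsv")
        write_truth_bed(truth, out / "truth.bed")
        echo = {
            "seed": sim_cfg.seed,
            "n_isolates": sim_cfg.n_isolates,
            "markers_per_chrom": sim_cfg.markers_per_chrom,
            "lambda_per_chrom": sim_cfg.lambda_per_chrom,
            "interference_nu": sim_cfg.interference_nu,
            "error_rate": sim_cfg.error_rate,
            "missing_rate": sim_cfg.missing_rate,
            "n_hotspot_windows": len(sim_cfg.hotspot_spec),
            "controllers": [asdict(q) for q in sim_cfg.qtl_spec],
            "mat_locus": sim_cfg.mat_locus,
        }
        (out / "sim_config.json").write_text(json.dumps(echo, indent=2, default=str))
    else:
        if config.genome is None:
            raise PipelineError("stage 'inputs' failed: a genome TSV is required")
        genome = read_genome(config.genome)
        matrix = read_genotype_table(config.genotype, genome)
    if config.phenotype is not None:
        ph = pd.read_csv(config.phenotype, sep="\t", dtype=str)
        mat_alleles = ph.set_index(ph.columns[0])[ph.columns[1]]
    return matrix, genome, mat_alleles, truth


@_stage("call")
def _stage_call(config: PipelineConfig, matrix, genome, out: Path):
    events = call_crossovers(matrix, min_run=config.min_run)
    counts = count_matrix(events, matrix.isolates, genome)
    write_events_bed(events, out / "events.bed")
    counts.to_csv(out / "counts.tsv", sep="\t")
    return events, counts


@_stage("hotspots")
def _stage_hotspots(config: PipelineConfig, events, counts, matrix, genome, out: Path):
    wc = window_counts(events, genome, config.window_size)
    model = fit_window_model(wc, config.window_size, config.alpha)
    hotspots = detect_hotspots(wc, model)
    hco, share = hco_per_isolate(events, hotspots, matrix.isolates)
    counts = counts.copy()
    counts["HCO"] = hco
    wc.to_csv(out / "windows.tsv", sep="\t", index=False)
    write_hotspots_bed(hotspots, out / "hotspots.bed")
    summary = {
        "window_size": model.window_size,
        "lambda": model.lam,
        "alpha": model.alpha,
        "threshold_k": model.threshold_k,
        "n_hotspots": len(hotspots),
        "genome_share_pct": round(100.0 * hotspot_genome_share(hotspots, genome), 1),
        "hco_share_pct": round(100.0 * share, 1),
        "fold_range": (
            [round(min(h.fold for h in hotspots)), round(max(h.fold for h in hotspots))]
            if hotspots
            else None
        ),
    }
    if hotspots and len(hotspots) >= 2:
        positions = pd.DataFrame(
            {
                "chromosome": [m.chromosome for m in matrix.markers],
                "pos_bp": [m.pos_bp for m in matrix.markers],
            }
        )
        anova = snp_density_test(positions, hotspots, genome, config.window_size)
        summary["snp_density_anova"] = {
            "F": anova.F,
            "p": anova.p,
            "mean_markers_hotspot": anova.mean_hotspot,
            "mean_markers_background": anova.mean_background,
        }
    (out / "hotspot_summary.json").write_text(json.dumps(summary, indent=2))
    counts.to_csv(out / "counts.tsv", sep="\t")
    return model, hotspots, counts, summary


@_stage("stats")
def _stage_stats(config: PipelineConfig, counts, genome, mat_alleles, out: Path):
    report: dict[str, Any] = {"population": population_summary(counts, genome)}
    if "HCO" in counts.columns and counts["TCO"].std() > 0 and counts["HCO"].std() > 0:
        r, p = pearson(counts["HCO"], counts["TCO"])
        report["hco_tco_correlation"] = {"r": r, "p": p}
    try:
        r, p = length_co_correlation(genome, counts)
        report["length_co_correlation"] = {"r": r, "p": p}
    except ValueError:
        pass
    if mat_alleles is not None:
        report["mating_type"] = mating_type_compare(counts, mat_alleles)
        report["segregation"] = segregation_test(mat_alleles)
    (out / "stats.json").write_text(json.dumps(report, indent=2))
    return report


@_stage("qtl")
def _stage_qtl(config: PipelineConfig, matrix, counts, genome, hotspots, out: Path):
    if not matrix.has_cM():
        (out / "qtl_peaks.tsv").write_text("")
        return [], {}
    traits = config.traits
    if traits is None:
        traits = ["TCO"] + (["HCO"] if "HCO" in counts.columns else [])
        traits += [_trait_name(c.name) for c in genome]
    all_peaks = []
    thresholds: dict[str, float] = {}
    for i, trait in enumerate(traits):
        col = trait if trait in counts.columns else None
        if col is None and trait.startswith("COchr"):
            for c in genome:
                if _trait_name(c.name) == trait:
                    col = c.name
                    break
        if col is None or col not in counts.columns:
            raise PipelineError(f"stage 'qtl' failed: unknown trait {trait!r}")
        y = counts[col]
        if y.std() == 0:
            continue
        res = scan_trait(matrix, y, trait=trait, step_cM=config.step_cM, cim=config.cim)
        thr = permutation_threshold(
            matrix,
            y,
            n_perm=config.n_perm,
            alpha=config.qtl_alpha,
            seed=(config.seed * 1009 + 7919 * i) % (2**31),
            step_cM=config.step_cM,
            cim=config.cim,
        )
        thresholds[trait] = thr
        res.profile().to_csv(out / f"qtl_lod_{trait}.tsv", sep="\t", index=False)
        peaks = extract_peaks(res, thr)
        peaks = associate_hotspots(peaks, hotspots, config.max_gap_bp)
        if config.annotation:
            peaks = [
                type(p)(**{**asdict(p), "n_genes": count_genes_in_interval(
                    config.annotation, p.chromosome, p.ci_lo_bp, p.ci_hi_bp
                )})
                for p in peaks
            ]
        all_peaks.extend(peaks)
    peaks_table(all_peaks).to_csv(out / "qtl_peaks.tsv", sep="\t", index=False)
    (out / "qtl_thresholds.json").write_text(json.dumps(thresholds, indent=2))
    return all_peaks, thresholds


# ---------------------------------------------------------------------------
# report


def render_report(bundle: dict[str, Any]) -> str:
    """Human-readable markdown summary of a completed bundle."""
    missing = [k for k in ("counts", "hotspot_summary", "stats") if k not in bundle]
    if missing:
        return "# Crossover-landscape report\n\nIncomplete bundle; missing: " + ", ".join(missing)
    counts = bundle["counts"]
    hs = bundle["hotspot_summary"]
    pop = bundle["stats"]["population"]
    lines = [
        "# Crossover-landscape report",
        "",
        f"Seed: {bundle.get('seed')} | isolates: {pop['n_isolates']} | "
        f"markers: {bundle.get('n_markers', 'n/a')}",
        "",
        "## Crossover summary",
        "",
        f"- Total crossovers: {pop['total_crossovers']}",
        f"- TCO per isolate: mean {pop['mean_tco']:.2f}, range {pop['min_tco']}-{pop['max_tco']}",
        "",
        "| Chromosome | mean CO / individual |",
        "|---|---|",
    ]
    for chrom, m in pop["mean_co_per_chromosome"].items():
        lines.append(f"| {chrom} | {m:.2f} |")
    lines += [
        "",
        "## Hotspots",
        "",
        f"- Window size: {hs['window_size']} bp; per-window mean {hs['lambda']:.3f}; "
        f"Poisson threshold >= {hs['threshold_k']} (alpha {hs['alpha']:g})",
        f"- {hs['n_hotspots']} hotspots ({hs['genome_share_pct']:.1f}% of genome)",
        f"- Crossovers in hotspots: {hs['hco_share_pct']:.1f}% of all events",
    ]
    if hs.get("fold_range"):
        lines.append(
            f"- Fold enrichment over genome average: {hs['fold_range'][0]}-{hs['fold_range'][1]}x"
        )
    if "hco_tco_correlation" in bundle["stats"]:
        c = bundle["stats"]["hco_tco_correlation"]
        lines.append(f"- HCO ~ TCO Pearson r = {c['r']:.3f} (p = {c['p']:.2e})")
    if "segregation" in bundle["stats"]:
        seg = bundle["stats"]["segregation"]
        ratio = " : ".join(str(v) for v in seg["counts"].values())
        lines.append(
            f"- Mating-type segregation {ratio} (chi2 = {seg['chi2']:.3f}, p = {seg['p']:.2f})"
        )
    lines += ["", "## QTLs", ""]
    peaks = bundle.get("qtl_peaks", [])
    if peaks:
        tbl = peaks_table(peaks)
        lines.append("| " + " | ".join(tbl.columns) + " |")
        lines.append("|" + "---|" * len(tbl.columns))
        for _, row in tbl.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row) + " |")
    else:
        lines.append("No QTL peaks exceeded the permutation threshold.")
    lines.append("")
    return "\n".join(lines)
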