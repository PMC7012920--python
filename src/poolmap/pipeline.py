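"""Study configuration and the umbrella pipeline.

``run_all`` executes the full synthetic study from one seed: population
simulation, extreme-pool selection, pooled read sampling, the QTL-Seq
window scan with confidence envelopes, the linkage LOD scan, the
pool-contrast depth fixture, and the candidate-gene report, writing every
stage's table plus a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import candidates as cand
from . import depthscan, io, linkage, popsim, qtlseq

__all__ = ["Config", "load_config", "run_all", "StageError", "get_logger"]

logger = logging.getLogger("poolmap")


def get_logger(verbose: bool = False) -> logging.Logger:
    """Stage-tagged stderr logging."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[poolmap:%(stage)s] %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    return logger


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class Config:
    """Study configuration; defaults are the synthetic study conditions."""

    # population simulation
    n_individuals: int = 200
    mean_crossovers: float = 25.0
    bias: float = 0.2
    n_chromosomes: int = 10
    chrom_length: int = 30_000_000
    markers_per_chrom: int = 5_000
    # pooling and read sampling
    pool_size: int = 25
    high_threshold: float = 0.7
    low_value: float = 0.0
    depth: int = 30
    error_rate: float = 0.01
    poisson_depth: bool = False
    # QTL-Seq analysis
    min_depth: int = 5
    filter_low: float = 0.3
    filter_high: float = 0.7
    filter_mode: str = "both-pools"
    window: int = 200_000
    step: int = 20_000
    ci_levels: tuple = (0.95, 0.99)
    n_sims: int = 1000
    k_windows: int = 5
    # linkage
    bin_size: int | None = None
    # depth-scan fixture
    dip_factor: float = 0.2
    insertion_halo: int = 100
    smooth_window: int = 50
    ratio_threshold: float = 0.5
    min_dip_length: int = 50
    # reproducibility
    seed: int = 0

    def stage_seed(self, k: int) -> int:
        return int((self.seed * 1_000_003 + k) % 2**31)


def load_config(source) -> Config:
    """Build a Config from a YAML path or mapping; unknown keys are a
    schema error naming the offending key."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    valid = {f.name for f in dataclasses.fields(Config)}
    for key in data:
        if key not in valid:
            raise ValueError(f"unknown config key: {key!r}")
    if "ci_levels" in data:
        data["ci_levels"] = tuple(data["ci_levels"])
    return Config(**data)


def run_all(config: Config, outdir, verbose: bool = False) -> dict:
    """Run the complete synthetic study; returns the manifest dict."""
    get_logger(verbose)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "version": __version__,
        "outputs": {},
    }

    def out(name: str, fname: str) -> Path:
        p = outdir / fname
        manifest["outputs"][name] = str(p)
        return p

    stage = "simulate"
    try:
        _log(stage, f"seed={config.stage_seed(1)} simulating marker map and population")
        marker_set = popsim.default_marker_set(
            config.n_chromosomes, config.chrom_length, config.markers_per_chrom
        )
        arch = popsim.default_architecture(marker_set)
        eggs, egg_rec = popsim.simulate_gametes(
            marker_set, config.n_individuals, config.mean_crossovers,
            config.bias, seed=config.stage_seed(1),
        )
        pollen, pol_rec = popsim.simulate_gametes(
            marker_set, config.n_individuals, config.mean_crossovers,
            config.bias, seed=config.stage_seed(2),
        )
        pop = popsim.make_f2_population(
            marker_set, eggs, pollen, seed=config.stage_seed(3),
            egg_crossovers=egg_rec, pollen_crossovers=pol_rec,
        )
        pop = popsim.assign_phenotypes(pop, arch)
        io.write_marker_map(marker_set, out("marker_map", "markers.tsv"))
        io.write_genotypes(pop, out("genotypes", "genotypes.tsv"))
        io.write_phenotypes(pop, out("phenotypes", "phenotypes.tsv"))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "pools"
    try:
        _log(stage, f"seed={config.stage_seed(4)} selecting extreme pools")
        high, low = popsim.select_pools(
            pop.phenotypes, config.high_threshold, config.low_value,
            config.pool_size, seed=config.stage_seed(4),
        )
        depth_high = popsim.simulate_pool_reads(
            pop, high, config.depth, config.error_rate,
            seed=config.stage_seed(5), poisson_depth=config.poisson_depth,
        )
        depth_low = popsim.simulate_pool_reads(
            pop, low, config.depth, config.error_rate,
            seed=config.stage_seed(6), poisson_depth=config.poisson_depth,
        )
        depth_table = pd.concat([depth_high, depth_low], ignore_index=True)
        io.write_depth_table(depth_table, out("depth_table", "allele_depths.tsv"))
        io.write_vcf(marker_set, depth_high, depth_low, out("vcf", "synthetic.vcf"))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "qtlseq"
    try:
        _log(stage, f"seed={config.stage_seed(7)} window scan")
        idx_a = qtlseq.compute_snp_index(depth_table, "A", config.min_depth)
        idx_b = qtlseq.compute_snp_index(depth_table, "B", config.min_depth)
        idx_a = qtlseq.filter_cosegregating(
            idx_a, config.filter_low, config.filter_high, config.filter_mode
        )
        idx_b = qtlseq.filter_cosegregating(
            idx_b, config.filter_low, config.filter_high, config.filter_mode
        )
        windows = qtlseq.window_deltas(
            idx_a, idx_b, config.window, config.step, marker_set.chrom_lengths()
        )
        env = qtlseq.confidence_envelope(
            windows, config.pool_size, config.n_sims, config.ci_levels,
            seed=config.stage_seed(7),
        )
        windows = qtlseq.attach_envelope(windows, env)
        interval = qtlseq.find_candidate_interval(
            windows, config.k_windows,
            snp_positions=idx_a[["chrom", "pos"]].drop_duplicates(),
        )
        io.write_windows_bed(windows, out("windows", "windows.tsv"))
        io.write_tsv(
            pd.DataFrame([dataclasses.asdict(interval)]),
            out("interval", "candidate_interval.tsv"),
        )
        manifest["qtlseq_peak"] = {
            "chrom": interval.chromosome,
            "raw_start": interval.raw_start,
            "raw_end": interval.raw_end,
            "peak_delta": interval.peak_delta,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "linkage"
    try:
        _log(stage, "LOD scan")
        profile = linkage.lod_scan(pop, config.bin_size)
        peak = linkage.peak_summary(profile)
        io.write_tsv(profile, out("lod", "lod_profile.tsv"))
        manifest["linkage_peak"] = peak
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "depthscan"
    try:
        _log(stage, f"seed={config.stage_seed(8)} pool depth contrast fixture")
        pathway = cand.packaged_pathway_table()
        gene = pathway.iloc[0]  # negative regulator carrying the insertion
        region_start = int(gene["start"]) - 30_000
        profile_depth = depthscan.simulate_depth_profiles(
            region_length=60_000,
            base_depth=config.depth,
            insertion_pos=int((gene["start"] + gene["end"]) // 2),
            insertion_halo=config.insertion_halo,
            dip_factor=config.dip_factor,
            seed=config.stage_seed(8),
            affected_pool="high",
            chromosome=str(gene["chrom"]),
            start=region_start,
        )
        dips = depthscan.detect_depth_dips(
            profile_depth, config.smooth_window, config.ratio_threshold,
            config.min_dip_length,
        )
        manifest["depth_dips"] = [dataclasses.asdict(d) for d in dips]
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "candidates"
    try:
        _log(stage, "candidate report")
        annotation = [
            cand.GeneRecord(
                str(r["gene_id"]), str(r["chrom"]), int(r["start"]), int(r["end"]),
                name=str(r["name"]),
            )
            for _, r in pathway.iterrows()
        ]
        report = cand.report_candidates([interval], dips, annotation, pathway)
        io.write_tsv(report, out("report", "candidate_report.tsv"))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    manifest_path = outdir / "manifest.json"
    manifest["outputs"]["manifest"] = str(manifest_path)
    with manifest_path.open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    _log("done", f"manifest written to {manifest_path}")
    return manifest
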