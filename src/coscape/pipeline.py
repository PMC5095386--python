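"""Pipeline orchestration: configs, fixtures, end-to-end runs and reports.

A run chains simulate -> filter -> phase/segment -> crossovers ->
landscape -> coupling on one seed and emits a machine-readable JSON report
(per-chromosome stats, hotspot/coldspot lists, correlations, provenance).
Identical configs produce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import blocks as blocks_mod
from . import coupling as coupling_mod
from . import datasets, landscape, markers, simulate

PKG_VERSION = "0.1.0"


def small_sim_config(seed: int = 0, **overrides) -> simulate.SimConfig:
    """A 2-chromosome, 10-F2 toy cross for tests and docs (fast, determinate)."""
    params: dict[str, Any] = dict(
        chrom_lengths={"chr1": 5_000_000, "chr2": 4_000_000},
        marker_density=1.5,
        n_f2=10,
        mean_co_per_gamete=1.0,
        depth_mean=50.0,
        base_error=0.01,
        geno_error=0.001,
        seed=seed,
    )
    params.update(overrides)
    return simulate.SimConfig(**params)


def study_sim_config(seed: int = 0, **overrides) -> simulate.SimConfig:
    """Study-scale conditions: 8 chromosomes, ~225 Mbp, 24 F2s, ~51x depth.

    Chromosome lengths and per-chromosome crossover intensities follow the
    published intraspecific peach summary (per-gamete mean = half the mean
    CO count per F2), marker density 1.5/kbp.
    """
    lengths = datasets.study_chrom_lengths_bp()
    mean_per_gamete = {
        c: m / 2.0 for c, m in zip(datasets.CHROMOSOMES, datasets.INTRASPECIFIC.mean_co)
    }
    params: dict[str, Any] = dict(
        chrom_lengths=lengths,
        marker_density=1.5,
        n_f2=datasets.INTRASPECIFIC.n_f2,
        mean_co_per_gamete=mean_per_gamete,
        depth_mean=50.0,
        base_error=0.01,
        geno_error=0.001,
        seed=seed,
    )
    params.update(overrides)
    return simulate.SimConfig(**params)


def make_fixture(seed: int = 0, **overrides):
    """Deterministic small fixture: (variant table, truth, config)."""
    cfg = small_sim_config(seed=seed, **overrides)
    table, truth = simulate.simulate_f2_population(cfg)
    return table, truth, cfg


@dataclass
class RunConfig:
    """End-to-end run parameters (one YAML document)."""

    sim: simulate.SimConfig
    outdir: str = "coscape_run"
    window_size: int = landscape.WINDOW_SIZE_DEFAULT
    n_rand: int = landscape.N_RAND_DEFAULT
    alpha: float = landscape.ALPHA_DEFAULT
    seed_k: int = 25
    seed_min_span: int = 10_000
    merge_tol: int = 0
    coupling_radius: int = 2_000
    filter_params: markers.FilterParams = field(default_factory=markers.FilterParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "sim" not in doc:
            raise ValueError("run config must contain a 'sim' section")
        sim = simulate.SimConfig(**doc.pop("sim"))
        fp = markers.FilterParams(**doc.pop("filter_params", {}))
        return cls(sim=sim, filter_params=fp, **doc)


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, write: bool = True) -> dict:
    """Execute the full pipeline on a simulated cross and build the report."""
    table, truth = simulate.simulate_f2_population(cfg.sim)
    matrix = markers.filter_variants(table, cfg.filter_params)
    events, blocks, phase_info = blocks_mod.call_intraspecific(
        matrix, k=cfg.seed_k, min_span=cfg.seed_min_span
    )

    lengths = cfg.sim.chrom_lengths
    stats = landscape.chromosome_stats(events, lengths, cfg.sim.n_f2)
    windows = landscape.window_counts(events, lengths, cfg.window_size)
    regions = landscape.merge_similar(windows, cfg.merge_tol)
    called = landscape.randomization_test(
        regions, lengths, n_events=len(events), n_rand=cfg.n_rand,
        seed=cfg.sim.seed, alpha=cfg.alpha,
    )
    called, spot_summary = landscape.region_rates(called, cfg.sim.n_f2, cfg.alpha)

    per_chrom = stats[stats["chrom"] != "All"]
    if len(per_chrom) >= 3:
        corr = landscape.spearman(per_chrom["length_mbp"], per_chrom["rate_cm_per_mbp"])
        corr_entry = {"rho": corr.rho, "pvalue": corr.pvalue, "method": corr.method}
    else:  # rank correlation undefined below 3 chromosomes
        corr_entry = {"rho": None, "pvalue": None, "method": "skipped (fewer than 3 chromosomes)"}
    score = simulate.score_crossovers(events, truth)

    report: dict[str, Any] = {
        "provenance": {
            "seed": cfg.sim.seed,
            "config_hash": _config_hash(cfg),
            "version": PKG_VERSION,
        },
        "markers": {"n_retained": matrix.n_markers(), "n_records": table.n_records()},
        "phasing": phase_info,
        "crossovers": {
            "n_events": int(len(events)),
            "mean_per_f2": float(len(events)) / cfg.sim.n_f2,
        },
        "chromosome_stats": stats.to_dict(orient="records"),
        "rate_vs_length": corr_entry,
        "hotspots": called[called["class"] == "hotspot"][
            ["chrom", "start", "end", "observed", "p_hot", "rate_cm_per_mbp"]
        ].to_dict(orient="records"),
        "coldspots": called[called["class"] == "coldspot"][
            ["chrom", "start", "end", "observed", "p_cold", "rate_cm_per_mbp"]
        ].to_dict(orient="records"),
        "hotspot_coldspot_summary": spot_summary,
        "truth_recovery": score,
    }

    if truth.mutations is not None and len(truth.mutations):
        prox = coupling_mod.proximity_enrichment_test(
            truth.mutations, events, lengths, radius=cfg.coupling_radius,
            n_rand=min(cfg.n_rand, 1000), seed=cfg.sim.seed,
        )
        binned = coupling_mod.binned_correlation(truth.mutations, events, lengths)
        report["coupling"] = {
            "proximity": prox,
            "binned": binned.to_dict(orient="records"),
        }

    if write:
        outdir = pathlib.Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        events.to_csv(outdir / "events.tsv", sep="\t", index=False)
        blocks.to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
        called.to_csv(outdir / "regions.tsv", sep="\t", index=False)
        stats.to_csv(outdir / "chromosome_stats.tsv", sep="\t", index=False)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def report_json(report: Mapping) -> str:
    """Canonical JSON serialization of a report (stable across runs)."""
    return json.dumps(report, indent=2, sort_keys=True, default=_json_default)
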