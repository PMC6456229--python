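"""Orchestration: simulate -> screen -> filter -> start -> enrich.

A pipeline run is driven by a plain key-value (YAML) config and is
deterministic for a given config: each stage reads delimited-text
tables, writes one result table into the output directory, and logs
counts in and out so the candidate funnel (e.g. 66 size mutants ->
32 small -> 21 fast-growing) is auditable.  A JSON manifest records the
package version, parameters and per-stage row counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .datatypes import BenchmarkSet
from .enrichment import (
    average_replicates,
    chip_enrichment_threshold,
    overlap_test,
    term_enrichment,
)
from .growth import start_candidate_filter, summarize_growth
from .phenome import aggregate_replicates, calibrate_cutoff, screen_report
from .start import critical_size, epistasis_call

logger = logging.getLogger("sizephenome.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_screen_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated stage inputs and parameters for one pipeline run."""

    outdir: Path
    seed: int = 0
    # screen stage (required)
    distributions: Path | None = None
    wt_map: Path | None = None
    cutoff_pct: float = 20.0
    benchmark_whi: tuple[str, ...] = ()
    benchmark_lge: tuple[str, ...] = ()
    # optional stages
    growth_curves: Path | None = None
    max_increase_pct: float = 10.0
    timecourses: Path | None = None
    budding_threshold: float = 0.25
    epistasis_medians: Path | None = None
    epistasis_tolerance_pct: float = 5.0
    chip_probes: Path | None = None
    k_sd: float = 2.0
    enrich_query: Path | None = None
    enrich_sets: Path | None = None
    enrich_universe: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent

        def _p(section: dict, key: str) -> Path | None:
            v = section.get(key)
            if v is None:
                return None
            p = Path(v)
            return p if p.is_absolute() else base / p

        screen = raw.get("screen", {})
        growth = raw.get("growth", {})
        start = raw.get("start", {})
        epi = raw.get("epistasis", {})
        chip = raw.get("chip", {})
        enrich = raw.get("enrich", {})
        bench = screen.get("benchmark", {})
        outdir = raw.get("outdir", "results")
        outdir = Path(outdir) if Path(outdir).is_absolute() else base / outdir
        return cls(
            outdir=outdir,
            seed=int(raw.get("seed", 0)),
            distributions=_p(screen, "distributions"),
            wt_map=_p(screen, "wt_map"),
            cutoff_pct=float(screen.get("cutoff_pct", 20)),
            benchmark_whi=tuple(bench.get("whi", [])),
            benchmark_lge=tuple(bench.get("lge", [])),
            growth_curves=_p(growth, "curves"),
            max_increase_pct=float(growth.get("max_increase_pct", 10)),
            timecourses=_p(start, "timecourses"),
            budding_threshold=float(start.get("threshold", 0.25)),
            epistasis_medians=_p(epi, "medians"),
            epistasis_tolerance_pct=float(epi.get("tolerance_pct", 5)),
            chip_probes=_p(chip, "probes"),
            k_sd=float(chip.get("k_sd", 2)),
            enrich_query=_p(enrich, "query"),
            enrich_sets=_p(enrich, "sets"),
            enrich_universe=_p(enrich, "universe"),
        )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("screen")
def _run_screen(config: PipelineConfig, manifest: dict) -> pd.DataFrame:
    if config.distributions is None or config.wt_map is None:
        raise ValueError("screen stage needs 'distributions' and 'wt_map' inputs")
    dists = io.read_distribution_table(config.distributions)
    wt_map = io.read_wt_map(config.wt_map)
    by_strain: dict[str, list] = {}
    for d in dists:
        by_strain.setdefault(d.strain_id, []).append(d)
    summaries = {s: aggregate_replicates(reps) for s, reps in by_strain.items()}

    cutoff = config.cutoff_pct
    if config.benchmark_whi or config.benchmark_lge:
        cutoff = calibrate_cutoff(
            summaries,
            wt_map,
            BenchmarkSet(config.benchmark_whi, config.benchmark_lge),
        )
        manifest["calibrated_cutoff_pct"] = cutoff
    report, counts = screen_report(summaries, wt_map, cutoff)
    report.to_csv(config.outdir / "screen_report.csv", index=False)
    manifest["screen"] = {
        "n_strains_in": len(summaries),
        "cutoff_pct": cutoff,
        "counts": counts,
    }
    logger.info("screen: %d strains -> counts %s", len(summaries), counts)
    return report


@_stage("growth")
def _run_growth(config: PipelineConfig, report: pd.DataFrame, manifest: dict) -> None:
    curves = io.read_growth_table(config.growth_curves)
    untreated = {c.strain_id: c for c in curves if c.condition == "untreated"}
    rows = []
    doubling = {}
    for strain, curve in sorted(untreated.items()):
        summ = summarize_growth(curve)
        doubling[strain] = summ.doubling_time_min
        rows.append(
            {
                "strain": strain,
                "doubling_time_min": summ.doubling_time_min,
                "t_half_min": summ.t_half_min,
            }
        )
    pd.DataFrame(rows).to_csv(config.outdir / "growth_summary.csv", index=False)

    whi = report.loc[report["call"] == "Whi", "strain"].tolist()
    wt_map = dict(zip(report["strain"], report["wt"]))
    retained = start_candidate_filter(
        whi, doubling, wt_map, doubling, config.max_increase_pct
    )
    pd.DataFrame({"strain": retained}).to_csv(
        config.outdir / "start_candidates.csv", index=False
    )
    manifest["growth"] = {
        "n_curves": len(curves),
        "n_whi_in": len(whi),
        "n_candidates_out": len(retained),
        "max_increase_pct": config.max_increase_pct,
    }
    logger.info("growth filter: %d Whi -> %d candidates", len(whi), len(retained))


@_stage("start")
def _run_start(config: PipelineConfig, manifest: dict) -> None:
    tcs = io.read_timecourse_table(config.timecourses)
    rows = []
    for tc in tcs:
        res = critical_size(tc, config.budding_threshold)
        rows.append(
            {
                "strain": tc.strain_id,
                "critical_size_fL": res.critical_size_fL,
                "threshold_fraction": res.threshold_fraction,
            }
        )
    pd.DataFrame(rows).to_csv(config.outdir / "critical_size.csv", index=False)
    manifest["start"] = {"n_timecourses": len(tcs)}


@_stage("epistasis")
def _run_epistasis(config: PipelineConfig, manifest: dict) -> None:
    table = io.read_epistasis_table(config.epistasis_medians)
    rows = []
    for rec in table.itertuples(index=False):
        call = epistasis_call(
            rec.wt_median_fL,
            rec.a_median_fL,
            rec.b_median_fL,
            rec.double_median_fL,
            config.epistasis_tolerance_pct,
            pair=(rec.gene_a, rec.gene_b),
        )
        rows.append(
            {"gene_a": rec.gene_a, "gene_b": rec.gene_b, "relation": call.relation}
        )
    pd.DataFrame(rows).to_csv(config.outdir / "epistasis_calls.csv", index=False)
    manifest["epistasis"] = {"n_pairs": len(rows)}


@_stage("chip")
def _run_chip(config: PipelineConfig, manifest: dict) -> None:
    ps = io.read_probe_table(config.chip_probes)
    means = average_replicates(ps)
    res = chip_enrichment_threshold(means, ps.probe_ids, ps.region_types, config.k_sd)
    pd.DataFrame({"probe_id": list(res.enriched_ids)}).to_csv(
        config.outdir / "chip_enriched.csv", index=False
    )
    manifest["chip"] = {
        "n_probes": ps.n_probes,
        "cutoff_log2": res.cutoff_log2,
        "fold_change_at_cutoff": res.fold_change_at_cutoff,
        "n_enriched": len(res.enriched_ids),
        "counts_by_region": res.counts_by_region,
    }


@_stage("enrich")
def _run_enrich(config: PipelineConfig, manifest: dict) -> None:
    query = io.read_gene_list(config.enrich_query)
    universe = io.read_gene_list(config.enrich_universe)
    sets = io.read_gmt(config.enrich_sets)
    table = term_enrichment(sets, query, universe)
    table.to_csv(config.outdir / "term_enrichment.csv", index=False)
    manifest["enrich"] = {"n_terms": len(sets), "n_query": len(set(query))}


def run_screen_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; return the manifest.

    The size screen is mandatory; growth filtering, critical-size
    estimation, epistasis calls, ChIP thresholding and term enrichment
    run when their inputs are configured.  Outputs are plain CSV tables
    plus ``manifest.json`` in ``config.outdir``.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed}
    report = _run_screen(config, manifest)
    if config.growth_curves is not None:
        _run_growth(config, report, manifest)
    if config.timecourses is not None:
        _run_start(config, manifest)
    if config.epistasis_medians is not None:
        _run_epistasis(config, manifest)
    if config.chip_probes is not None:
        _run_chip(config, manifest)
    if config.enrich_query is not None:
        if config.enrich_sets is None or config.enrich_universe is None:
            raise PipelineError(
                "stage 'enrich' failed: needs 'query', 'sets' and 'universe'"
            )
        _run_enrich(config, manifest)
    with open(config.outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
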