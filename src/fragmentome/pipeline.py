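"""End-to-end orchestration: fragments in, genome-wide report out.

One call runs ingest -> copy number / tumor fraction -> fragmentomics ->
nucleosome profiling (and xenograft assignment when two genomes are given)
and emits a machine-readable JSON report plus per-module TSV outputs.
Rerunning with the same config and seed reproduces every numeric output.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import spawn_seeds
from . import cna as cna_mod
from .fragmentomics import end_motif_profile, proportion_in_range, size_histogram
from .ingest import (SIZE_STRATA, downsample_fragments, filter_fragments,
                     load_fragments, read_fragments_tsv)
from .nucleoprofile import SiteSet, estimate_gc_bias, site_coverage_profile
from .simulate import SimulationConfig, ensure_reference, simulate_sample

__all__ = ["RunConfig", "run_end_to_end", "run_lod_ladder"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Provide either a ``simulation`` config (reference included) or
    ``fragments_path`` + ``reference_path``.
    """

    simulation: SimulationConfig | None = None
    fragments_path: str | None = None
    reference_path: str | None = None
    host_fragments_path: str | None = None  # same reads vs a host genome
    layout: str = "single_end"
    min_mapq: int = 5
    bin_width: int = 10_000
    hmm: cna_mod.HMMConfig = field(default_factory=cna_mod.HMMConfig)
    strata: dict = field(default_factory=lambda: dict(SIZE_STRATA))
    tss_sites: SiteSet | str | None = None
    nrr_sites: SiteSet | str | None = None
    window: int = 1000
    central: int = 500
    l_max: int = 5000
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.simulation is None and self.fragments_path is None:
            raise ValueError("need a simulation config or a fragments path")
        for p in (self.fragments_path, self.reference_path,
                  self.host_fragments_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")


def _load_fragments_any(path, layout: str):
    if str(path).endswith((".tsv", ".txt")):
        return read_fragments_tsv(path)
    return load_fragments(path, layout)


def _site_set(spec, default_name) -> SiteSet | None:
    if spec is None:
        return None
    if isinstance(spec, SiteSet):
        return spec
    return SiteSet.from_bed(spec, name=default_name)


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full analysis and return the report dict.

    On a stage failure the report records the stage and error, downstream
    stages are skipped, and ``report["error"]`` is set (the CLI exits
    nonzero on it).
    """
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "version": __version__, "seed": config.seed,
                    "stages": {}, "manifest": {}, "timings_s": {}}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def _fail(stage: str, exc: Exception) -> dict:
        report["error"] = {"stage": stage, "message": str(exc)}
        report["stages"][stage] = "failed"
        _write_report(report, outdir)
        return report

    # ingest
    t0 = time.perf_counter()
    try:
        if config.simulation is not None:
            sample = simulate_sample(config.simulation)
            fragments = sample.fragments
            reference = config.simulation.reference
        else:
            fragments = _load_fragments_any(config.fragments_path,
                                            config.layout)
            reference = (ensure_reference(config.reference_path)
                         if config.reference_path else None)
        fragments = filter_fragments(fragments, min_mapq=config.min_mapq)
        if len(fragments) == 0:
            raise ValueError("no fragments survive filtering")
    except Exception as exc:  # noqa: BLE001 - report and stop
        return _fail("ingest", exc)
    report["stages"]["ingest"] = "ok"
    report["n_fragments"] = int(len(fragments))
    report["timings_s"]["ingest"] = round(time.perf_counter() - t0, 3)

    # copy number / tumor fraction
    t0 = time.perf_counter()
    try:
        if reference is None:
            raise ValueError("copy-number analysis needs a reference")
        profile = cna_mod.bin_fragments(fragments, config.bin_width, reference)
        corrected = cna_mod.correct_and_normalize(profile)
        estimate = cna_mod.fit_tumor_fraction(corrected, config.hmm)
        segments = cna_mod.viterbi_segments(corrected, estimate)
    except Exception as exc:  # noqa: BLE001
        return _fail("cna", exc)
    report["stages"]["cna"] = "ok"
    report["tumor_fraction"] = estimate.tumor_fraction
    report["detected"] = bool(estimate.detected)
    report["cna"] = estimate.to_dict()
    report["n_segments"] = int(len(segments))
    report["timings_s"]["cna"] = round(time.perf_counter() - t0, 3)
    if outdir:
        corrected.to_tsv(outdir / "bins.tsv")
        segments.to_csv(outdir / "segments.tsv", sep="\t", index=False)
        report["manifest"]["bins"] = "bins.tsv"
        report["manifest"]["segments"] = "segments.tsv"

    # fragmentomics
    t0 = time.perf_counter()
    try:
        hist = size_histogram(fragments, l_max=config.l_max)
        strata_props = {k: proportion_in_range(fragments, lo, hi)
                        for k, (lo, hi) in config.strata.items()}
        motifs = end_motif_profile(fragments, reference, config.strata)
        gini = {k: (m.gini if m.total else None) for k, m in motifs.items()}
    except Exception as exc:  # noqa: BLE001
        return _fail("fragmentomics", exc)
    report["stages"]["fragmentomics"] = "ok"
    report["size"] = {"median": hist.median, "mode": hist.mode,
                      "overflow": hist.overflow,
                      "strata_proportions": strata_props}
    report["end_motifs"] = {"gini": gini}
    report["timings_s"]["fragmentomics"] = round(time.perf_counter() - t0, 3)
    if outdir:
        hist.to_frame().to_csv(outdir / "size_histogram.tsv", sep="\t",
                               index=False)
        pd.concat([m.to_frame() for m in motifs.values()]).to_csv(
            outdir / "end_motifs.tsv", sep="\t", index=False)
        report["manifest"]["size_histogram"] = "size_histogram.tsv"
        report["manifest"]["end_motifs"] = "end_motifs.tsv"

    # nucleosome profiling
    t0 = time.perf_counter()
    try:
        central = {}
        tss = _site_set(config.tss_sites, "TSS")
        nrr = _site_set(config.nrr_sites, "NRR")
        if tss is not None or nrr is not None:
            curve = estimate_gc_bias(fragments, reference)
            for label, sites in (("TSS", tss), ("NRR", nrr)):
                if sites is None:
                    continue
                prof = site_coverage_profile(
                    fragments, sites, gc_curve=curve, reference=reference,
                    window=config.window, central=config.central)
                central[label] = prof.central_coverage
                if outdir:
                    prof.to_frame().to_csv(
                        outdir / f"profile_{label.lower()}.tsv",
                        sep="\t", index=False)
                    report["manifest"][f"profile_{label}"] = (
                        f"profile_{label.lower()}.tsv")
    except Exception as exc:  # noqa: BLE001
        return _fail("nucleoprofile", exc)
    report["stages"]["nucleoprofile"] = "ok" if central else "skipped"
    report["central_coverage"] = central
    report["timings_s"]["nucleoprofile"] = round(time.perf_counter() - t0, 3)

    # xenograft assignment when a second (host-genome) alignment set is given
    t0 = time.perf_counter()
    if (config.host_fragments_path is not None
            and config.fragments_path is not None):
        try:
            from .xenomap import assign_by_best_genome, origin_size_summary
            graft_aln = _load_fragments_any(config.fragments_path,
                                            config.layout)
            host_aln = _load_fragments_any(config.host_fragments_path,
                                           config.layout)
            result = assign_by_best_genome(graft_aln, host_aln,
                                           min_mapq=config.min_mapq,
                                           labels=("graft", "host"))
            sizes = origin_size_summary(result, graft_aln, host_aln,
                                        l_max=config.l_max)
        except Exception as exc:  # noqa: BLE001
            return _fail("xenomap", exc)
        report["stages"]["xenomap"] = "ok"
        report["xenograft"] = {
            "counts": result.counts, "ties": result.n_ties,
            "proportion_gt_300": {k: v["proportion_gt_300"]
                                  for k, v in sizes.items()}}
        if outdir:
            result.table.to_csv(outdir / "xenograft_assignments.tsv",
                                sep="\t", index=False)
            report["manifest"]["xenograft_assignments"] = (
                "xenograft_assignments.tsv")
        report["timings_s"]["xenomap"] = round(time.perf_counter() - t0, 3)
    else:
        report["stages"]["xenomap"] = "skipped"

    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path | None) -> None:
    if outdir:
        path = outdir / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                   default=_json_default) + "\n")
        report["manifest"]["report"] = "report.json"


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_lod_ladder(config: RunConfig, depths, replicates: int,
                   seed: int) -> pd.DataFrame:
    """Limit-of-detection ladder: detection rate vs sequencing depth.

    For each replicate a sample is simulated at the deepest depth and
    downsampled to each requested depth; the tumor fraction is re-estimated
    at every depth and a detection (TF > threshold) is recorded. Returns a
    table with one row per depth: n_detected, n_replicates, detection_rate.
    """
    if config.simulation is None:
        raise ValueError("LoD ladder needs a simulation config")
    depths = [int(d) for d in depths]
    if depths != sorted(depths, reverse=True):
        raise ValueError("depths must be given in descending order")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = config.simulation
    reference = base.reference
    seeds = spawn_seeds(seed, 2 * replicates)
    detected = {d: 0 for d in depths}
    skipped = []
    for r in range(replicates):
        sim = SimulationConfig(
            reference=reference, size_model=base.size_model,
            n_fragments=max(depths), tumor_fraction=base.tumor_fraction,
            cna=base.cna, end_motif_bias=base.end_motif_bias,
            tss_sites=base.tss_sites, tss_halfwidth=base.tss_halfwidth,
            tss_keep_prob=base.tss_keep_prob, mapq=base.mapq,
            seed=seeds[2 * r])
        fragments = filter_fragments(simulate_sample(sim).fragments,
                                     min_mapq=config.min_mapq)
        for j, d in enumerate(depths):
            if d > len(fragments):
                skipped.append(d)
                continue
            sub = downsample_fragments(fragments, count=d,
                                       seed=seeds[2 * r + 1] + j)
            profile = cna_mod.bin_fragments(sub, config.bin_width, reference)
            corrected = cna_mod.correct_and_normalize(profile)
            est = cna_mod.fit_tumor_fraction(corrected, config.hmm)
            if est.detected:
                detected[d] += 1
    rows = [(d, detected[d], replicates, detected[d] / replicates)
            for d in depths if d not in skipped]
    return pd.DataFrame(rows, columns=["depth", "n_detected", "n_replicates",
                                       "detection_rate"])
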