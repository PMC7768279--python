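"""End-to-end orchestration: simulate -> call -> IDR -> differential -> HC ->
integrate -> enrich -> report, as one reproducible run.

A run is fully determined by its :class:`RunConfig` and seed; every stage
writes plain files in standard formats into the run directory so any stage
can be rerun or inspected independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from prescout import __version__
from prescout.idr import IDRModel, IDRParams, match_replicate_peaks
from prescout.integrate import (
    annotate_candidates,
    build_hc_differential,
    candidates_to_table,
    rank_candidates,
    summarize_counts,
)
from prescout.intervals import IntervalSet, intersect, merge_within, write_bed
from prescout.peaks import (
    PeakCallConfig,
    call_peaks,
    classify_differential,
    score_peaks_log10_fold,
)
from prescout.simulate import (
    CoverageSimulation,
    SimulationDesign,
    gen_coverage,
    gen_evidence,
    gen_tss_table,
)

log = logging.getLogger("prescout")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; serializable, hashable."""

    design: SimulationDesign = field(default_factory=SimulationDesign)
    peak_config: PeakCallConfig = field(default_factory=PeakCallConfig)
    idr_init: IDRParams = field(default_factory=IDRParams)
    merge_gap: int = 500
    seed: int = 0
    outdir: str = "prescout_run"

    def to_dict(self):
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def overlap_stats(called: IntervalSet, truth: IntervalSet) -> dict:
    """Base-level sensitivity and precision of a called set against truth."""
    called_m = merge_within(called, 0)
    truth_m = merge_within(truth, 0)
    inter = intersect(called_m, truth_m).total_bases()
    called_b = called_m.total_bases()
    truth_b = truth_m.total_bases()
    return {
        "called_bases": called_b,
        "truth_bases": truth_b,
        "overlap_bases": inter,
        "sensitivity": inter / truth_b if truth_b else 0.0,
        "precision": inter / called_b if called_b else 0.0,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full synthetic-design pipeline; returns the run directory.

    Stages: coverage simulation with planted truth; per-replicate peak
    calling against matched input and differential classification between
    conditions; replicate-consistency diagnostics (IDR on matched peak-score
    pairs); high-confidence set construction (merge within ``merge_gap``,
    intersect across replicates); evidence annotation and candidate ranking;
    bookkeeping against the planted truth.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(name)s: %(message)s")
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    log.info("prescout %s | seed=%d | config=%s", __version__, config.seed, config.config_hash())

    try:
        sim = gen_coverage(config.design, seed=config.seed)
        sim.truth_bed(outdir / "truth.bed")
        cfg = config.peak_config

        # per-replicate peak calls vs matched input, and IDR diagnostics per condition
        rep_peaks = {}
        for (cond, rep), track in sim.tracks.items():
            peaks = call_peaks(track, sim.inputs[rep], cfg, broad=True)
            rep_peaks[(cond, rep)] = peaks
            write_bed(peaks, outdir / f"peaks_cond{cond}_rep{rep}.bed")
        log.info("peak calling done: %s", {k: len(v) for k, v in rep_peaks.items()})

        idr_summaries = {}
        for cond in (1, 2):
            # replicate consistency wants continuous log10 fold-change
            # scores, not the tied/saturating q-value scores
            scored = [
                score_peaks_log10_fold(
                    sim.tracks[(cond, rep)], sim.inputs[rep], rep_peaks[(cond, rep)]
                )
                for rep in (1, 2)
            ]
            pairs = match_replicate_peaks(scored[0], scored[1])
            if len(pairs) >= IDRModel.MIN_PAIRS:
                fit = IDRModel(pairs).fit(init=config.idr_init)
                idr_summaries[f"cond{cond}"] = {
                    "n_pairs": fit.n_pairs,
                    "pi_reproducible": fit.params.pi,
                    "rho": fit.params.rho,
                    "converged": fit.converged,
                    "n_idr_le_0.05": int((fit.global_idr <= 0.05).sum()),
                }
                fit.to_table().to_csv(outdir / f"idr_cond{cond}.tsv", sep="\t", index=False)
            else:
                idr_summaries[f"cond{cond}"] = {"n_pairs": len(pairs), "skipped": True}
        log.info("IDR diagnostics: %s", idr_summaries)

        # differential classification per replicate, then HC construction
        diffs = {}
        for rep in (1, 2):
            diffs[rep] = classify_differential(
                sim.tracks[(1, rep)], sim.tracks[(2, rep)], cfg, control=sim.inputs[rep]
            )
        hc = build_hc_differential(diffs[1], diffs[2], merge_gap=config.merge_gap)
        for name, s in hc.classes().items():
            write_bed(s, outdir / f"hc_{name}.bed")
        log.info(
            "HC classes: %s",
            {k: (len(v), v.total_bases()) for k, v in hc.classes().items()},
        )

        # evidence annotation on the condition-1-enriched HC set
        tf_sets, conserved, accessibility = gen_evidence(sim, seed=config.seed + 1)
        tss = gen_tss_table(sim, seed=config.seed + 2)
        candidates = annotate_candidates(
            hc.enriched_in_1, tf_sets, conserved, accessibility, tss
        )
        ranked = rank_candidates(candidates)
        table = candidates_to_table(ranked)
        table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)

        summary = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "idr": idr_summaries,
            "counts": summarize_counts(hc, ranked),
            "recovery": {
                name: overlap_stats(hc.classes()[name], sim.truth[name])
                for name in ("cond1_enriched", "cond2_enriched")
            },
            "elapsed_s": round(time.time() - t0, 2),
        }
        with open(outdir / "summary.json", "w") as f:
            json.dump(summary, f, indent=2)
        log.info("run complete in %.1f s", time.time() - t0)
        return outdir
    except Exception:
        log.exception("pipeline stage failed; partial outputs kept in %s", outdir)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def report(run_dir) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    with open(run_dir / "summary.json") as f:
        s = json.load(f)
    c = s["counts"]
    lines = [
        f"prescout run {run_dir} (seed {s['seed']}, config {s['config_hash']})",
        "-" * 64,
        f"HC cond1-enriched peaks: {c['n_hc_cond1_enriched']:5d}  "
        f"({c['bases_hc_cond1_enriched']} bases)",
        f"HC cond2-enriched peaks: {c['n_hc_cond2_enriched']:5d}  "
        f"({c['bases_hc_cond2_enriched']} bases)",
        f"HC common peaks:         {c['n_hc_common']:5d}  ({c['bases_hc_common']} bases)",
        "-" * 64,
        f"candidates annotated:    {c['n_candidates']}",
        f"  TF union overlap:      {c['n_tf_union']} ({c['pct_tf_union']:.1f}%)",
        f"  TF intersect overlap:  {c['n_tf_intersect']} ({c['pct_tf_intersect']:.1f}%)",
        f"  conserved overlap:     {c['n_conserved']} ({c['pct_conserved']:.1f}%)",
    ]
    for name, r in s.get("recovery", {}).items():
        lines.append(
            f"recovery {name}: sensitivity {r['sensitivity']:.3f}, "
            f"precision {r['precision']:.3f}"
        )
    for cond, d in s.get("idr", {}).items():
        if not d.get("skipped"):
            lines.append(
                f"IDR {cond}: {d['n_pairs']} pairs, pi={d['pi_reproducible']:.3f}, "
                f"rho={d['rho']:.3f}, {d['n_idr_le_0.05']} at IDR<=0.05"
            )
    lines.append(f"elapsed: {s['elapsed_s']} s")
    return "\n".join(lines)
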