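"""High-confidence differential peak sets and multi-evidence pRE candidates.

The core inference of the workflow: per replicate, differential peak classes
are merged within 500 bp (histone domains are ragged; merging stabilises
peak definitions), then the high-confidence (HC) set of a class is the
base-level intersection across the two replicates — merge first, intersect
second.  HC condition-enriched peaks are then annotated with evidence
overlap (TF-binding peak sets, conserved elements, per-cell-type
accessibility), assigned a nearest gene by TSS distance, and ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from prescout.intervals import (
    GenomicInterval,
    IntervalSet,
    intersect,
    merge_within,
    overlaps_any,
    subtract,
    union,
)
from prescout.peaks import DifferentialResult


@dataclass
class CandidateRE:
    """A candidate putative regulatory element with its evidence flags."""

    interval: GenomicInterval
    diff_class: str  # cond1_enriched | cond2_enriched | common
    tf_hits: dict[str, bool] = field(default_factory=dict)
    conserved: bool = False
    accessibility: dict[str, bool] = field(default_factory=dict)
    nearest_gene: str | None = None
    nearest_gene_distance: int | None = None

    @property
    def tf_union(self) -> bool:
        return any(self.tf_hits.values())

    @property
    def tf_intersect(self) -> bool:
        return bool(self.tf_hits) and all(self.tf_hits.values())

    @property
    def rank_key(self):
        """Lexicographic descending sort key: TF intersection, TF hit count,
        conservation, selective-accessibility count, peak score; ties broken
        by coordinate (ascending)."""
        return (
            -int(self.tf_intersect),
            -sum(self.tf_hits.values()),
            -int(self.conserved),
            -sum(self.accessibility.values()),
            -(self.interval.score or 0.0),
            self.interval.chrom,
            self.interval.start,
            self.interval.end,
        )


def hc_peaks(rep1: IntervalSet, rep2: IntervalSet, merge_gap: int = 500) -> IntervalSet:
    """High-confidence peaks for one class: merge within ``merge_gap`` in each
    replicate, then base-level intersect.  Commutative; the order (merge
    first, intersect second) matters and is fixed."""
    return intersect(merge_within(rep1, merge_gap), merge_within(rep2, merge_gap))


def build_hc_differential(
    diff_rep1: DifferentialResult,
    diff_rep2: DifferentialResult,
    merge_gap: int = 500,
) -> DifferentialResult:
    """HC differential classes across two replicates.

    Applies :func:`hc_peaks` per class, then trims any cross-class overlap
    merging re-created; enriched classes take priority over common.
    """
    enr1 = hc_peaks(diff_rep1.enriched_in_1, diff_rep2.enriched_in_1, merge_gap)
    enr2 = hc_peaks(diff_rep1.enriched_in_2, diff_rep2.enriched_in_2, merge_gap)
    common = hc_peaks(diff_rep1.common, diff_rep2.common, merge_gap)
    # enforce mutual disjointness; enriched classes win over common
    enr2 = subtract(enr2, enr1)
    common = subtract(common, union([enr1, enr2]))
    return DifferentialResult(enr1, enr2, common)


def annotate_candidates(
    hc_enriched: IntervalSet,
    tf_sets: dict[str, IntervalSet] | None = None,
    conserved: IntervalSet | None = None,
    accessibility: dict[str, IntervalSet] | None = None,
    tss_table=None,
    diff_class: str = "cond1_enriched",
) -> list[CandidateRE]:
    """Annotate each HC enriched peak with evidence-overlap flags.

    ``tss_table`` is a sequence of (gene, chrom, tss) records (or a
    DataFrame with those columns); the nearest gene is by distance from the
    peak midpoint to the TSS, ties broken alphabetically.
    """
    tf_sets = tf_sets or {}
    accessibility = accessibility or {}
    cands = [CandidateRE(iv, diff_class) for iv in hc_enriched]

    for tf, peaks in tf_sets.items():
        for cand, flag in zip(cands, overlaps_any(hc_enriched, peaks)):
            cand.tf_hits[tf] = flag
    if conserved is not None:
        for cand, flag in zip(cands, overlaps_any(hc_enriched, conserved)):
            cand.conserved = flag
    for cell_type, peaks in accessibility.items():
        for cand, flag in zip(cands, overlaps_any(hc_enriched, peaks)):
            cand.accessibility[cell_type] = flag
    if tss_table is not None:
        tss = _as_tss_records(tss_table)
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for gene, chrom, pos in tss:
            by_chrom.setdefault(chrom, []).append((pos, gene))
        for cand in cands:
            mid = (cand.interval.start + cand.interval.end) // 2
            best = None
            for pos, gene in by_chrom.get(cand.interval.chrom, []):
                key = (abs(pos - mid), gene)
                if best is None or key < best:
                    best = key
            if best is not None:
                cand.nearest_gene_distance, cand.nearest_gene = best
    return cands


def _as_tss_records(tss_table):
    if hasattr(tss_table, "itertuples"):  # DataFrame
        return [(r.gene, r.chrom, int(r.tss)) for r in tss_table.itertuples()]
    return [(g, c, int(p)) for g, c, p in tss_table]


def rank_candidates(candidates: list[CandidateRE]) -> list[CandidateRE]:
    """Deterministic ordering by evidence strength (see CandidateRE.rank_key)."""
    return sorted(candidates, key=lambda c: c.rank_key)


def summarize_counts(hc: DifferentialResult, candidates: list[CandidateRE]) -> dict:
    """Bookkeeping report: counts per class, evidence-overlap percentages."""
    n = len(candidates)
    tf_union = sum(c.tf_union for c in candidates)
    tf_intersect = sum(c.tf_intersect for c in candidates)
    cons = sum(c.conserved for c in candidates)
    per_tf = {}
    if candidates:
        for tf in candidates[0].tf_hits:
            per_tf[tf] = sum(c.tf_hits.get(tf, False) for c in candidates)
    return {
        "n_hc_cond1_enriched": len(hc.enriched_in_1),
        "n_hc_cond2_enriched": len(hc.enriched_in_2),
        "n_hc_common": len(hc.common),
        "bases_hc_cond1_enriched": hc.enriched_in_1.total_bases(),
        "bases_hc_cond2_enriched": hc.enriched_in_2.total_bases(),
        "bases_hc_common": hc.common.total_bases(),
        "n_candidates": n,
        "n_tf_union": tf_union,
        "n_tf_intersect": tf_intersect,
        "n_conserved": cons,
        "per_tf_counts": per_tf,
        "pct_tf_union": 100.0 * tf_union / n if n else 0.0,
        "pct_tf_intersect": 100.0 * tf_intersect / n if n else 0.0,
        "pct_conserved": 100.0 * cons / n if n else 0.0,
    }


def candidates_to_table(candidates: list[CandidateRE]):
    """Candidates as a pandas DataFrame (BED6+ layout with flag columns)."""
    import pandas as pd

    rows = []
    for c in candidates:
        row = {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "name": c.interval.name or ".",
            "score": c.interval.score if c.interval.score is not None else 0.0,
            "diff_class": c.diff_class,
            "tf_union": c.tf_union,
            "tf_intersect": c.tf_intersect,
            "conserved": c.conserved,
            "nearest_gene": c.nearest_gene or ".",
            "nearest_gene_distance": (
                c.nearest_gene_distance if c.nearest_gene_distance is not None else -1
            ),
        }
        for tf, hit in c.tf_hits.items():
            row[f"tf_{tf}"] = hit
        for ct, hit in c.accessibility.items():
            row[f"atac_{ct}"] = hit
        rows.append(row)
    return pd.DataFrame(rows)
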