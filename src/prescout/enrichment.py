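"""Known-motif enrichment, genomic-context annotation, and region-gene
(GREAT-style) term enrichment.

Motif fold enrichment follows the published arithmetic exactly:
fold = (% of target sequences with a hit) / (% of background sequences with
a hit), with an upper-tail binomial p-value at the background hit rate.
Region-gene association uses the basal+extension rule: every gene gets a
basal regulatory domain (5 kb upstream / 1 kb downstream of its TSS,
strand-aware) extended toward the neighbouring genes' basal domains up to
1 Mb; a region associates with every gene whose domain it overlaps.  Term
significance requires binomial (region-based) FDR < 0.05, hypergeometric
(gene-based) FDR < 0.05, and region fold enrichment > 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from prescout.intervals import GenomicInterval, IntervalSet, merge_within
from prescout.stats import bh_fdr

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Motif:
    """A known TF-binding motif: IUPAC consensus or position weight matrix.

    For PWM mode, ``pwm`` is an (L, 4) matrix of per-position base
    probabilities (columns A, C, G, T; each row sums to 1); a window is a
    hit iff its log-odds score (vs uniform background) reaches
    ``match_threshold`` times the maximum achievable score.
    """

    id: str
    consensus: str | None = None
    pwm: np.ndarray | None = None
    match_threshold: float = 0.8

    def __post_init__(self):
        if (self.consensus is None) == (self.pwm is None):
            raise ValueError("provide exactly one of consensus or pwm")
        if self.consensus is not None:
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC letters in consensus: {bad}")
            self.consensus = self.consensus.upper()
        else:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
                raise ValueError("pwm must be an (L, 4) matrix")
            if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("pwm rows must sum to 1")

    def __len__(self):
        return len(self.consensus) if self.consensus is not None else self.pwm.shape[0]


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _consensus_matches(window: str, consensus: str) -> bool:
    # N in the *sequence* never matches, even against N in the consensus
    for s, c in zip(window, consensus):
        if s == "N" or s not in IUPAC[c]:
            return False
    return True


def _pwm_logodds(motif: Motif):
    # floor probabilities so a zero cell scores very negative, not -inf
    p = np.maximum(motif.pwm, 1e-4)
    return np.log2(p / 0.25)


def scan_motif(seqs, motif: Motif):
    """Scan sequences (both strands) for motif occurrences.

    Parameters
    ----------
    seqs : iterable of (name, sequence) pairs, or plain sequences
    motif : Motif

    Returns
    -------
    DataFrame with columns name, hit (bool), count (occurrences over both
    strands; a palindromic site counts once per strand placement).
    """
    records = [(s if isinstance(s, tuple) else (f"seq{i}", s)) for i, s in enumerate(seqs)]
    L = len(motif)
    lo = _pwm_logodds(motif) if motif.pwm is not None else None
    max_score = lo.max(axis=1).sum() if lo is not None else None
    rows = []
    for name, seq in records:
        seq = seq.upper()
        count = 0
        for strand_seq in (seq, reverse_complement(seq)):
            for i in range(len(strand_seq) - L + 1):
                window = strand_seq[i : i + L]
                if motif.consensus is not None:
                    if _consensus_matches(window, motif.consensus):
                        count += 1
                else:
                    if "N" in window:
                        continue
                    idx = [_BASE_IDX[b] for b in window]
                    score = lo[np.arange(L), idx].sum()
                    if score >= motif.match_threshold * max_score:
                        count += 1
        rows.append({"name": name, "hit": count > 0, "count": count})
    return pd.DataFrame(rows)


def motif_fold_enrichment(targets, background, motif: Motif):
    """Fold = (% targets with a hit) / (% background with a hit).

    p is the upper-tail binomial P(X >= k_t; n_t, background hit rate).
    With zero background hits the fold is infinite and the p-value uses a
    floored background rate of 0.5 / n_background.

    Returns a dict with fold, p, counts and rates.
    """
    t = scan_motif(targets, motif)
    b = scan_motif(background, motif)
    n_t, n_b = len(t), len(b)
    if n_t == 0 or n_b == 0:
        raise ValueError("both target and background sets must be non-empty")
    k_t, k_b = int(t["hit"].sum()), int(b["hit"].sum())
    rate_t, rate_b = k_t / n_t, k_b / n_b
    if k_b > 0:
        fold = rate_t / rate_b
        rate_for_p = rate_b
    else:
        fold = float("inf") if k_t > 0 else float("nan")
        rate_for_p = 0.5 / n_b
    p = float(stats.binom.sf(k_t - 1, n_t, rate_for_p)) if k_t > 0 else 1.0
    return {
        "motif": motif.id,
        "fold": fold,
        "p": p,
        "target_hits": k_t,
        "n_targets": n_t,
        "background_hits": k_b,
        "n_background": n_b,
        "target_pct": 100.0 * rate_t,
        "background_pct": 100.0 * rate_b,
    }


# ---------------------------------------------------------------------------
# Gene models, genomic context, GREAT-style association
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene anchored at its TSS, with optional structure for context calls.

    ``exons`` (list of (start, end)) lets the midpoint annotator call
    exon/intron/TTS; ``utr5`` spans let it call 5'UTR.  Without structure a
    gene contributes only its promoter window.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def span(self) -> tuple[int, int] | None:
        if not self.exons:
            return None
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def tes(self) -> int | None:
        """Transcription end site (the far end of the gene span)."""
        sp = self.span
        if sp is None:
            return None
        return sp[1] if self.strand == "+" else sp[0]


CONTEXT_CATEGORIES = ["promoter-TSS", "5UTR", "exon", "intron", "TTS", "intergenic"]


def annotate_genomic_context(
    peaks: IntervalSet,
    gene_models: list[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 100,
    tts_flank: tuple[int, int] = (100, 1000),
):
    """Category of each peak midpoint with fixed precedence
    promoter-TSS > 5UTR > exon > intron > TTS > intergenic.

    The promoter window is -promoter_up..+promoter_down around the TSS
    (strand-aware); the TTS window is -tts_flank[0]..+tts_flank[1] around
    the transcription end site.

    Returns (list of categories, dict of category proportions).
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    def category(chrom: str, pos: int) -> str:
        best = len(CONTEXT_CATEGORIES) - 1
        for g in genes_by_chrom.get(chrom, []):
            sgn = 1 if g.strand == "+" else -1
            rel = sgn * (pos - g.tss)
            if -promoter_up <= rel <= promoter_down:
                return "promoter-TSS"
            cat = None
            if any(s <= pos < e for s, e in g.utr5):
                cat = "5UTR"
            elif any(s <= pos < e for s, e in g.exons):
                cat = "exon"
            else:
                tes = g.tes
                if tes is not None:
                    rel_tes = sgn * (pos - tes)
                    span = g.span
                    if -tts_flank[0] <= rel_tes <= tts_flank[1]:
                        cat = "TTS"
                    elif span[0] <= pos < span[1]:
                        cat = "intron"
            if cat is not None:
                best = min(best, CONTEXT_CATEGORIES.index(cat))
        return CONTEXT_CATEGORIES[best]

    cats = [category(iv.chrom, (iv.start + iv.end) // 2) for iv in peaks]
    n = len(cats)
    props = {c: cats.count(c) / n if n else 0.0 for c in CONTEXT_CATEGORIES}
    return cats, props


@dataclass
class RegionGeneAssociations:
    """Region-gene associations plus the regulatory domains that produced them."""

    region_genes: list[list[str]]  # parallel to regions
    regions: IntervalSet
    domains: dict[str, IntervalSet]  # gene -> regulatory domain (single interval)
    genes: list[str]

    def genes_hit(self) -> set[str]:
        return {g for gl in self.region_genes for g in gl}

    def regions_per_gene(self) -> dict[str, int]:
        out: dict[str, int] = {g: 0 for g in self.genes}
        for gl in self.region_genes:
            for g in gl:
                out[g] += 1
        return out


def associate_regions_to_genes(
    regions: IntervalSet,
    gene_models: list[GeneModel],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
    genome: dict[str, int] | None = None,
) -> RegionGeneAssociations:
    """Basal+extension association rule.

    Basal domain: TSS - basal_up .. TSS + basal_down (strand-aware).
    Each side extends to the nearest neighbouring basal domain boundary, at
    most ``max_extension`` from the TSS, never cutting into the gene's own
    basal domain, clipped to the chromosome if its length is known.
    A region associates with every gene whose domain it overlaps.
    """
    genome = genome or (regions.genome or {})
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)

    domains: dict[str, IntervalSet] = {}
    for chrom, genes in by_chrom.items():
        genes = sorted(genes, key=lambda g: (g.tss, g.gene_id))
        basal = []
        for g in genes:
            if g.strand == "+":
                b = (g.tss - basal_up, g.tss + basal_down)
            else:
                b = (g.tss - basal_down, g.tss + basal_up)
            basal.append((max(0, b[0]), b[1]))
        chrom_len = genome.get(chrom)
        for i, g in enumerate(genes):
            bs, be = basal[i]
            prev_ends = [basal[j][1] for j in range(len(genes)) if genes[j].tss < g.tss]
            next_starts = [basal[j][0] for j in range(len(genes)) if genes[j].tss > g.tss]
            left_limit = max(prev_ends) if prev_ends else 0
            right_limit = min(next_starts) if next_starts else (chrom_len if chrom_len else g.tss + max_extension)
            start = min(bs, max(left_limit, g.tss - max_extension))
            end = max(be, min(right_limit, g.tss + max_extension))
            start = max(0, start)
            if chrom_len is not None:
                end = min(end, chrom_len)
                start = min(start, chrom_len - 1)
            domains[g.gene_id] = IntervalSet([GenomicInterval(chrom, start, max(end, start + 1))])

    region_genes = []
    for iv in regions:
        hits = [
            gid
            for gid, dom in domains.items()
            if dom[0].chrom == iv.chrom and iv.start < dom[0].end and dom[0].start < iv.end
        ]
        region_genes.append(sorted(hits))
    return RegionGeneAssociations(
        region_genes=region_genes,
        regions=regions,
        domains=domains,
        genes=[g.gene_id for g in gene_models],
    )


def term_enrichment(
    associations: RegionGeneAssociations,
    term_map: dict[str, set[str]],
    genome_length: int,
) -> pd.DataFrame:
    """GREAT-style term enrichment table.

    Per term: binomial test over regions (success probability = fraction of
    the genome covered by the union of the term genes' regulatory domains);
    hypergeometric test over genes; fold = observed / expected region hits.
    Significant iff binomial FDR < 0.05, hypergeometric FDR < 0.05 and
    fold > 2 (BH across terms).
    """
    n_regions = len(associations.regions)
    all_genes = set(associations.genes)
    genes_hit = associations.genes_hit() & all_genes
    rows = []
    for term, genes in sorted(term_map.items()):
        genes = set(genes) & all_genes
        dom_union = merge_within(
            IntervalSet([associations.domains[g][0] for g in genes]) if genes else IntervalSet([]),
            0,
        )
        covered = dom_union.total_bases()
        p_success = covered / genome_length if genome_length else 0.0
        k = sum(1 for gl in associations.region_genes if genes.intersection(gl))
        expected = n_regions * p_success
        fold = (k / expected) if expected > 0 else (float("inf") if k else 0.0)
        if k > 0 and 0 < p_success < 1:
            p_binom = float(stats.binom.sf(k - 1, n_regions, p_success))
        elif p_success >= 1:
            p_binom = 1.0
        else:
            p_binom = 1.0 if k == 0 else 0.0
        k_genes = len(genes & genes_hit)
        p_hyper = float(
            stats.hypergeom.sf(k_genes - 1, len(all_genes), len(genes), len(genes_hit))
        ) if genes else 1.0
        rows.append(
            {
                "term": term,
                "n_term_genes": len(genes),
                "region_hits": k,
                "expected_hits": expected,
                "fold": fold,
                "p_binomial": p_binom,
                "gene_hits": k_genes,
                "p_hypergeom": p_hyper,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_binomial"] = bh_fdr(df["p_binomial"].to_numpy())
        df["fdr_hypergeom"] = bh_fdr(df["p_hypergeom"].to_numpy())
        df["significant"] = (
            (df["fdr_binomial"] < 0.05)
            & (df["fdr_hypergeom"] < 0.05)
            & (df["fold"] > 2)
        )
    return df


# ---------------------------------------------------------------------------
# Plain-text I/O: FASTA, motif files, TSS tables, term maps
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    records, name, chunks = [], None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        records.append((name, "".join(chunks)))
    return records


def write_fasta(records, path, width=60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_motifs(path) -> list[Motif]:
    """Read motifs: either ``id<TAB>consensus`` lines, or matrix blocks
    headed by ``>id`` followed by one ``A C G T`` probability row per
    position."""
    motifs, block_id, block_rows = [], None, []

    def flush():
        if block_id is not None:
            motifs.append(Motif(block_id, pwm=np.array(block_rows)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                block_id, block_rows = line[1:].split()[0], []
            elif block_id is not None:
                block_rows.append([float(x) for x in line.split()])
            else:
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) == 1:
                    motifs.append(Motif(f"motif{len(motifs) + 1}", consensus=parts[0]))
                else:
                    motifs.append(Motif(parts[0], consensus=parts[1]))
    flush()
    return motifs


def read_tss_table(path) -> list[GeneModel]:
    """Read a BED-like TSS table: chrom, tss, gene, strand (tab-separated)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected chrom, tss, gene, strand")
            genes.append(GeneModel(f[2], f[0], int(f[1]), f[3]))
    return genes


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV: term<TAB>gene."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            term, gene = line.split("\t")[:2]
            terms.setdefault(term, set()).add(gene)
    return terms
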