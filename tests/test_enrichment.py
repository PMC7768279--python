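"""Motif scanning/enrichment, genomic context, and region-gene term tests."""

import math
from fractions import Fraction

import numpy as np
import pytest

from prescout.enrichment import (
    GeneModel,
    IUPAC,
    Motif,
    RegionGeneAssociations,
    annotate_genomic_context,
    associate_regions_to_genes,
    motif_fold_enrichment,
    read_fasta,
    read_motifs,
    read_term_map,
    read_tss_table,
    reverse_complement,
    scan_motif,
    term_enrichment,
    write_fasta,
)
from prescout.intervals import GenomicInterval, IntervalSet
from prescout.simulate import gen_motif_sequences


def naive_scan(seq, consensus):
    """Independent sliding-window oracle for consensus matching."""
    seq = seq.upper()
    hits = 0
    for strand_seq in (seq, reverse_complement(seq)):
        for i in range(len(strand_seq) - len(consensus) + 1):
            window = strand_seq[i : i + len(consensus)]
            if all(s != "N" and s in IUPAC[c] for s, c in zip(window, consensus)):
                hits += 1
    return hits


class TestScanMotif:
    def test_simple_hit(self):
        df = scan_motif([("s", "GGTAATGG")], Motif("m", consensus="TAAT"))
        assert bool(df["hit"][0])

    def test_all_n_sequence_never_hits(self):
        df = scan_motif([("s", "N" * 50)], Motif("m", consensus="NNNN"))
        assert not bool(df["hit"][0])

    def test_reverse_complement_invariance(self, rng):
        motif = Motif("m", consensus="TGACGTCA"[:6])
        seqs = ["".join(rng.choice(list("ACGT"), 80)) for _ in range(20)]
        fwd = scan_motif(seqs, motif)
        rev = scan_motif([reverse_complement(s) for s in seqs], motif)
        assert list(fwd["hit"]) == list(rev["hit"])
        assert list(fwd["count"]) == list(rev["count"])

    def test_counts_match_sliding_window_oracle(self, rng):
        motif = Motif("m", consensus="TAWT")
        seqs = ["".join(rng.choice(list("ACGTN"), 60)) for _ in range(30)]
        df = scan_motif(seqs, motif)
        assert list(df["count"]) == [naive_scan(s, "TAWT") for s in seqs]

    def test_pwm_mode_perfect_site(self):
        pwm = np.zeros((4, 4))
        for i, base in enumerate("TAAT"):
            pwm[i, "ACGT".index(base)] = 1.0
        motif = Motif("m", pwm=pwm, match_threshold=0.99)
        assert bool(scan_motif([("s", "GGTAATGG")], motif)["hit"][0])
        assert not bool(scan_motif([("s", "GGTGCTGG")], motif)["hit"][0])

    def test_invalid_motif_definitions_rejected(self):
        with pytest.raises(ValueError):
            Motif("m", consensus="TAXT")
        with pytest.raises(ValueError):
            Motif("m", pwm=np.ones((4, 4)))
        with pytest.raises(ValueError):
            Motif("m")


class TestFoldEnrichment:
    def test_identical_sets_fold_one(self, rng):
        seqs = [("a", "GGTAATGG"), ("b", "CCCCCCCC")]
        res = motif_fold_enrichment(seqs, seqs, Motif("m", consensus="TAAT"))
        assert res["fold"] == pytest.approx(1.0)

    def test_forced_ratio_ten(self):
        targets = [("t%d" % i, "GGTAATGG" if i < 5 else "GGGGGGGG") for i in range(10)]
        background = [("b%d" % i, "GGTAATGG" if i < 1 else "GGGGGGGG") for i in range(20)]
        res = motif_fold_enrichment(targets, background, Motif("m", consensus="TAAT"))
        assert res["fold"] == pytest.approx((5 / 10) / (1 / 20))

    def test_zero_background_hits_reports_infinite_fold(self):
        targets = [("t", "GGTAATGG")]
        background = [("b%d" % i, "GGGGGGGG") for i in range(10)]
        res = motif_fold_enrichment(targets, background, Motif("m", consensus="TAAT"))
        assert math.isinf(res["fold"])
        assert 0 < res["p"] <= 1

    def test_planted_simulation_p_matches_exact_binomial(self):
        targets, background, _ = gen_motif_sequences(
            n_target=200, n_background=200, target_rate=0.4, background_rate=0.05,
            seed=5,
        )
        motif = Motif("m", consensus="TAATTA")
        res = motif_fold_enrichment(targets, background, motif)
        # exact rational binomial upper tail: P(X >= k; n, p)
        k, n = res["target_hits"], res["n_targets"]
        p = Fraction(res["background_hits"], res["n_background"])
        tail = sum(
            math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
        )
        assert res["p"] == pytest.approx(float(tail), rel=1e-10)
        assert res["fold"] == pytest.approx(
            (res["target_hits"] / res["n_targets"])
            / (res["background_hits"] / res["n_background"])
        )


class TestGenomicContext:
    def _genes(self):
        return [
            GeneModel(
                "plus", "chr1", 10_000, "+",
                exons=[(10_000, 10_500), (12_000, 12_400)],
                utr5=[(10_000, 10_100)],
            ),
            GeneModel("minus", "chr1", 30_000, "-", exons=[(28_000, 30_000)]),
        ]

    def _cat(self, chrom, pos):
        peaks = IntervalSet([GenomicInterval(chrom, pos - 5, pos + 5)])
        cats, _ = annotate_genomic_context(peaks, self._genes())
        return cats[0]

    def test_peak_at_tss_is_promoter(self):
        assert self._cat("chr1", 10_000) == "promoter-TSS"
        # strand-aware window: for the minus-strand gene "upstream" is right
        assert self._cat("chr1", 30_500) == "promoter-TSS"

    def test_categories_by_position(self):
        assert self._cat("chr1", 10_300) == "exon"
        assert self._cat("chr1", 11_000) == "intron"
        # inside the last exon the exon call outranks the TTS window
        assert self._cat("chr1", 12_395) == "exon"
        assert self._cat("chr1", 12_500) == "TTS"
        assert self._cat("chr1", 50_000) == "intergenic"

    def test_empty_chromosome_is_intergenic(self):
        assert self._cat("chr9", 1_000) == "intergenic"

    def test_proportions_sum_to_one(self, rng):
        peaks = IntervalSet(
            [
                GenomicInterval("chr1", int(p), int(p) + 10)
                for p in rng.integers(0, 60_000, size=50)
            ]
        )
        cats, props = annotate_genomic_context(peaks, self._genes())
        assert sum(props.values()) == pytest.approx(1.0)
        assert len(cats) == 50


class TestRegionGeneAssociation:
    def _three_gene_chrom(self):
        # hand-computed basal+extension domains on a 1 Mb chromosome:
        #   geneA + TSS 100k: basal [95k, 101k)
        #   geneB - TSS 500k: basal [499k, 505k)
        #   geneC + TSS 900k: basal [895k, 901k)
        return [
            GeneModel("geneA", "chr1", 100_000, "+"),
            GeneModel("geneB", "chr1", 500_000, "-"),
            GeneModel("geneC", "chr1", 900_000, "+"),
        ]

    def test_region_inside_basal_domain(self):
        regions = IntervalSet([GenomicInterval("chr1", 96_000, 96_500)])
        assoc = associate_regions_to_genes(
            regions, self._three_gene_chrom(), genome={"chr1": 1_000_000}
        )
        assert assoc.region_genes == [["geneA"]]

    def test_extension_reaches_neighbour_basal_boundary(self):
        genes = self._three_gene_chrom()
        genome = {"chr1": 1_000_000}
        # extensions from both sides meet at the neighbours' basal
        # boundaries, so the inter-gene gap belongs to both flanking genes
        regions = IntervalSet([GenomicInterval("chr1", 400_000, 400_100)])
        assoc = associate_regions_to_genes(regions, genes, genome=genome)
        assert assoc.region_genes == [["geneA", "geneB"]]
        regions2 = IntervalSet([GenomicInterval("chr1", 600_000, 600_100)])
        assoc2 = associate_regions_to_genes(regions2, genes, genome=genome)
        assert assoc2.region_genes == [["geneB", "geneC"]]
        # but a region inside a basal domain maps only to its own gene
        regions3 = IntervalSet([GenomicInterval("chr1", 99_000, 99_100)])
        assoc3 = associate_regions_to_genes(regions3, genes, genome=genome)
        assert assoc3.region_genes == [["geneA"]]

    def test_region_beyond_max_extension_unassociated(self):
        genes = [GeneModel("solo", "chr1", 100_000, "+")]
        regions = IntervalSet([GenomicInterval("chr1", 1_200_000, 1_200_100)])
        assoc = associate_regions_to_genes(
            regions, genes, genome={"chr1": 5_000_000}
        )
        assert assoc.region_genes == [[]]

    def test_hand_computed_domains(self):
        genes = self._three_gene_chrom()
        assoc = associate_regions_to_genes(
            IntervalSet([]), genes, genome={"chr1": 1_000_000}
        )
        dom = {g: (d[0].start, d[0].end) for g, d in assoc.domains.items()}
        assert dom["geneA"] == (0, 499_000)  # left: chrom start; right: B basal
        assert dom["geneB"] == (101_000, 895_000)
        assert dom["geneC"] == (505_000, 1_000_000)

    def test_monotone_in_max_extension(self):
        genes = self._three_gene_chrom()
        regions = IntervalSet(
            [GenomicInterval("chr1", int(p), int(p) + 200) for p in
             range(0, 990_000, 37_000)]
        )
        prev = None
        for ext in (10_000, 100_000, 1_000_000):
            assoc = associate_regions_to_genes(
                regions, genes, max_extension=ext, genome={"chr1": 1_000_000}
            )
            pairs = {
                (i, g) for i, gl in enumerate(assoc.region_genes) for g in gl
            }
            if prev is not None:
                assert prev <= pairs
            prev = pairs


class TestTermEnrichment:
    def _toy(self):
        genes = [
            GeneModel(f"g{i}", "chr1", 50_000 + 100_000 * i, "+") for i in range(8)
        ]
        regions = IntervalSet(
            [GenomicInterval("chr1", 49_000 + 100_000 * (i % 2), 49_200 + 100_000 * (i % 2))
             for i in range(6)]
        )
        assoc = associate_regions_to_genes(
            regions, genes, genome={"chr1": 900_000}
        )
        return assoc

    def test_whole_genome_term_not_enriched(self):
        assoc = self._toy()
        df = term_enrichment(assoc, {"all": {f"g{i}" for i in range(8)}}, 900_000)
        row = df.iloc[0]
        # the union of all domains tiles the chromosome: expected == observed
        assert row["fold"] == pytest.approx(1.0, abs=0.05)
        assert row["p_binomial"] > 0.5

    def test_zero_hit_term_not_significant(self):
        assoc = self._toy()
        df = term_enrichment(assoc, {"none": {"g7"}}, 900_000)
        row = df.iloc[0]
        assert row["region_hits"] == 0 and row["fold"] == 0.0
        assert not row["significant"]

    def test_planted_dense_term_is_significant(self):
        # 100 genes tile a 1 Mb chromosome; regions pile up around the four
        # genes of one term at several times the genome-wide density
        rng = np.random.default_rng(4)
        genes = [GeneModel(f"g{i}", "chr1", 5_000 + 10_000 * i, "+") for i in range(100)]
        term_genes = {f"g{i}" for i in range(4)}
        spans = []
        for _ in range(60):
            g = int(rng.integers(0, 4))
            pos = 5_000 + 10_000 * g + int(rng.integers(-3000, 3000))
            spans.append(GenomicInterval("chr1", pos, pos + 150))
        for _ in range(10):
            pos = int(rng.integers(200_000, 990_000))
            spans.append(GenomicInterval("chr1", pos, pos + 150))
        assoc = associate_regions_to_genes(
            IntervalSet(spans), genes, genome={"chr1": 1_000_000}
        )
        df = term_enrichment(
            assoc,
            {"dense": term_genes, "other": {f"g{i}" for i in range(50, 54)}},
            1_000_000,
        ).set_index("term")
        assert bool(df.loc["dense", "significant"])
        assert df.loc["dense", "fold"] > 2
        assert not bool(df.loc["other", "significant"])


class TestIO:
    def test_fasta_roundtrip(self, tmp_path):
        recs = [("a", "ACGT" * 40), ("b", "N" * 10)]
        p = tmp_path / "x.fa"
        write_fasta(recs, p)
        assert read_fasta(p) == recs

    def test_read_motifs_consensus_and_pwm(self, tmp_path):
        p = tmp_path / "motifs.txt"
        p.write_text(
            "DLX\tTAATTA\n>PWM1\n0.97 0.01 0.01 0.01\n0.01 0.01 0.01 0.97\n"
        )
        motifs = read_motifs(p)
        assert motifs[0].id == "DLX" and motifs[0].consensus == "TAATTA"
        assert motifs[1].pwm.shape == (2, 4)

    def test_tss_and_term_map_readers(self, tmp_path):
        tss = tmp_path / "tss.tsv"
        tss.write_text("chr1\t1000\tgeneA\t+\nchr2\t500\tgeneB\t-\n")
        genes = read_tss_table(tss)
        assert [g.gene_id for g in genes] == ["geneA", "geneB"]
        tm = tmp_path / "terms.tsv"
        tm.write_text("termX\tgeneA\ntermX\tgeneB\ntermY\tgeneA\n")
        terms = read_term_map(tm)
        assert terms == {"termX": {"geneA", "geneB"}, "termY": {"geneA"}}
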