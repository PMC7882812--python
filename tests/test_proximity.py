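import numpy as np
import pytest

from qremap.eclip import ValidatedQre
from qremap.intervals import GenomicInterval, interval_gap
from qremap.mirna import MiRnaTargetSite
from qremap.proximity import (
    ProximityConfig,
    find_proximal_pairs,
    summarize_genes,
)
from qremap.scanner import MotifHit


def vqre(blocks, gene="G1", tid="t1", support=1, contig="chr1"):
    g = tuple(GenomicInterval(contig, s, e, "+") for s, e in blocks)
    hit = MotifHit(
        transcript_id=tid, gene_symbol=gene, t_start=0, t_end=5,
        genomic_blocks=g, core_seq="ACUAA", half_site_t_start=None,
        spans_junction=len(g) > 1,
    )
    return ValidatedQre(hit, support, (), {"rep1": True})


def site(start, end, gene="G1", mirna="miR-1", score=-2.0, contig="chr1"):
    return MiRnaTargetSite(
        mirna_id=mirna, gene_symbol=gene,
        interval=GenomicInterval(contig, start, end), mirsvr_score=score,
    )


class TestFindProximalPairs:
    def test_distance_five_is_proximal(self):
        pairs = find_proximal_pairs([vqre([(1000, 1005)])], [site(1010, 1032)])
        assert len(pairs) == 1 and pairs[0].distance_nt == 5

    def test_distance_twenty_excluded_strict(self):
        pairs = find_proximal_pairs([vqre([(1000, 1005)])], [site(1025, 1047)])
        assert pairs == []

    def test_distance_nineteen_included(self):
        pairs = find_proximal_pairs([vqre([(1000, 1005)])], [site(1024, 1046)])
        assert len(pairs) == 1 and pairs[0].distance_nt == 19

    def test_overlap_is_distance_zero(self):
        pairs = find_proximal_pairs([vqre([(1000, 1005)])], [site(1003, 1025)])
        assert pairs[0].distance_nt == 0

    def test_cross_gene_pairs_excluded(self):
        pairs = find_proximal_pairs(
            [vqre([(1000, 1005)], gene="G1")], [site(1010, 1032, gene="G2")]
        )
        assert pairs == []

    def test_junction_qre_uses_nearest_block(self):
        q = vqre([(100, 103), (200, 202)])
        pairs = find_proximal_pairs([q], [site(205, 227)])
        assert pairs[0].distance_nt == 3

    def test_monotone_in_max_distance(self):
        rng = np.random.default_rng(4)
        qres = [vqre([(int(p), int(p) + 5)]) for p in rng.integers(0, 2000, 10)]
        sites = [site(int(p), int(p) + 22) for p in rng.integers(0, 2000, 20)]
        sizes = [
            len(find_proximal_pairs(qres, sites, ProximityConfig(max_distance_nt=d)))
            for d in (5, 20, 50, 200)
        ]
        assert sizes == sorted(sizes)

    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(6)
        qres = [vqre([(int(p), int(p) + 5)]) for p in rng.integers(0, 3000, 30)]
        sites = [site(int(p), int(p) + 22) for p in rng.integers(0, 3000, 40)]
        pairs = find_proximal_pairs(qres, sites)
        brute = set()
        for qi, q in enumerate(qres):
            for si, s in enumerate(sites):
                d = min(interval_gap(b, s.interval) for b in q.hit.genomic_blocks)
                if d < 20:
                    brute.add((q.hit.genomic_blocks, s.interval, d))
        assert {(p.qre.hit.genomic_blocks, p.site.interval, p.distance_nt) for p in pairs} == brute

    def test_order_invariant(self):
        rng = np.random.default_rng(8)
        qres = [vqre([(int(p), int(p) + 5)]) for p in rng.integers(0, 500, 8)]
        sites = [site(int(p), int(p) + 22) for p in rng.integers(0, 500, 8)]
        a = find_proximal_pairs(qres, sites)
        b = find_proximal_pairs(list(reversed(qres)), list(reversed(sites)))
        key = lambda ps: [(p.qre.hit.genomic_blocks, p.site.interval) for p in ps]
        assert key(a) == key(b)

    def test_spliced_mode_agrees_within_one_exon(self, sim_dir, pipeline_result):
        """Genomic and spliced distances coincide for single-exon placements."""
        from qremap.proximity import ProximityConfig, find_proximal_pairs

        utrs = {u.region.transcript_id: u for u in pipeline_result["utrs"]}
        genomic = pipeline_result["pairs"]
        spliced = find_proximal_pairs(
            pipeline_result["validated"],
            pipeline_result["kept_sites"],
            ProximityConfig(coordinate_space="spliced"),
            utrs,
        )
        g = {(p.gene_symbol, p.site.mirna_id): p.distance_nt for p in genomic}
        s = {(p.gene_symbol, p.site.mirna_id): p.distance_nt for p in spliced}
        assert g == s


class TestSummarizeGenes:
    def test_groups_and_orders(self):
        q = vqre([(1000, 1005)])
        pairs = find_proximal_pairs(
            [q, vqre([(5000, 5005)], gene="A9", tid="t2")],
            [
                site(1010, 1032, mirna="miR-1"),
                site(1012, 1034, mirna="miR-2"),
                site(5010, 5032, gene="A9", mirna="miR-3"),
            ],
        )
        table = summarize_genes(pairs)
        assert list(table["gene"]) == ["A9", "G1"]
        row = table[table["gene"] == "G1"].iloc[0]
        assert row["n_pairs"] == 2 and row["n_mirnas"] == 2

    def test_empty(self):
        assert summarize_genes([]).empty

    def test_fixture_contains_only_planted_genes(self, sim_truth, pipeline_result):
        assert list(pipeline_result["gene_summary"]["gene"]) == sorted(
            sim_truth.proximal_genes
        )
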