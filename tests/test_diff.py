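"""Transcript matching, extension classification and gene correspondence."""

import numpy as np
import pytest

from annoforge import (
    SimParams,
    classify_extension,
    detect_merged_genes,
    gene_correspondence,
    gene_coverage_change,
    generate_annotation_pair,
    match_transcripts,
    summarize_extensions,
)
from annoforge.diff import TranscriptMatch, boundary_deltas
from annoforge.recovery import extension_recovery, merge_recovery

from .conftest import make_annotation, make_gene, make_tx
from .oracles import exonic_union_length_oracle


class TestMatching:
    def test_same_intron_chain_matches(self):
        old = make_annotation([make_gene("g", [[(0, 100), (200, 300)]])])
        new = make_annotation([make_gene("g", [[(0, 100), (200, 350)]])])
        (m,) = match_transcripts(old, new)
        assert m.new_id is not None and m.category == "tts_extended"

    def test_different_intron_chain_no_match(self):
        old = make_annotation([make_gene("g", [[(0, 100), (200, 300)]])])
        new = make_annotation([make_gene("g", [[(0, 100), (250, 350)]])])
        (m,) = match_transcripts(old, new)
        assert m.new_id is None and m.category == "no_internal_match"

    def test_single_exon_requires_unique_overlap(self):
        old = make_annotation([make_gene("g", [[(100, 200)]])])
        new_unique = make_annotation([make_gene("g", [[(150, 400)]])])
        (m,) = match_transcripts(old, new_unique)
        assert m.new_id == "g.t1"
        new_two = make_annotation([make_gene("g", [[(150, 250)], [(90, 160)]])])
        (m,) = match_transcripts(old, new_two)
        assert m.category == "no_internal_match"

    def test_ambiguous_picks_most_extended(self):
        old = make_annotation([make_gene("g", [[(100, 200), (300, 400)]])])
        new = make_annotation(
            [make_gene("g", [[(100, 200), (300, 400)], [(50, 200), (300, 500)]])]
        )
        (m,) = match_transcripts(old, new)
        assert m.ambiguous and m.new_id == "g.t2"
        assert m.category == "both_extended"

    def test_brute_force_agreement_on_random_pairs(self, rng):
        """Match decisions equal an all-pairs intron-chain comparison."""
        p = SimParams(seed=11, n_genes=150, n_merged_pairs=3, n_novel_genes=5,
                      events_per_type={"SE": 3, "RI": 3})
        old, new, _ = generate_annotation_pair(p)
        matches = {m.old_id: m for m in match_transcripts(old, new)}
        new_txs = list(new.transcripts())
        for old_t in old.transcripts():
            if len(old_t.exons) > 1:
                brute = [
                    t for t in new_txs
                    if t.chrom == old_t.chrom and t.strand == old_t.strand
                    and t.intron_chain == old_t.intron_chain
                ]
            else:
                brute = [
                    t for t in new_txs
                    if len(t.exons) == 1 and t.chrom == old_t.chrom
                    and t.strand == old_t.strand
                    and t.span_start < old_t.span_end
                    and old_t.span_start < t.span_end
                ]
                if len(brute) != 1:
                    brute = []
            m = matches[old_t.transcript_id]
            assert (m.new_id is not None) == bool(brute)
            if brute:
                assert m.new_id in {t.transcript_id for t in brute}


class TestExtensionClassification:
    @pytest.mark.parametrize(
        "strand,old_ex,new_ex,category,deltas",
        [
            ("+", [(100, 500)], [(100, 700)], "tts_extended", (0, 200)),
            ("-", [(100, 500)], [(50, 500)], "tts_extended", (0, 50)),
            ("-", [(100, 500)], [(100, 700)], "tss_extended", (200, 0)),
            ("+", [(100, 500)], [(100, 500)], "no_change", (0, 0)),
            ("+", [(100, 500)], [(50, 700)], "both_extended", (50, 200)),
            ("+", [(100, 500)], [(100, 450)], "contracted", (0, -50)),
            ("+", [(100, 500)], [(150, 700)], "tts_extended", (-50, 200)),
        ],
    )
    def test_categories_and_signed_deltas(self, strand, old_ex, new_ex, category, deltas):
        old_t = make_tx("o", old_ex, strand)
        new_t = make_tx("n", new_ex, strand)
        cat, rec = classify_extension(old_t, new_t)
        assert cat == category
        assert (rec.tss_delta, rec.tts_delta) == deltas

    def test_translation_and_mirror_invariance(self):
        old_t = make_tx("o", [(100, 200), (300, 500)], "+")
        new_t = make_tx("n", [(100, 200), (300, 700)], "+")
        cat, rec = classify_extension(old_t, new_t)
        shift = 10_000
        cat2, rec2 = classify_extension(
            make_tx("o", [(100 + shift, 200 + shift), (300 + shift, 500 + shift)], "+"),
            make_tx("n", [(100 + shift, 200 + shift), (300 + shift, 700 + shift)], "+"),
        )
        assert (cat, rec) == (cat2, rec2)
        C = 10_000
        mirror = lambda ex: sorted((C - e, C - s) for s, e in ex)
        cat3, rec3 = classify_extension(
            make_tx("o", mirror([(100, 200), (300, 500)]), "-"),
            make_tx("n", mirror([(100, 200), (300, 700)]), "-"),
        )
        assert (cat, rec) == (cat3, rec3)


class TestSummaries:
    def test_median_of_planted_deltas(self):
        matches = [
            TranscriptMatch("a", "a", "tts_extended", extension=boundary_deltas(
                make_tx("o", [(0, 100)]), make_tx("n", [(0, 100 + d)])))
            for d in (100, 251, 300)
        ]
        s = summarize_extensions(matches)
        assert s.median_tts_extension == 251
        assert s.median_tss_extension is None

    def test_no_extensions_medians_undefined(self):
        matches = [TranscriptMatch("a", "a", "no_change")]
        s = summarize_extensions(matches)
        assert s.counts["no_change"] == 1
        assert s.median_tss_extension is None and s.median_tts_extension is None


class TestCoverageChange:
    def test_fold_change_classes(self):
        old = make_annotation([make_gene("g", [[(0, 1000)]])])
        new = make_annotation([make_gene("g", [[(0, 1200)]])])
        table = gene_correspondence(old, new)
        (rec,) = gene_coverage_change(old, new, table)
        assert rec.klass == "more" and rec.fold_change == pytest.approx(1.2)
        same = gene_coverage_change(old, old, gene_correspondence(old, old))
        assert same[0].klass == "same" and same[0].fold_change == 1.0

    def test_klass_against_per_base_oracle(self, rng):
        p = SimParams(seed=21, n_genes=120, n_merged_pairs=0, n_novel_genes=0,
                      events_per_type={})
        old, new, _ = generate_annotation_pair(p)
        table = gene_correspondence(old, new)
        for rec in gene_coverage_change(old, new, table):
            o = exonic_union_length_oracle(old.genes[rec.old_gene_id])
            n = exonic_union_length_oracle(new.genes[rec.new_gene_id])
            assert (rec.old_nt, rec.new_nt) == (o, n)


class TestMergesAndCorrespondence:
    def test_basic_merge(self):
        old = make_annotation(
            [make_gene("A", [[(0, 1000)]]), make_gene("B", [[(2000, 3000)]])]
        )
        new = make_annotation([make_gene("M", [[(0, 1000), (2000, 3000)]])])
        (rec,) = detect_merged_genes(old, new)
        assert rec.old_gene_ids == frozenset({"A", "B"})

    def test_strand_mismatch_no_merge(self):
        old = make_annotation(
            [make_gene("A", [[(0, 1000)]], "+"), make_gene("B", [[(2000, 3000)]], "-")]
        )
        new = make_annotation([make_gene("M", [[(0, 1000), (2000, 3000)]], "+")])
        assert detect_merged_genes(old, new) == []

    def test_correspondence_partition(self):
        old = make_annotation(
            [make_gene("A", [[(0, 100)]]), make_gene("L", [[(5000, 5100)]])]
        )
        new = make_annotation(
            [make_gene("A2", [[(0, 150)]]), make_gene("N", [[(9000, 9100)]])]
        )
        t = gene_correspondence(old, new)
        assert t.old_class == {"A": "one_to_one", "L": "lost"}
        assert t.new_class == {"A2": "one_to_one", "N": "new_gene"}

    def test_planted_merges_recovered_over_seeds(self):
        """All planted merges found, zero spurious, across 10 seeds."""
        for seed in range(10):
            p = SimParams(seed=seed, n_genes=100, n_merged_pairs=4,
                          n_novel_genes=3, events_per_type={"SE": 2})
            old, new, truth = generate_annotation_pair(p)
            r = merge_recovery(detect_merged_genes(old, new), truth)
            assert r["sensitivity"] == 1.0 and r["false_positives"] == 0

    def test_merge_detection_order_independent(self):
        p = SimParams(seed=4, n_genes=60, n_merged_pairs=3, n_novel_genes=0,
                      events_per_type={})
        old, new, _ = generate_annotation_pair(p)
        recs = detect_merged_genes(old, new)
        shuffled_old = make_annotation(
            [old.genes[g] for g in reversed(sorted(old.genes))], old.source_label
        )
        recs2 = detect_merged_genes(shuffled_old, new)
        assert [(r.new_gene_id, r.old_gene_ids) for r in recs] == [
            (r.new_gene_id, r.old_gene_ids) for r in recs2
        ]


class TestPlantedRecovery:
    def test_planted_categories_and_deltas_exact(self):
        p = SimParams(seed=2)
        old, new, truth = generate_annotation_pair(p)
        matches = match_transcripts(old, new)
        r = extension_recovery(matches, truth)
        assert r["n"] >= 400
        assert r["category_recovery"] == 1.0
        assert r["delta_recovery"] == 1.0

    def test_summaries_equal_realized_sample_medians(self):
        p = SimParams(seed=2)
        old, new, truth = generate_annotation_pair(p)
        s = summarize_extensions(match_transcripts(old, new))
        tts = sorted(
            f["tts_delta"] for f in truth.transcripts.values() if f["tts_delta"] > 0
        )
        tss = sorted(
            f["tss_delta"] for f in truth.transcripts.values() if f["tss_delta"] > 0
        )
        assert s.median_tts_extension == float(np.median(tts))
        assert s.median_tss_extension == float(np.median(tss))
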