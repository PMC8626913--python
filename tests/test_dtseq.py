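"""dT-seq: polyT filtering, coverage, peaks, summits, categorization."""

from collections import defaultdict

import numpy as np
import pytest

from annoforge import (
    AlignedFirstMate,
    CoverageTrack,
    DtSeqParams,
    Peak,
    SimParams,
    call_peaks,
    categorize_dt_peaks,
    classify_peak_context,
    compute_coverage,
    filter_polyt_reads,
    five_prime_reduce,
    generate_annotation_pair,
    polya_junction_track,
    retain_reads,
    simulate_dthex_reads,
    tts_metaprofile,
)
from annoforge.recovery import tts_recovery

from .conftest import make_annotation, make_gene, make_tx
from .oracles import coverage_oracle


def read(start, end, strand="+", chrom="chr1", lib="dT", rid="r"):
    return AlignedFirstMate(rid, chrom, start, end, strand, lib)


def track_from(cov_by_pos, strand="+", chrom="chr1"):
    pos = np.array(sorted(cov_by_pos))
    cnt = np.array([cov_by_pos[p] for p in pos])
    return CoverageTrack(chrom, strand, pos, cnt)


class TestPolyTFilter:
    @pytest.mark.parametrize(
        "seq,keep,trimmed",
        [
            ("TTTTTTACGT", True, "ACGT"),
            ("TTATTTCGCG", True, "CGCG"),   # one interruption tolerated
            ("ACGTTTACGT", False, ""),      # 3 Ts in first 6
            ("TTTTTAGGGG", True, "AGGGG"),  # interruption not followed by T kept
            ("TTTT", False, ""),            # shorter than the prefix
        ],
    )
    def test_rule(self, seq, keep, trimmed):
        k, t = filter_polyt_reads(seq)
        assert (k, t) == (keep, trimmed)

    def test_trimmed_is_suffix_and_keep_matches_count(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(300):
            seq = "".join(rng.choice(bases, size=int(rng.integers(6, 30)),
                                     p=[0.15, 0.15, 0.15, 0.55]))
            keep, trimmed = filter_polyt_reads(seq)
            assert keep == (seq[:6].count("T") >= 5)
            if keep:
                assert seq.endswith(trimmed)
                assert not trimmed.startswith("TT")


class TestCoverage:
    def test_interval_stabbing(self):
        t = compute_coverage([read(0, 10), read(5, 15)])
        assert t.coverage_at(7) == 2 and t.coverage_at(12) == 1 and t.coverage_at(20) == 0

    def test_empty(self):
        t = compute_coverage([])
        assert len(t.positions) == 0

    def test_matches_dense_oracle(self, rng):
        reads = [
            read(int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 2000, 1000), rng.integers(1, 120, 1000))
        ]
        t = compute_coverage(reads)
        dense = coverage_oracle(reads, 0, 2200)
        sparse = np.zeros(2200, dtype=int)
        sparse[t.positions] = t.counts
        assert np.array_equal(dense, sparse)


class TestPeaks:
    def test_summit_definition_plus_strand(self):
        t = track_from({1: 1, 2: 2, 3: 5, 4: 5, 5: 4})
        (pk,) = call_peaks(t)
        assert (pk.start, pk.end, pk.max_cov) == (1, 6, 5)
        assert pk.summit == 4  # tentative {3,4}; most downstream on +

    def test_summit_definition_minus_strand(self):
        t = track_from({1: 1, 2: 2, 3: 5, 4: 5, 5: 4}, strand="-")
        (pk,) = call_peaks(t)
        assert pk.summit == 3  # downstream is leftward

    def test_uniform_coverage_all_tentative(self):
        t = track_from({p: 1 for p in range(10, 20)})
        (pk,) = call_peaks(t)
        assert pk.summit == 19

    def test_peaks_tile_covered_positions(self, rng):
        for _ in range(50):
            cov = {}
            for s in rng.integers(0, 500, 40):
                for x in range(int(s), int(s) + int(rng.integers(1, 30))):
                    cov[x] = cov.get(x, 0) + 1
            t = track_from(cov)
            peaks = call_peaks(t)
            tiled = sorted(x for pk in peaks for x in range(pk.start, pk.end))
            assert tiled == sorted(cov)
            for a, b in zip(peaks, peaks[1:]):
                assert a.end < b.start  # disjoint and maximal

    def test_summit_against_direct_evaluation_oracle(self, rng):
        """1000 random tracks: summit satisfies its defining predicate and
        downstream-maximality."""
        for i in range(1000):
            strand = "+" if i % 2 else "-"
            n = int(rng.integers(1, 60))
            pos = np.unique(rng.integers(0, 300, n))
            cnt = rng.integers(1, 50, len(pos))
            t = CoverageTrack("c", strand, pos, cnt)
            cov = dict(zip(pos.tolist(), cnt.tolist()))
            for pk in call_peaks(t):
                in_peak = [x for x in cov if pk.start <= x < pk.end]
                mx = max(cov[x] for x in in_peak)
                tentative = [x for x in in_peak if cov[x] >= 0.9 * mx]
                want = max(tentative) if strand == "+" else min(tentative)
                assert pk.max_cov == mx and pk.summit == want


class TestCategorization:
    def hexpk(self, start, end, summit, strand="+"):
        return Peak("chr1", strand, start, end, 10, summit)

    def test_downstream_retained(self):
        dt = self.hexpk(80, 120, 100)
        (d,) = categorize_dt_peaks([dt], [self.hexpk(70, 110, 90)])
        assert d.retained and d.category == "summit_downstream_or_equal"

    def test_any_downstream_hex_summit_discards(self):
        dt = self.hexpk(80, 120, 100)
        hexes = [self.hexpk(70, 110, 90), self.hexpk(95, 130, 110)]
        (d,) = categorize_dt_peaks([dt], hexes)
        assert not d.retained and d.category == "summit_upstream_of_hex"

    def test_no_overlap_discarded_by_default(self):
        dt = self.hexpk(80, 120, 100)
        (d,) = categorize_dt_peaks([dt], [self.hexpk(300, 350, 320)])
        assert not d.retained and d.category == "no_hex_overlap"
        (d2,) = categorize_dt_peaks([dt], [self.hexpk(300, 350, 320)],
                                    keep_no_overlap=True)
        assert d2.retained

    def test_equal_summit_retained(self):
        dt = self.hexpk(80, 120, 100)
        (d,) = categorize_dt_peaks([dt], [self.hexpk(70, 110, 100)])
        assert d.retained

    def test_minus_strand_mirror(self):
        dt = self.hexpk(80, 120, 100, "-")
        (d,) = categorize_dt_peaks([dt], [self.hexpk(90, 130, 110, "-")])
        assert d.retained  # 100 <= 110 is downstream on -


class TestReadOps:
    def test_retain_reads_subset_by_overlap(self):
        from annoforge.dtseq import PeakDecision, CATEGORY_DOWNSTREAM, CATEGORY_NO_OVERLAP

        keep = Peak("chr1", "+", 100, 200, 5, 150)
        drop = Peak("chr1", "+", 500, 600, 5, 550)
        decisions = [
            PeakDecision(keep, CATEGORY_DOWNSTREAM, True),
            PeakDecision(drop, CATEGORY_NO_OVERLAP, False),
        ]
        reads = [read(120, 180, rid="in"), read(520, 580, rid="out"),
                 read(190, 260, rid="edge")]
        kept = retain_reads(reads, decisions)
        assert [r.read_id for r in kept] == ["in", "edge"]
        assert set(kept) <= set(reads)

    def test_five_prime_reduce_strand_aware_and_conserving(self):
        reads = [read(100, 150, "+"), read(100, 150, "-"), read(100, 150, "+")]
        pts = five_prime_reduce(reads)
        assert pts == {100: 2, 149: 1}
        assert sum(pts.values()) == len(reads)

    def test_polya_junction_is_three_prime(self):
        assert polya_junction_track([read(100, 150, "+")]) == {149: 1}
        assert polya_junction_track([read(100, 150, "-")]) == {100: 1}


class TestPeakContext:
    def test_utr3_cds_other(self):
        tx = make_tx("t", [(0, 1000)], cds=[(100, 600)])
        ann = make_annotation([make_gene("g", [[(0, 1000)]])])
        ann.genes["g"].transcripts[0] = tx
        peaks = [
            Peak("chr1", "+", 600, 650, 5, 610),   # just past CDS end
            Peak("chr1", "+", 300, 350, 5, 320),   # mid-CDS
            Peak("chr1", "+", 5000, 5100, 5, 5050),
        ]
        assert classify_peak_context(peaks, ann) == ["UTR3", "CDS", "other"]

    def test_no_cds_only_other(self):
        ann = make_annotation([make_gene("g", [[(0, 1000)]])])
        pk = Peak("chr1", "+", 300, 350, 5, 320)
        assert classify_peak_context([pk], ann) == ["other"]


class TestMetaprofile:
    def test_delta_at_zero(self):
        sites = [(500, "+"), (900, "-")]
        cov = {500: 3, 900: 7}
        prof = tts_metaprofile(cov, sites, DtSeqParams(metaprofile_halfwidth=10))
        assert prof.matrix[0, 10] == 3 and prof.matrix[1, 10] == 7
        assert prof.mean_profile[10] == 5
        assert prof.matrix.sum() == 10

    def test_minus_strand_rows_oriented(self):
        # coverage 5 nt downstream of a minus-strand TTS at 900 -> position 895
        prof = tts_metaprofile({895: 4}, [(900, "-")], DtSeqParams(metaprofile_halfwidth=10))
        assert prof.matrix[0, 15] == 4  # offset +5

    def test_edge_padding_flagged(self):
        prof = tts_metaprofile({2: 1}, [(2, "+")], DtSeqParams(metaprofile_halfwidth=10))
        assert prof.padded[0]
        assert prof.matrix[0, :8].sum() == 0

    def test_empty_track_zero_matrix(self):
        prof = tts_metaprofile({}, [(100, "+")])
        assert prof.matrix.sum() == 0

    def test_jittered_junctions_mode_near_zero(self, rng):
        """polyA junctions with sigma=20 jitter: smoothed mean profile peaks
        within 5 nt of the annotated TTS."""
        sites = [(int(x), "+" if i % 2 else "-")
                 for i, x in enumerate(rng.integers(10_000, 1_000_000, 400))]
        cov = {}
        for pos, strand in sites:
            sign = 1 if strand == "+" else -1
            for j in np.round(rng.normal(0, 20, 50)).astype(int):
                g = pos + sign * j
                cov[g] = cov.get(g, 0) + 1
        prof = tts_metaprofile(cov, sites)
        kernel = np.ones(21) / 21
        smooth = np.convolve(prof.mean_profile, kernel, mode="same")
        mode = prof.offsets[int(np.argmax(smooth))]
        assert abs(mode) <= 5


class TestEndToEndRecovery:
    def run(self, seed, sigma):
        p = SimParams(seed=seed, n_genes=50, exons_per_gene=(3, 6),
                      n_merged_pairs=0, n_novel_genes=0, events_per_type={},
                      summit_jitter_sd=sigma, n_internal_a_stretches=50)
        old, _, _ = generate_annotation_pair(p)
        dt, hx, truth = simulate_dthex_reads(old, p)
        groups = defaultdict(lambda: ([], []))
        for r in dt:
            groups[(r.chrom, r.strand)][0].append(r)
        for r in hx:
            groups[(r.chrom, r.strand)][1].append(r)
        decisions = []
        for (c, s), (d, h) in groups.items():
            decisions += categorize_dt_peaks(
                call_peaks(compute_coverage(d)), call_peaks(compute_coverage(h))
            )
        return decisions, truth

    def test_noiseless_recovery_exact(self):
        decisions, truth = self.run(seed=3, sigma=0.0)
        r = tts_recovery(decisions, truth)
        assert r["sensitivity"] == 1.0 and r["precision"] == 1.0
        # every retained summit sits exactly on a true TTS
        sites = {(s["chrom"], s["strand"], s["pos"]) for s in truth.tts_sites}
        for d in decisions:
            if d.retained:
                pk = d.dt_peak
                assert (pk.chrom, pk.strand, pk.summit) in sites

    def test_strand_mirroring_preserves_retention(self):
        decisions, _ = self.run(seed=3, sigma=0.0)
        n_plus = sum(d.retained for d in decisions if d.dt_peak.strand == "+")
        n_minus = sum(d.retained for d in decisions if d.dt_peak.strand == "-")
        assert n_plus + n_minus == 50
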