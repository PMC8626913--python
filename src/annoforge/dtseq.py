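"""dT-seq analysis: polyT read filtering, strand-aware coverage, peak and
summit calling, dT-vs-hexamer categorization, and TTS metaprofiles.

The protocol compares two libraries made from the same polyA-selected,
fragmented RNA: one primed with an anchored oligo-dT (reads mark polyA
junctions) and one with random hexamers (reads sample transcript bodies).
A dT coverage peak marks a genuine transcription termination site only if
there is no hexamer signal downstream of its summit; internal A-stretches
produce dT piles with hexamer coverage continuing downstream and are
rejected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .models import GenomeAnnotation, is_downstream_or_equal


@dataclass
class DtSeqParams:
    prefix_len: int = 6          # bases examined at the read 5' end
    min_t: int = 5               # minimum T count in the prefix
    summit_frac: float = 0.9     # fraction of peak max defining tentative summits
    metaprofile_halfwidth: int = 100   # nt each side of the TTS (0.2 kb window)
    min_extension_for_profile: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.summit_frac <= 1):
            raise ValueError("summit_frac must be in (0, 1]")
        if self.min_t > self.prefix_len:
            raise ValueError("min_t cannot exceed prefix_len")


@dataclass(frozen=True)
class AlignedFirstMate:
    """First mate of a pair (the mate closest to the polyA tail)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    library: str  # "dT" | "hex"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read interval must be non-empty")

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


def filter_polyt_reads(seq: str, p: DtSeqParams = DtSeqParams()) -> Tuple[bool, str]:
    """Keep a raw dT read iff its 5' prefix is T-rich, and trim the T tail.

    Keep iff the first ``prefix_len`` bases contain at least ``min_t`` T.
    Trimming removes the leading T run, tolerating at most one non-T
    interruption (only when the interruption is followed by further T).
    """
    seq = seq.upper()
    if len(seq) < p.prefix_len:
        return False, ""
    if seq[: p.prefix_len].count("T") < p.min_t:
        return False, ""
    i = 0
    mismatch_used = False
    n = len(seq)
    while i < n:
        if seq[i] == "T":
            i += 1
        elif not mismatch_used and i + 1 < n and seq[i + 1] == "T":
            mismatch_used = True
            i += 1
        else:
            break
    return True, seq[i:]


@dataclass
class CoverageTrack:
    """Sparse per-base read coverage on one chrom and strand."""

    chrom: str
    strand: str
    positions: np.ndarray  # sorted int positions with coverage >= 1
    counts: np.ndarray

    def coverage_at(self, pos: int) -> int:
        i = np.searchsorted(self.positions, pos)
        if i < len(self.positions) and self.positions[i] == pos:
            return int(self.counts[i])
        return 0

    def as_dict(self) -> Dict[int, int]:
        return dict(zip(self.positions.tolist(), self.counts.tolist()))


def compute_coverage(reads: Sequence[AlignedFirstMate]) -> CoverageTrack:
    """Per-base count of read intervals containing each position.

    All reads must share chrom and strand (filter upstream per library).
    """
    if not reads:
        return CoverageTrack("", "", np.array([], int), np.array([], int))
    chroms = {r.chrom for r in reads}
    strands = {r.strand for r in reads}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("compute_coverage expects a single chrom and strand")
    # difference array over event boundaries
    starts = np.array([r.start for r in reads])
    ends = np.array([r.end for r in reads])
    bounds = np.unique(np.concatenate([starts, ends]))
    delta = np.zeros(len(bounds), dtype=int)
    np.add.at(delta, np.searchsorted(bounds, starts), 1)
    np.add.at(delta, np.searchsorted(bounds, ends), -1)
    level = np.cumsum(delta)
    pos_chunks: List[np.ndarray] = []
    cnt_chunks: List[np.ndarray] = []
    for i in range(len(bounds) - 1):
        if level[i] > 0:
            seg = np.arange(bounds[i], bounds[i + 1])
            pos_chunks.append(seg)
            cnt_chunks.append(np.full(len(seg), level[i], dtype=int))
    positions = np.concatenate(pos_chunks) if pos_chunks else np.array([], int)
    counts = np.concatenate(cnt_chunks) if cnt_chunks else np.array([], int)
    return CoverageTrack(reads[0].chrom, reads[0].strand, positions, counts)


@dataclass(frozen=True)
class Peak:
    chrom: str
    strand: str
    start: int
    end: int
    max_cov: int
    summit: int

    def overlaps(self, other: "Peak") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


def call_peaks(track: CoverageTrack, p: DtSeqParams = DtSeqParams()) -> List[Peak]:
    """Maximal contiguous covered runs with strand-aware summits.

    Tentative summits are positions with coverage >= summit_frac x peak max;
    the summit is the most downstream tentative summit (largest coordinate on
    ``+``, smallest on ``-``).
    """
    peaks: List[Peak] = []
    if len(track.positions) == 0:
        return peaks
    breaks = np.where(np.diff(track.positions) > 1)[0] + 1
    for pos, cnt in zip(
        np.split(track.positions, breaks), np.split(track.counts, breaks)
    ):
        max_cov = int(cnt.max())
        threshold = p.summit_frac * max_cov
        tentative = pos[cnt >= threshold]
        summit = int(tentative.max() if track.strand == "+" else tentative.min())
        peaks.append(
            Peak(track.chrom, track.strand, int(pos[0]), int(pos[-1]) + 1,
                 max_cov, summit)
        )
    return peaks


CATEGORY_NO_OVERLAP = "no_hex_overlap"
CATEGORY_UPSTREAM = "summit_upstream_of_hex"
CATEGORY_DOWNSTREAM = "summit_downstream_or_equal"


@dataclass
class PeakDecision:
    dt_peak: Peak
    category: str
    retained: bool


def categorize_dt_peaks(
    dt_peaks: Sequence[Peak],
    hex_peaks: Sequence[Peak],
    keep_no_overlap: bool = False,
) -> List[PeakDecision]:
    """Sort dT peaks into the three published categories.

    A dT peak is retained iff its summit is downstream of or equal to the
    summit of EVERY overlapping hex peak — i.e. it has no hex signal
    downstream.  Peaks with no hex overlap are discarded by default
    (``keep_no_overlap`` exposes the sensitivity-analysis variant).
    """
    decisions: List[PeakDecision] = []
    for dt in dt_peaks:
        overlapping = [h for h in hex_peaks if dt.overlaps(h)]
        if not overlapping:
            decisions.append(
                PeakDecision(dt, CATEGORY_NO_OVERLAP, retained=keep_no_overlap)
            )
            continue
        ok = all(
            is_downstream_or_equal(dt.summit, h.summit, dt.strand)
            for h in overlapping
        )
        category = CATEGORY_DOWNSTREAM if ok else CATEGORY_UPSTREAM
        decisions.append(PeakDecision(dt, category, retained=ok))
    return decisions


def retain_reads(
    reads: Sequence[AlignedFirstMate], decisions: Sequence[PeakDecision]
) -> List[AlignedFirstMate]:
    """dT reads overlapping at least one retained peak by >= 1 nt."""
    retained = [d.dt_peak for d in decisions if d.retained]
    out: List[AlignedFirstMate] = []
    for r in reads:
        for pk in retained:
            if (
                r.chrom == pk.chrom
                and r.strand == pk.strand
                and r.start < pk.end
                and pk.start < r.end
            ):
                out.append(r)
                break
    return out


def five_prime_reduce(reads: Sequence[AlignedFirstMate]) -> Dict[int, int]:
    """Each read reduced to one count at its strand-aware 5' base."""
    return dict(Counter(r.five_prime for r in reads))


def polya_junction_track(reads: Sequence[AlignedFirstMate]) -> Dict[int, int]:
    """Each read reduced to its strand-aware 3' base — for dT first mates this
    is the polyA junction position."""
    return dict(Counter(r.three_prime for r in reads))


def classify_peak_context(
    peaks: Sequence[Peak], ann: GenomeAnnotation
) -> List[str]:
    """Label each peak UTR3 / CDS / other by its summit position.

    UTR3 wins over CDS; transcripts without CDS contribute only to "other".
    """
    utr3: List[Tuple[str, str, int, int]] = []
    cds: List[Tuple[str, str, int, int]] = []
    for t in ann.transcripts():
        iv = t.utr3_interval()
        if iv is not None:
            utr3.append((t.chrom, t.strand, iv[0], iv[1]))
        for c in t.cds or []:
            cds.append((t.chrom, t.strand, c.start, c.end))
    labels: List[str] = []
    for pk in peaks:
        where = "other"
        for chrom, strand, s, e in utr3:
            if chrom == pk.chrom and strand == pk.strand and s <= pk.summit < e:
                where = "UTR3"
                break
        if where == "other":
            for chrom, strand, s, e in cds:
                if chrom == pk.chrom and strand == pk.strand and s <= pk.summit < e:
                    where = "CDS"
                    break
        labels.append(where)
    return labels


@dataclass
class Metaprofile:
    matrix: np.ndarray        # site x offset, rows oriented 5'->3'
    offsets: np.ndarray       # -halfwidth .. +halfwidth
    mean_profile: np.ndarray  # column means
    padded: np.ndarray        # bool per site: window clipped at contig edge


def tts_metaprofile(
    track: CoverageTrack | Dict[int, int],
    tts_positions: Sequence[Tuple[int, str]],
    p: DtSeqParams = DtSeqParams(),
) -> Metaprofile:
    """Coverage in a window around each TTS, oriented 5'->3'.

    ``track`` may be a CoverageTrack or a bare position->count map (e.g. a
    polyA-junction point track).  Windows reaching below position 0 are
    zero-padded and flagged.
    """
    cov = track.as_dict() if isinstance(track, CoverageTrack) else track
    h = p.metaprofile_halfwidth
    offsets = np.arange(-h, h + 1)
    n = len(tts_positions)
    matrix = np.zeros((n, len(offsets)))
    padded = np.zeros(n, dtype=bool)
    for i, (pos, strand) in enumerate(tts_positions):
        sign = 1 if strand == "+" else -1
        genomic = pos + sign * offsets
        clipped = genomic < 0
        if clipped.any():
            padded[i] = True
        matrix[i] = [0 if c else cov.get(int(g), 0) for g, c in zip(genomic, clipped)]
    mean_profile = matrix.mean(axis=0) if n else np.zeros(len(offsets))
    return Metaprofile(matrix, offsets, mean_profile, padded)
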