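"""GTF (and read-only GFF3) parsing and writing.

GTF coordinates are 1-based inclusive; the internal model is 0-based
half-open.  Conversion is confined to this module.
"""

from __future__ import annotations

import io
import logging
import re
from collections import defaultdict
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Union

from .models import (
    Exon,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TranscriptModel,
    ValidationError,
)

log = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lncRNA", "other")

_GTF_ATTR = re.compile(r'(\S+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r"([^=;\s]+)=([^;]*)")


class GtfParseError(ValueError):
    """A line could not be parsed; the message names the line number."""


def _parse_attributes(field: str, dialect: str) -> Dict[str, str]:
    pattern = _GTF_ATTR if dialect == "gtf" else _GFF3_ATTR
    return {k: v for k, v in pattern.findall(field)}


def _normalize_biotype(raw: str) -> str:
    if raw in BIOTYPES:
        return raw
    if raw in ("lnc_RNA", "lincRNA"):
        return "lncRNA"
    return "other"


def _as_lines(source: Union[str, Path, Iterable[str]]) -> Iterator[str]:
    if isinstance(source, Path):
        with open(source) as fh:
            yield from fh
        return
    if isinstance(source, str):
        if source and "\n" not in source and Path(source).exists():
            with open(source) as fh:
                yield from fh
            return
        yield from io.StringIO(source)
        return
    yield from source


def read_gtf(
    source: Union[str, Path, Iterable[str]],
    label: str = "",
    dialect: str = "gtf",
) -> GenomeAnnotation:
    """Parse exon/CDS features into a :class:`GenomeAnnotation`.

    ``source`` may be a path, a multi-line string, or an iterable of lines.
    Biotype is read from ``gene_biotype`` falling back to ``gene_type``;
    unknown values map to ``other``.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    exons: Dict[str, List[Exon]] = defaultdict(list)
    cds: Dict[str, List[GenomicInterval]] = defaultdict(list)
    tx_gene: Dict[str, str] = {}
    gene_biotype: Dict[str, str] = {}
    gene_order: List[str] = []

    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
            )
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
        if feature not in ("exon", "CDS"):
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
        if start1 > end1:
            raise ValidationError(
                f"line {lineno}: start {start1} > end {end1}"
            )
        attrs = _parse_attributes(attr_s, dialect)
        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id")
        if tid is None or gid is None:
            raise GtfParseError(
                f"line {lineno}: missing gene_id or transcript_id attribute"
            )
        prev_gene = tx_gene.setdefault(tid, gid)
        if prev_gene != gid:
            raise ValidationError(
                f"line {lineno}: transcript {tid} assigned to genes "
                f"{prev_gene} and {gid}"
            )
        if gid not in gene_biotype:
            gene_order.append(gid)
        raw_bt = attrs.get("gene_biotype", attrs.get("gene_type"))
        if raw_bt is not None or gid not in gene_biotype:
            gene_biotype[gid] = _normalize_biotype(raw_bt) if raw_bt else "other"
        iv = GenomicInterval(chrom, start1 - 1, end1, strand)
        if feature == "exon":
            exons[tid].append(Exon(iv))
        else:
            cds[tid].append(iv)

    genes: Dict[str, GeneModel] = {}
    by_gene: Dict[str, List[TranscriptModel]] = defaultdict(list)
    for tid, ex in exons.items():
        gid = tx_gene[tid]
        chroms = {e.interval.chrom for e in ex}
        if len(chroms) > 1:
            raise ValidationError(
                f"transcript {tid} spans chromosomes {sorted(chroms)}"
            )
        by_gene[gid].append(
            TranscriptModel(tid, gid, ex, cds=cds.get(tid) or None)
        )
    for tid in cds:
        if tid not in exons:
            raise ValidationError(f"transcript {tid} has CDS but no exons")
    for gid in gene_order:
        if gid in by_gene:
            txs = sorted(by_gene[gid], key=lambda t: (t.span_start, t.transcript_id))
            genes[gid] = GeneModel(gid, txs, biotype=gene_biotype.get(gid, "other"))
    return GenomeAnnotation(genes=genes, source_label=label)


def write_gtf_lines(ann: GenomeAnnotation) -> Iterator[str]:
    """Emit exon (and CDS) feature lines, deterministically ordered."""
    genes = sorted(
        ann.genes.values(), key=lambda g: (g.chrom, g.span_start, g.gene_id)
    )
    for gene in genes:
        txs = sorted(
            gene.transcripts, key=lambda t: (t.span_start, t.transcript_id)
        )
        for t in txs:
            attrs = (
                f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_biotype "{gene.biotype}";'
            )
            for e in t.exons:
                yield (
                    f"{t.chrom}\tannoforge\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}"
                )
            for c in t.cds or []:
                yield (
                    f"{t.chrom}\tannoforge\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{t.strand}\t0\t{attrs}"
                )


def write_gtf(ann: GenomeAnnotation, path: Union[str, Path, None] = None) -> str:
    text = "\n".join(write_gtf_lines(ann))
    if text:
        text += "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
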