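"""Genomic-context classification of SV clusters against gene models.

Gene models come from GFF3 or GTF (via :mod:`gffutils`); UTRs are derived as
exon-minus-CDS, sided by strand.  An SV's context is the highest-precedence
label over everything it overlaps:

    EXONIC_CODING > UTR5 / UTR3 > INTRONIC > INTERGENIC

Overlap is strand-agnostic on the 1-based inclusive [pos, end] interval;
insertions are classified by their single insertion point.  "Exonic" for the
exonic-fraction statistic means {EXONIC_CODING, UTR5, UTR3}.
"""

from __future__ import annotations

import bisect
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils

__all__ = [
    "Context",
    "GeneModel",
    "Transcript",
    "GenomicContext",
    "GeneIndex",
    "load_gene_models",
    "classify_context",
]

log = logging.getLogger(__name__)


class Context(str, enum.Enum):
    EXONIC_CODING = "EXONIC_CODING"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRONIC = "INTRONIC"
    INTERGENIC = "INTERGENIC"


_PRECEDENCE = {
    Context.EXONIC_CODING: 4,
    Context.UTR5: 3,
    Context.UTR3: 3,
    Context.INTRONIC: 2,
    Context.INTERGENIC: 1,
}

EXONIC_CONTEXTS = frozenset({Context.EXONIC_CODING, Context.UTR5, Context.UTR3})

Interval = tuple[int, int]  # 1-based inclusive


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval]
    cds: list[Interval]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def longest_transcript(self) -> Transcript:
        return max(self.transcripts, key=lambda t: (t.span, t.transcript_id))


@dataclass
class GenomicContext:
    context: Context
    genes: list[str]
    detail: str

    def __post_init__(self) -> None:
        if (self.context is Context.INTERGENIC) != (not self.genes):
            raise ValueError("genes must be empty iff context is INTERGENIC")

    @property
    def is_exonic(self) -> bool:
        return self.context in EXONIC_CONTEXTS


def _subtract(intervals: list[Interval], holes: list[Interval]) -> list[Interval]:
    """Interval-set difference on sorted 1-based inclusive intervals."""
    out = []
    for s, e in intervals:
        pieces = [(s, e)]
        for hs, he in holes:
            next_pieces = []
            for ps, pe in pieces:
                if he < ps or hs > pe:
                    next_pieces.append((ps, pe))
                    continue
                if ps < hs:
                    next_pieces.append((ps, hs - 1))
                if he < pe:
                    next_pieces.append((he + 1, pe))
            pieces = next_pieces
        out.extend(pieces)
    return sorted(out)


def _derive_utrs(tx: Transcript, strand: str) -> None:
    if not tx.cds:
        # Non-coding transcript: treat all exon sequence as 3' UTR-like
        # non-coding exon content for precedence purposes.
        tx.utr3 = sorted(tx.exons)
        return
    cds_min = min(s for s, _ in tx.cds)
    cds_max = max(e for _, e in tx.cds)
    noncoding = _subtract(sorted(tx.exons), [(cds_min, cds_max)])
    left = [iv for iv in noncoding if iv[1] < cds_min]
    right = [iv for iv in noncoding if iv[0] > cds_max]
    if strand == "-":
        tx.utr5, tx.utr3 = right, left
    else:
        tx.utr5, tx.utr3 = left, right


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse GFF3/GTF into gene models with derived UTRs.

    Features without resolvable parents are skipped with a warning.  GTF and
    GFF3 encodings of the same gene produce identical models.
    """
    path = str(path)
    is_gtf = path.endswith((".gtf", ".gtf.gz"))
    kwargs = dict(dbfn=":memory:", keep_order=True, merge_strategy="create_unique")
    if is_gtf:
        kwargs.update(disable_infer_genes=True, disable_infer_transcripts=True)
    try:
        db = gffutils.create_db(path, **kwargs)
    except Exception as exc:  # empty file or no parseable features
        log.warning("no gene features parsed from %s (%s)", path, exc)
        return []

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        name = (
            gene.attributes.get("gene_name", [None])[0]
            or gene.attributes.get("Name", [None])[0]
            or gene.id
        )
        gm = GeneModel(
            gene_id=gene.id,
            gene_name=name,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start,
            end=gene.end,
        )
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            exons = sorted((f.start, f.end) for f in db.children(tx, featuretype="exon"))
            cds = sorted((f.start, f.end) for f in db.children(tx, featuretype="CDS"))
            if not exons:
                log.warning("transcript %s has no exons; skipped", tx.id)
                continue
            t = Transcript(transcript_id=tx.id.split(":")[-1], exons=exons, cds=cds)
            _derive_utrs(t, gene.strand)
            gm.transcripts.append(t)
        if gm.transcripts:
            models.append(gm)
        else:
            log.warning("gene %s has no transcripts with exons; skipped", gene.id)
    models.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return models


class GeneIndex:
    """Per-chromosome overlap lookup over gene models (sorted starts with a
    running max-end, queried via bisect)."""

    def __init__(self, models: list[GeneModel]):
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for gm in models:
            self._by_chrom.setdefault(gm.chrom, []).append(gm)
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        for chrom, genes in self._by_chrom.items():
            genes.sort(key=lambda g: (g.start, g.end))
            self._starts[chrom] = [g.start for g in genes]
            running = []
            cur = 0
            for g in genes:
                cur = max(cur, g.end)
                running.append(cur)
            self._maxend[chrom] = running

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        genes = self._by_chrom.get(chrom, [])
        if not genes:
            return []
        hi = bisect.bisect_right(self._starts[chrom], end)
        out = []
        for i in range(hi - 1, -1, -1):
            if self._maxend[chrom][i] < start:
                break
            g = genes[i]
            if g.end >= start and g.start <= end:
                out.append(g)
        out.reverse()
        return out


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _classify_against_transcript(start: int, end: int, tx: Transcript) -> Context | None:
    """Highest-precedence context of [start, end] within one transcript, or
    None if the interval does not touch the transcript at all."""
    tx_start = min(s for s, _ in tx.exons)
    tx_end = max(e for _, e in tx.exons)
    if end < tx_start or start > tx_end:
        return None
    coding = any(_overlap((start, end), iv) for iv in tx.cds)
    if coding:
        return Context.EXONIC_CODING
    if any(_overlap((start, end), iv) for iv in tx.utr5):
        return Context.UTR5
    if any(_overlap((start, end), iv) for iv in tx.utr3):
        return Context.UTR3
    return Context.INTRONIC


def _exon_number(i: int, n: int, strand: str) -> int:
    return n - i if strand == "-" else i + 1


def _detail_for(start: int, end: int, gene: GeneModel) -> str:
    """Feature enumeration in genomic order within the gene's longest
    transcript, e.g. "partially exon 2, intron 2, exon 3"."""
    tx = gene.longest_transcript
    n = len(tx.exons)
    parts: list[str] = []
    for i, (es, ee) in enumerate(tx.exons):
        num = _exon_number(i, n, gene.strand)
        if _overlap((start, end), (es, ee)):
            if start <= es and end >= ee:
                parts.append(f"exon {num}")
            elif es <= start and ee >= end:
                parts.append(f"within exon {num}")
            else:
                parts.append(f"partially exon {num}")
        if i + 1 < n:
            gap = (ee + 1, tx.exons[i + 1][0] - 1)
            if gap[0] <= gap[1] and _overlap((start, end), gap):
                intron_num = num if gene.strand != "-" else num - 1
                parts.append(f"intron {intron_num}")
    return ", ".join(parts) if parts else "gene body"


def classify_context(cluster, index: GeneIndex) -> GenomicContext:
    """Classify an SV cluster (or any object with chrom/pos/end/svtype)
    against indexed gene models.

    Precedence is taken over all overlapped transcripts of all overlapped
    genes; insertions use the single base at ``pos``.
    """
    start = cluster.pos
    end = cluster.pos if getattr(cluster, "svtype", None) == "INS" else cluster.end
    genes = index.overlapping(cluster.chrom, start, end)
    if not genes:
        return GenomicContext(context=Context.INTERGENIC, genes=[], detail="intergenic")

    best = Context.INTRONIC
    gene_contexts: list[tuple[GeneModel, Context]] = []
    for gene in genes:
        gbest: Context | None = None
        for tx in gene.transcripts:
            ctx = _classify_against_transcript(start, end, tx)
            if ctx is not None and (gbest is None or _PRECEDENCE[ctx] > _PRECEDENCE[gbest]):
                gbest = ctx
        if gbest is None:
            gbest = Context.INTRONIC  # inside gene span but outside transcript spans
        gene_contexts.append((gene, gbest))
        if _PRECEDENCE[gbest] > _PRECEDENCE[best]:
            best = gbest

    # Primary gene = max precedence, ties broken by genomic order.
    primary = max(gene_contexts, key=lambda gc: (_PRECEDENCE[gc[1]], -gc[0].start))[0]
    ordered = [primary.gene_name] + [g.gene_name for g, _ in gene_contexts if g is not primary]
    return GenomicContext(context=best, genes=ordered, detail=_detail_for(start, end, primary))
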