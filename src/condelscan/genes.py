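"""Gene models from BED12 and the canonical-isoform TSS convention.

The screen anchors its scan window at the transcription start site of each
gene's canonical isoform, defined as the transcript with the longest
genomic span (ties broken by lexicographically smallest transcript id).
The TSS is strand-aware: span start on '+', last base of the span on '-'.

BED12 input convention: the ``name`` column is ``gene_id:transcript_id``;
a name without a colon is both gene and transcript id (single-isoform
gene).  Lines sharing a gene_id form one gene and must agree on chrom and
strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .intervals import Interval, IntervalSet

__all__ = ["Transcript", "GeneModel", "read_gene_models", "parse_bed12_text"]


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    span: Interval
    exons: IntervalSet

    def __post_init__(self) -> None:
        if self.exons.is_empty():
            raise ValueError(f"{self.transcript_id}: transcript needs exons")
        if (self.exons.starts[0] < self.span.start
                or self.exons.ends[-1] > self.span.end):
            raise ValueError(
                f"{self.transcript_id}: exons outside transcript span")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene needs transcripts")

    @property
    def canonical(self) -> Transcript:
        return max(self.transcripts,
                   key=lambda t: (len(t.span), _neg_lex(t.transcript_id)))

    @property
    def tss(self) -> int:
        span = self.canonical.span
        return span.start if self.strand == "+" else span.end - 1

    @property
    def span(self) -> Interval:
        """Span of the canonical transcript."""
        return self.canonical.span

    def exon_set(self) -> IntervalSet:
        """Flattened union of exons across all transcripts."""
        out = self.transcripts[0].exons
        for t in self.transcripts[1:]:
            out = out.union(t.exons)
        return out


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smallest id on ties."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def parse_bed12_text(text: str) -> list[GeneModel]:
    per_gene: dict[str, list[tuple[str, str, str, Transcript]]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) == 1:
            f = line.split()
        if len(f) < 12:
            raise ValueError(
                f"line {lineno}: BED12 needs 12 columns, got {len(f)}")
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), \
            f[3], f[4], f[5]
        n_exons = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_exons or len(offsets) != n_exons:
            raise ValueError(f"line {lineno}: exon count mismatch")
        gene_id, _, tx_id = name.partition(":")
        tx_id = tx_id or gene_id
        exons = IntervalSet(
            chrom,
            [start + o for o in offsets],
            [start + o + s for o, s in zip(offsets, sizes)])
        tx = Transcript(tx_id, Interval(chrom, start, end), exons)
        if gene_id not in per_gene:
            order.append(gene_id)
        per_gene.setdefault(gene_id, []).append((chrom, strand, tx_id, tx))
    genes: list[GeneModel] = []
    for gene_id in order:
        rows = per_gene[gene_id]
        chroms = {r[0] for r in rows}
        strands = {r[1] for r in rows}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {gene_id!r}: transcripts disagree on chrom/strand")
        tx_ids = [r[2] for r in rows]
        if len(set(tx_ids)) != len(tx_ids):
            raise ValueError(f"gene {gene_id!r}: duplicate transcript id")
        genes.append(GeneModel(gene_id, rows[0][0], rows[0][1],
                               tuple(r[3] for r in rows)))
    return genes


def read_gene_models(path) -> list[GeneModel]:
    with open(path, encoding="ascii") as fh:
        return parse_bed12_text(fh.read())


def write_bed12_text(genes: Sequence[GeneModel]) -> str:
    lines = []
    for g in genes:
        for t in g.transcripts:
            starts = t.exons.starts
            ends = t.exons.ends
            sizes = ",".join(str(e - s) for s, e in zip(starts, ends))
            offs = ",".join(str(s - t.span.start) for s in starts)
            name = (g.gene_id if t.transcript_id == g.gene_id
                    else f"{g.gene_id}:{t.transcript_id}")
            lines.append("\t".join(map(str, [
                g.chrom, t.span.start, t.span.end, name, 0, g.strand,
                t.span.start, t.span.end, 0, len(t.exons), sizes, offs])))
    return "\n".join(lines) + ("\n" if lines else "")
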