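"""Build the measurable intron reference from a gene annotation.

Introns are the gaps between consecutive exons of a transcript. An intron is
only measurable for retention if its boundaries are unambiguous, so introns
that overlap an exon of their own gene (in any isoform), or anything belonging
to a different gene, are dropped. Flanking-exon boundaries are kept with each
intron because downstream junction counting and splice-site flank extraction
both need them.

Coordinates are 0-based half-open internally; GTF input is 1-based inclusive
and converted on parse; BED output is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

Interval = tuple[int, int]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass
class GeneModel:
    """One gene: a set of transcripts, each an ordered list of exon intervals."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[Interval]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        for tx_id, exons in self.transcripts.items():
            for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
                if s1 < e0:
                    raise ValueError(
                        f"{self.gene_id}/{tx_id}: overlapping or unsorted exons "
                        f"[{s0},{e0}) and [{s1},{e1})"
                    )

    @property
    def exons(self) -> list[Interval]:
        """Union of exon intervals over all transcripts (sorted, deduplicated)."""
        return sorted({iv for exons in self.transcripts.values() for iv in exons})


@dataclass(frozen=True)
class IntronRecord:
    """One intron with its immediately flanking exons (genomic coordinates)."""

    intron_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    left_exon: Interval
    right_exon: Interval

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"intron end must exceed start: [{self.start},{self.end})")
        if self.left_exon[1] != self.start or self.right_exon[0] != self.end:
            raise ValueError(f"{self.intron_id}: flanking exons must abut the intron")

    @property
    def length(self) -> int:
        return self.end - self.start


def make_intron_id(chrom: str, start: int, end: int, strand: str, gene_id: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}:{gene_id}"


def parse_gtf(path: str) -> list[GeneModel]:
    """Read exon features from a GTF file into GeneModels.

    Only ``exon`` features are consumed; they are grouped by gene_id and
    transcript_id. 1-based inclusive GTF coordinates become 0-based half-open.

    Raises
    ------
    GtfParseError
        On a malformed line (message names the 1-based line number) or an
        exon feature lacking a transcript_id attribute.
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if end1 < start1:
                raise GtfParseError(f"line {lineno}: end < start")
            attr = dict(_ATTR_RE.findall(attrs))
            gene_id = attr.get("gene_id")
            tx_id = attr.get("transcript_id")
            if gene_id is None:
                raise GtfParseError(f"line {lineno}: exon lacks gene_id attribute")
            if tx_id is None:
                raise GtfParseError(f"line {lineno}: exon lacks transcript_id attribute")
            gene = genes.get(gene_id)
            if gene is None:
                gene = genes[gene_id] = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand)
            elif gene.chrom != chrom or gene.strand != strand:
                raise GtfParseError(f"line {lineno}: gene {gene_id} spans multiple chroms/strands")
            gene.transcripts.setdefault(tx_id, []).append((start1 - 1, end1))
    for gene in genes.values():
        for exons in gene.transcripts.values():
            exons.sort()
        gene.validate()
    return list(genes.values())


def _overlaps(iv: Interval, others: Iterable[Interval]) -> bool:
    s, e = iv
    return any(s < oe and os_ < e for os_, oe in others)


def build_intron_reference(genes: Sequence[GeneModel]) -> list[IntronRecord]:
    """Derive the union-consensus intron set from gene models.

    For each transcript, introns are the gaps between consecutive exons.
    Identical introns from several transcripts are emitted once, recording the
    shortest flanking exons seen. Introns overlapping any exon of the same
    gene (any isoform) are dropped, as are introns touching another gene's
    exons or emitted identically by two genes — retention cannot be measured
    unambiguously there.
    """
    by_chrom_exons: dict[str, list[tuple[str, Interval]]] = {}
    for gene in genes:
        for iv in gene.exons:
            by_chrom_exons.setdefault(gene.chrom, []).append((gene.gene_id, iv))

    candidates: dict[tuple[str, int, int, str, str], tuple[Interval, Interval]] = {}
    for gene in genes:
        own_exons = gene.exons
        for exons in gene.transcripts.values():
            for (ls, le), (rs, re_) in zip(exons, exons[1:]):
                start, end = le, rs
                if start >= end:
                    continue  # zero-length gap between abutting exons
                if _overlaps((start, end), own_exons):
                    continue
                key = (gene.chrom, start, end, gene.strand, gene.gene_id)
                left, right = (ls, le), (rs, re_)
                if key in candidates:
                    pl, pr = candidates[key]
                    if le - ls < pl[1] - pl[0]:
                        pl = left
                    if re_ - rs < pr[1] - pr[0]:
                        pr = right
                    candidates[key] = (pl, pr)
                else:
                    candidates[key] = (left, right)

    # cross-gene ambiguity: same interval from two genes, or overlap with a
    # different gene's exon
    interval_owners: dict[tuple[str, int, int], set[str]] = {}
    for chrom, start, end, _strand, gene_id in candidates:
        interval_owners.setdefault((chrom, start, end), set()).add(gene_id)

    records: list[IntronRecord] = []
    for (chrom, start, end, strand, gene_id), (left, right) in sorted(candidates.items()):
        if len(interval_owners[(chrom, start, end)]) > 1:
            continue
        foreign = [iv for gid, iv in by_chrom_exons.get(chrom, []) if gid != gene_id]
        if _overlaps((start, end), foreign):
            continue
        records.append(
            IntronRecord(
                intron_id=make_intron_id(chrom, start, end, strand, gene_id),
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                left_exon=left,
                right_exon=right,
            )
        )
    return records


def write_intron_bed(introns: Sequence[IntronRecord], path: str) -> None:
    """Write introns as BED6 plus two columns carrying the flanking exons.

    Columns 1-6 are standard BED6 (name = intron_id, score = 0); columns 7/8
    hold ``start-end`` of the left and right flanking exon so that the file
    round-trips losslessly. BED6 consumers ignore the extras.
    """
    with open(path, "w") as fh:
        for rec in introns:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.intron_id}\t0\t{rec.strand}"
                f"\t{rec.left_exon[0]}-{rec.left_exon[1]}"
                f"\t{rec.right_exon[0]}-{rec.right_exon[1]}\n"
            )


def read_intron_bed(path: str) -> list[IntronRecord]:
    """Read introns written by :func:`write_intron_bed` (inverse round trip)."""
    records: list[IntronRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"line {lineno}: expected 8 columns (BED6+2)")
            chrom, start_s, end_s, name, _score, strand, left_s, right_s = fields[:8]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            ls, le = (int(x) for x in left_s.split("-"))
            rs, re_ = (int(x) for x in right_s.split("-"))
            gene_id = name.rsplit(":", 1)[1]
            records.append(
                IntronRecord(
                    intron_id=name,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    left_exon=(ls, le),
                    right_exon=(rs, re_),
                )
            )
    return records
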