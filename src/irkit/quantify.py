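"""Per-intron, per-sample retention metrics from spliced alignments.

For every reference intron and sample the module computes:

* ``ID``  — intron depth: median per-base read depth across the intron,
* ``coverage`` — fraction of intron positions covered by at least one read,
* ``SL`` / ``SR`` — junction reads linking the transcript-5'/3' flanking exon
  to another exon of the same gene,
* ``SE`` — reads whose N-gap matches the intron exactly,
* ``ir_ratio`` — ID / (ID + max(SL, SR)), the estimated fraction of the
  gene's transcripts retaining the intron.

A read whose N-gap matches the intron exactly evidences both flank junctions,
so it increments SE, SL and SR. SL/SR are reported in transcript orientation:
on the minus strand the genomic-right junction counter is SL.

Depth counts reads (duplicate, secondary and supplementary alignments are
skipped by flag); bases of a read falling outside the intron contribute
nothing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .reference import GeneModel, IntronRecord

# CIGAR op codes: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_ALIGNED_OPS = {0, 7, 8}
_SKIP_FLAGS = 0x100 | 0x200 | 0x400 | 0x800  # secondary, qcfail, dup, supplementary

METRIC_COLUMNS = ["ID", "coverage", "SL", "SR", "SE", "ir_ratio"]


@dataclass
class SampleQuant:
    """All intron metrics for one sample.

    ``metrics`` is a DataFrame indexed by intron_id with columns
    ID, coverage, SL, SR, SE, ir_ratio (one row per reference intron).
    """

    sample_id: str
    total_aligned_reads: int
    metrics: pd.DataFrame
    depth_vectors: dict[str, np.ndarray] | None = None


def intron_depth(depth: np.ndarray) -> float:
    """Median per-base depth over the intron (mean of central pair if even)."""
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("depth vector must be non-empty")
    return float(np.median(depth))


def intron_coverage(depth: np.ndarray) -> float:
    """Fraction of intron positions with depth >= 1."""
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("depth vector must be non-empty")
    return float(np.mean(depth >= 1))


def ir_ratio(ID: float, SL: int, SR: int) -> float:
    """ID / (ID + max(SL, SR)); 0 when both terms vanish."""
    if ID < 0 or SL < 0 or SR < 0:
        raise ValueError("ID, SL and SR must be non-negative")
    denom = ID + max(SL, SR)
    return float(ID / denom) if denom > 0 else 0.0


def _cigar_walk(read: pysam.AlignedSegment) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Return (aligned reference segments, N-gap intervals) for one read."""
    segments: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    for op, length in read.cigartuples:
        if op in _ALIGNED_OPS:
            segments.append((pos, pos + length))
            pos += length
        elif op == 3:  # N
            gaps.append((pos, pos + length))
            pos += length
        elif op == 2:  # D consumes reference without read bases
            pos += length
        elif op in (1, 4, 5, 6):  # I, S, H, P do not consume reference
            continue
        else:
            raise ValueError(f"unsupported CIGAR op code {op} in read {read.query_name}")
    return segments, gaps


def collect_alignments(
    sam_path: str,
    introns: Sequence[IntronRecord],
    genes: Sequence[GeneModel] | None = None,
    sample_id: str | None = None,
    keep_depth: bool = False,
) -> SampleQuant:
    """Quantify every reference intron from one SAM/BAM file.

    ``genes`` supplies the exon intervals used to decide whether a junction's
    far end lands "in another exon of the same gene"; when omitted, the union
    of flanking exons recorded in the intron reference stands in for the
    gene's exon set.

    Reads on reference names absent from the annotation are skipped with a
    warning; an unsupported CIGAR operation raises.
    """
    if sample_id is None:
        sample_id = sam_path.rsplit("/", 1)[-1].rsplit(".", 1)[0]

    gene_exons: dict[str, list[tuple[int, int]]] = {}
    if genes is not None:
        for g in genes:
            gene_exons[g.gene_id] = g.exons
    else:
        for rec in introns:
            ivs = gene_exons.setdefault(rec.gene_id, [])
            for iv in (rec.left_exon, rec.right_exon):
                if iv not in ivs:
                    ivs.append(iv)

    by_chrom: dict[str, list[int]] = {}
    for i, rec in enumerate(introns):
        by_chrom.setdefault(rec.chrom, []).append(i)

    depth = [np.zeros(rec.length, dtype=np.int64) for rec in introns]
    SL_g = np.zeros(len(introns), dtype=np.int64)  # genomic-left junction count
    SR_g = np.zeros(len(introns), dtype=np.int64)  # genomic-right
    SE = np.zeros(len(introns), dtype=np.int64)

    def in_exon(gene_id: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in gene_exons.get(gene_id, ()))

    n_reads = 0
    known_chroms = set(by_chrom)
    warned: set[str] = set()
    mode = "rb" if sam_path.endswith(".bam") else "r"
    with pysam.AlignmentFile(sam_path, mode) as fh:
        for read in fh:
            if read.is_unmapped or (read.flag & _SKIP_FLAGS):
                continue
            chrom = read.reference_name
            if chrom not in known_chroms:
                if chrom not in warned:
                    import warnings

                    warnings.warn(f"reference {chrom!r} absent from annotation; skipping its reads")
                    warned.add(chrom)
                n_reads += 1
                continue
            n_reads += 1
            segments, gaps = _cigar_walk(read)
            idxs = by_chrom[chrom]
            for seg_s, seg_e in segments:
                for i in idxs:
                    rec = introns[i]
                    lo, hi = max(seg_s, rec.start), min(seg_e, rec.end)
                    if lo < hi:
                        depth[i][lo - rec.start : hi - rec.start] += 1
            for gap_s, gap_e in gaps:
                for i in idxs:
                    rec = introns[i]
                    exact = gap_s == rec.start and gap_e == rec.end
                    if exact:
                        SE[i] += 1
                        SL_g[i] += 1
                        SR_g[i] += 1
                        continue
                    if gap_s == rec.start and in_exon(rec.gene_id, gap_e):
                        SL_g[i] += 1
                    if gap_e == rec.end and in_exon(rec.gene_id, gap_s - 1):
                        SR_g[i] += 1

    rows = []
    for i, rec in enumerate(introns):
        ID = intron_depth(depth[i])
        cov = intron_coverage(depth[i])
        if rec.strand == "+":
            sl, sr = int(SL_g[i]), int(SR_g[i])
        else:
            sl, sr = int(SR_g[i]), int(SL_g[i])
        rows.append(
            {
                "intron_id": rec.intron_id,
                "ID": ID,
                "coverage": cov,
                "SL": sl,
                "SR": sr,
                "SE": int(SE[i]),
                "ir_ratio": ir_ratio(ID, sl, sr),
            }
        )
    metrics = pd.DataFrame(rows).set_index("intron_id") if rows else pd.DataFrame(
        columns=METRIC_COLUMNS
    )
    depth_vectors = (
        {rec.intron_id: depth[i] for i, rec in enumerate(introns)} if keep_depth else None
    )
    return SampleQuant(
        sample_id=sample_id, total_aligned_reads=n_reads, metrics=metrics,
        depth_vectors=depth_vectors,
    )


def write_quant_tsv(quant: SampleQuant, path: str) -> None:
    out = quant.metrics.reset_index()
    out.insert(1, "sample_id", quant.sample_id)
    out.to_csv(path, sep="\t", index=False)


def read_quant_tsv(path: str) -> SampleQuant:
    df = pd.read_csv(path, sep="\t")
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else path.rsplit("/", 1)[-1]
    metrics = df.drop(columns=["sample_id"]).set_index("intron_id")
    return SampleQuant(sample_id=sample_id, total_aligned_reads=-1, metrics=metrics)
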