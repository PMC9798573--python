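"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the structure of a tumour/normal RNA-seq cohort at
desk scale: a random genome with alternating exon/intron gene structures, a
per-sample per-intron retention fraction pi drawn from a beta distribution
around the group mean theta, and junction-region fragments that are either
spliced (an N-gap exactly matching the intron) or unspliced (a single match
block spanning the whole intron). Because every unspliced read covers the
intron end to end, the intron depth ID equals the unspliced fragment count
exactly and the estimated IR ratio U/(U+S) inherits a closed-form binomial
link to pi — the property the consistency checks rely on. Reads are
single-end so depth counts reads and fragments interchangeably.

Also generated: negative-binomial expression matrices with genes planted to
co-vary with per-sample IR event counts, condition-wise log-fold-change
tables with planted condition-exclusive genes, and genomes with an RBP
consensus motif planted at elevated rates in chosen splice-site flanks.

All generators are pure functions of (design, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .reference import GeneModel, IntronRecord, build_intron_reference
from .motifs import reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimDesign:
    """Study-condition knobs for the synthetic cohort.

    Defaults emulate a matched tumour/normal cohort: 20 samples per group,
    a baseline retention fraction of 0.1 with a planted increase of 0.2 in
    one fifth of introns, across-sample IR variability of beta precision 30,
    and 100 expected junction fragments per intron per sample.
    """

    n_genes: int = 20
    introns_per_gene: int = 2
    exon_len: int = 120
    intron_len: int = 60
    read_len: int = 75
    gap_len: int = 100
    n_normal: int = 20
    n_cancer: int = 20
    theta_normal: float = 0.1
    delta_ir: float = 0.2
    frac_differential: float = 0.2
    phi_sim: float = 30.0
    depth: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intron_len > self.read_len - 2:
            raise ValueError("intron_len must be <= read_len - 2 so unspliced reads span the intron")
        for name in ("n_genes", "introns_per_gene", "exon_len", "intron_len", "read_len",
                     "n_normal", "n_cancer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.theta_normal <= 1 and 0 <= self.theta_normal + self.delta_ir <= 1):
            raise ValueError("retention fractions must stay in [0, 1]")


def simulate_genome(design: SimDesign) -> tuple[dict[str, str], list[GeneModel]]:
    """One contig of i.i.d. uniform bases carrying the gene loci end to end.

    Genes alternate strand (+, -, +, ...); each has one transcript with
    ``introns_per_gene + 1`` exons of ``exon_len`` separated by introns of
    ``intron_len``, and loci are separated by ``gap_len`` of intergenic
    sequence.
    """
    rng = np.random.default_rng([design.seed, 0])
    genes: list[GeneModel] = []
    pos = design.gap_len
    for gi in range(design.n_genes):
        gene_id = f"G{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        exons = []
        p = pos
        for _ in range(design.introns_per_gene + 1):
            exons.append((p, p + design.exon_len))
            p += design.exon_len + design.intron_len
        p -= design.intron_len  # no trailing intron
        genes.append(
            GeneModel(gene_id=gene_id, chrom="chr1", strand=strand,
                      transcripts={f"{gene_id}.t1": exons})
        )
        pos = p + design.gap_len
    length = pos
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    return {"chr1": seq}, genes


def write_fasta(genome: Mapping[str, str], path: str, line_width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    """Emit exon features, 1-based inclusive, Ensembl-style quoted attributes."""
    with open(path, "w") as fh:
        for g in genes:
            for tx_id, exons in g.transcripts.items():
                for s, e in exons:
                    attrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}";'
                    fh.write(f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


def _beta_draw(rng: np.random.Generator, mu: float, phi: float) -> float:
    if mu <= 0.0:
        return 0.0
    if mu >= 1.0:
        return 1.0
    return float(rng.beta(mu * phi, (1 - mu) * phi))


def simulate_sample_reads(
    design: SimDesign,
    genome: Mapping[str, str],
    introns: Sequence[IntronRecord],
    theta: Mapping[str, float],
    sample_id: str,
    sample_seed: int,
    out_sam: str,
) -> pd.DataFrame:
    """Write one sample's SAM; return the per-intron truth (pi, fragment counts).

    Per intron: the sample-level retention pi ~ Beta(mean=theta, precision
    phi_sim); fragment count n ~ Poisson(depth); U ~ Binomial(n, pi)
    fragments are unspliced (a read_len M-block spanning the intron, start
    uniform over covering offsets) and the remaining n-U are spliced reads
    whose N-gap matches the intron exactly.
    """
    rng = np.random.default_rng([design.seed, 1, sample_seed])
    chrom = introns[0].chrom if introns else "chr1"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in genome],
    }
    seq_cache = {c: genome[c] for c in genome}
    truth_rows = []
    with pysam.AlignmentFile(out_sam, "w", header=header) as out:
        tid_of = {c: i for i, c in enumerate(genome)}
        read_no = 0
        for rec in introns:
            pi = _beta_draw(rng, theta[rec.intron_id], design.phi_sim)
            n = int(rng.poisson(design.depth))
            U = int(rng.binomial(n, pi)) if n else 0
            L = rec.end - rec.start
            pad = design.read_len - L
            left_len = rec.left_exon[1] - rec.left_exon[0]
            right_len = rec.right_exon[1] - rec.right_exon[0]
            for k in range(n):
                a = pysam.AlignedSegment()
                a.query_name = f"{sample_id}:{rec.intron_id}:{k}"
                a.flag = 0
                a.reference_id = tid_of[rec.chrom]
                a.mapping_quality = 60
                if k < U:  # unspliced: spans the whole intron
                    lo = max(1, design.read_len - L - right_len)
                    hi = min(pad - 1, left_len)
                    off = int(rng.integers(lo, hi + 1))
                    start = rec.start - off
                    a.reference_start = start
                    a.cigarstring = f"{design.read_len}M"
                    a.query_sequence = seq_cache[rec.chrom][start : start + design.read_len]
                else:  # spliced: N-gap exactly matching the intron
                    amax = min(design.read_len - 1, left_len)
                    amin = max(1, design.read_len - right_len)
                    left = int(rng.integers(amin, amax + 1))
                    right = design.read_len - left
                    start = rec.start - left
                    a.reference_start = start
                    a.cigarstring = f"{left}M{L}N{right}M"
                    a.query_sequence = (
                        seq_cache[rec.chrom][start : start + left]
                        + seq_cache[rec.chrom][rec.end : rec.end + right]
                    )
                out.write(a)
                read_no += 1
            truth_rows.append(
                {"intron_id": rec.intron_id, "sample_id": sample_id, "pi": pi,
                 "n_fragments": n, "n_unspliced": U}
            )
    return pd.DataFrame(truth_rows)


@dataclass
class CohortSim:
    outdir: Path
    fasta: Path
    gtf: Path
    metadata: Path
    sam_paths: dict[str, Path]
    genome: dict[str, str]
    genes: list[GeneModel]
    introns: list[IntronRecord]
    intron_truth: pd.DataFrame   # per intron: theta_normal, theta_cancer, is_differential
    sample_truth: pd.DataFrame   # per (intron, sample): pi, fragment counts
    groups: pd.Series


def simulate_cohort(design: SimDesign, outdir: str | Path) -> CohortSim:
    """Full cohort: genome, annotation, per-sample SAMs, metadata and truth.

    A random ``frac_differential`` subset of introns carries
    theta_cancer = theta_normal + delta_ir; the rest are null. Every output
    (FASTA, GTF, SAMs, metadata.tsv, truth tables, design.resolved.yaml) is
    written under ``outdir`` and fully determined by the design seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = simulate_genome(design)
    introns = build_intron_reference(genes)

    rng = np.random.default_rng([design.seed, 2])
    n_diff = int(round(design.frac_differential * len(introns)))
    diff_idx = set(rng.choice(len(introns), size=n_diff, replace=False).tolist())
    intron_truth = pd.DataFrame(
        {
            "intron_id": [r.intron_id for r in introns],
            "theta_normal": design.theta_normal,
            "theta_cancer": [
                design.theta_normal + (design.delta_ir if i in diff_idx else 0.0)
                for i in range(len(introns))
            ],
            "is_differential": [i in diff_idx for i in range(len(introns))],
        }
    ).set_index("intron_id")

    fasta = outdir / "genome.fa"
    gtf = outdir / "annotation.gtf"
    write_fasta(genome, str(fasta))
    write_gtf(genes, str(gtf))

    sam_dir = outdir / "sams"
    sam_dir.mkdir(exist_ok=True)
    sample_ids = [f"normal_{i:03d}" for i in range(design.n_normal)] + [
        f"cancer_{i:03d}" for i in range(design.n_cancer)
    ]
    group_of = {s: ("normal" if s.startswith("normal") else "cancer") for s in sample_ids}
    sam_paths: dict[str, Path] = {}
    truth_frames = []
    for si, sample_id in enumerate(sample_ids):
        col = "theta_normal" if group_of[sample_id] == "normal" else "theta_cancer"
        theta = intron_truth[col].to_dict()
        path = sam_dir / f"{sample_id}.sam"
        truth_frames.append(
            simulate_sample_reads(design, genome, introns, theta, sample_id, si, str(path))
        )
        sam_paths[sample_id] = path

    groups = pd.Series(group_of, name="group")
    metadata = outdir / "metadata.tsv"
    groups.rename_axis("sample_id").to_frame().reset_index().to_csv(metadata, sep="\t", index=False)
    sample_truth = pd.concat(truth_frames, ignore_index=True)
    intron_truth.reset_index().to_csv(outdir / "truth_introns.tsv", sep="\t", index=False)
    sample_truth.to_csv(outdir / "truth_samples.tsv", sep="\t", index=False)
    with open(outdir / "design.resolved.yaml", "w") as fh:
        yaml.safe_dump(asdict(design), fh, sort_keys=True)

    return CohortSim(
        outdir=outdir, fasta=fasta, gtf=gtf, metadata=metadata, sam_paths=sam_paths,
        genome=genome, genes=genes, introns=introns, intron_truth=intron_truth,
        sample_truth=sample_truth, groups=groups,
    )


def simulate_expression(
    event_counts: pd.Series,
    n_genes: int = 200,
    n_planted_pos: int = 10,
    n_planted_neg: int = 10,
    coupling: float = 1.0,
    dispersion: float = 0.1,
    libsize_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts with genes planted to track IR event counts.

    Planted genes have log10 mean tied linearly (slope ``+-coupling``) to the
    centred log10 IR event count of each sample; library sizes vary
    log-normally (sd ``libsize_sd``) so size-factor recovery is testable.
    Returns (counts genes x samples, per-gene truth with the planted class).
    """
    rng = np.random.default_rng([seed, 3])
    samples = list(event_counts.index)
    z = np.log10(event_counts.to_numpy(float) + 1)
    z = z - z.mean()
    genes = [f"E{gi:04d}" for gi in range(n_genes)]
    base = rng.lognormal(mean=np.log(200), sigma=1.0, size=n_genes)
    coeff = np.zeros(n_genes)
    coeff[:n_planted_pos] = coupling
    coeff[n_planted_pos : n_planted_pos + n_planted_neg] = -coupling
    sf_true = rng.lognormal(mean=0.0, sigma=libsize_sd, size=len(samples))
    sf_true /= np.exp(np.mean(np.log(sf_true)))
    mean = base[:, None] * sf_true[None, :] * 10 ** (coeff[:, None] * z[None, :])
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "planted": np.where(coeff > 0, "pos", np.where(coeff < 0, "neg", "none")),
            "coupling": coeff,
        }
    ).set_index("gene_id")
    truth["base_mean"] = base
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth.attrs["size_factors"] = pd.Series(sf_true, index=samples, name="true_size_factor")
    return counts_df, truth


def simulate_lfc_table(
    n_genes: int = 200,
    conditions: Sequence[str] = ("BRCA", "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8"),
    n_exclusive: int = 10,
    exclusive_lfc: float = 3.0,
    null_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, set]:
    """Genes x conditions log2-fold-change table with planted exclusive genes.

    The first ``n_exclusive`` genes carry a large LFC only in the reference
    (first) condition; everything else is null noise. Returns the table and
    the planted exclusive gene set.
    """
    rng = np.random.default_rng([seed, 4])
    genes = [f"E{gi:04d}" for gi in range(n_genes)]
    lfc = rng.normal(0.0, null_sd, size=(n_genes, len(conditions)))
    signs = rng.choice([-1.0, 1.0], size=n_exclusive)
    lfc[:n_exclusive, 0] = signs * exclusive_lfc
    table = pd.DataFrame(lfc, index=genes, columns=list(conditions))
    return table, set(genes[:n_exclusive])


def plant_motifs(
    genome: Mapping[str, str],
    introns: Sequence[IntronRecord],
    consensus: str,
    region_tag: str,
    ir_intron_ids: set,
    rate_ir: float,
    rate_nr: float,
    seed: int = 0,
    width: int = 50,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Write ``consensus`` into the named flank region of a random intron subset.

    IR-class introns receive the motif with probability ``rate_ir``, the rest
    with ``rate_nr``, at a uniform offset within the region. The sequence is
    written in transcript orientation (reverse-complemented onto the genome
    for minus-strand introns). Returns the modified genome and a truth table
    of planted positions; regions shorter than the consensus are skipped with
    a warning.
    """
    import warnings

    from .motifs import REGION_TAGS

    if region_tag not in REGION_TAGS:
        raise ValueError(f"unknown region tag {region_tag!r}")
    rng = np.random.default_rng([seed, 5])
    seqs = {c: list(genome[c]) for c in genome}
    rows = []
    for rec in introns:
        s, e = rec.start, rec.end
        (ls, le), (rs, re_) = rec.left_exon, rec.right_exon
        gl_exon = (max(ls, s - width), s)
        gl_intron = (s, min(s + width, e))
        gr_intron = (max(e - width, s), e)
        gr_exon = (e, min(re_, e + width))
        if rec.strand == "+":
            windows = {"5p_exon": gl_exon, "5p_intron": gl_intron,
                       "3p_intron": gr_intron, "3p_exon": gr_exon}
        else:
            windows = {"5p_exon": gr_exon, "5p_intron": gr_intron,
                       "3p_intron": gl_intron, "3p_exon": gl_exon}
        a, b = windows[region_tag]
        rate = rate_ir if rec.intron_id in ir_intron_ids else rate_nr
        plant = bool(rng.random() < rate)
        span = (b - a) - len(consensus)
        if plant and span < 0:
            warnings.warn(f"{rec.intron_id}: region {region_tag} shorter than consensus; skipped")
            plant = False
        pos = -1
        if plant:
            off = int(rng.integers(0, span + 1))
            if rec.strand == "+":
                gpos = a + off
                insert = consensus
            else:
                # transcript-orientation offset measured from the region's 5' end,
                # which is the genomic right edge on the minus strand
                gpos = b - off - len(consensus)
                insert = reverse_complement(consensus)
            seqs[rec.chrom][gpos : gpos + len(consensus)] = list(insert)
            pos = off
        rows.append(
            {"intron_id": rec.intron_id, "region_tag": region_tag,
             "is_ir": rec.intron_id in ir_intron_ids, "planted": plant, "offset": pos}
        )
    new_genome = {c: "".join(seqs[c]) for c in seqs}
    return new_genome, pd.DataFrame(rows)
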