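"""RBP motif scanning around splice sites of retained vs non-retained introns.

Each splice site contributes two 50-nt flank regions (exonic and intronic
side), always in transcript orientation since RBP motifs bind RNA: minus-
strand windows are reverse-complemented and the region tags swapped. Motifs
are position weight matrices scored as log2 odds against an i.i.d.
background; the hit threshold is calibrated so that a random background
window exceeds it with probability at most ``p_target`` (the exact score
distribution is computed by dynamic programming over discretized scores).
Per-region hit frequencies of differentially retained (IR) vs non-retained
(NR) introns are compared with a two-sample pooled-variance t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import IntronRecord

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
REGION_TAGS = ("5p_exon", "5p_intron", "3p_intron", "3p_exon")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position weight matrix over A,C,G,T/U with an i.i.d. background model."""

    motif_id: str
    rbp_name: str
    matrix: np.ndarray  # L x 4 probabilities, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.background = np.asarray(self.background, float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be L x 4")
        # regularize: add pseudocount, renormalize rows
        self.matrix = self.matrix + self.pseudocount
        self.matrix /= self.matrix.sum(axis=1, keepdims=True)
        self.background = self.background / self.background.sum()

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """L x 4 log2(p / background) score matrix (-inf for impossible bases)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background)

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class FlankRegion:
    intron_id: str
    region_tag: str  # 5p_exon / 5p_intron / 3p_intron / 3p_exon
    sequence: str    # transcript orientation
    width: int
    truncated: bool = False


@dataclass
class RegionFreqResult:
    motif_id: str
    region_tag: str
    mean_freq_ir: float
    mean_freq_nr: float
    t_stat: float
    p: float
    degenerate: bool = False


def read_pwms(path: str, format: str = "meme") -> list[PWM]:
    """Load PWMs from a MEME minimal file or an ATtRACT-style tab file.

    The tab dialect is: a header line ``>motif_id<TAB>rbp_name`` followed by
    L whitespace-separated rows of four probabilities (A C G U/T order).
    Rows not summing to ~1 are renormalized with a warning; U equals T
    internally.
    """
    if format == "meme":
        return _read_meme_minimal(path)
    if format == "attract-tab":
        return _read_attract_tab(path)
    raise ValueError(f"unknown PWM format {format!r}")


def _read_meme_minimal(path: str) -> list[PWM]:
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    background = np.full(4, 0.25)
    bg = getattr(record, "background", None)
    if bg:
        background = np.array([bg.get(b, 0.25) for b in _ALPHABET], float)
    out = []
    for m in record:
        mat = np.array([[m.pwm[b][i] for b in _ALPHABET] for i in range(m.length)], float)
        name = m.name or ""
        out.append(PWM(motif_id=name, rbp_name=name, matrix=mat, background=background))
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


def _read_attract_tab(path: str) -> list[PWM]:
    import warnings

    out: list[PWM] = []
    motif_id = rbp = None
    rows: list[list[float]] = []

    def flush() -> None:
        if motif_id is None:
            return
        if not rows:
            raise ValueError(f"{path}: motif {motif_id} has no matrix rows")
        mat = np.array(rows, float)
        sums = mat.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-3):
            warnings.warn(f"{motif_id}: matrix rows not summing to 1; renormalizing")
            mat = mat / sums[:, None]
        out.append(PWM(motif_id=motif_id, rbp_name=rbp or motif_id, matrix=mat))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split("\t")
                motif_id = parts[0].strip()
                rbp = parts[1].strip() if len(parts) > 1 else motif_id
                rows = []
            else:
                vals = [float(x) for x in line.replace("\t", " ").split()]
                if len(vals) != 4:
                    raise ValueError(f"{path}: expected 4 probabilities per row, got {len(vals)}")
                rows.append(vals)
    flush()
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


def write_pwms_tab(pwms: Sequence[PWM], path: str) -> None:
    """Write PWMs in the ATtRACT-style tab dialect (lossless to ~1e-12)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\t{p.rbp_name}\n")
            for row in p.matrix:
                fh.write("\t".join(f"{v:.15g}" for v in row) + "\n")


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    """Substring [start, end) of a contig from a dict of strings or a pyfaidx.Fasta."""
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start:end].upper()
    return str(seq[start:end]).upper()


def extract_flanks(
    genome: Mapping[str, str], introns: Sequence[IntronRecord], width: int = 50
) -> list[FlankRegion]:
    """Four transcript-orientation flank regions per intron.

    5p_exon / 5p_intron sit at the donor splice site (last ``width`` nt of the
    upstream exon, first ``width`` nt of the intron); 3p_intron / 3p_exon at
    the acceptor. Windows are clipped at the flanking-exon and intron
    boundaries; clipped regions carry ``truncated=True``. Minus-strand
    sequences are reverse-complemented and the genomic windows mirrored.
    """
    out: list[FlankRegion] = []
    for rec in introns:
        s, e = rec.start, rec.end
        (ls, le), (rs, re_) = rec.left_exon, rec.right_exon
        # genomic windows, left-to-right
        gl_exon = (max(ls, s - width), s)
        gl_intron = (s, min(s + width, e))
        gr_intron = (max(e - width, s), e)
        gr_exon = (e, min(re_, e + width))
        if rec.strand == "+":
            layout = [("5p_exon", gl_exon), ("5p_intron", gl_intron),
                      ("3p_intron", gr_intron), ("3p_exon", gr_exon)]
        else:
            layout = [("5p_exon", gr_exon), ("5p_intron", gr_intron),
                      ("3p_intron", gl_intron), ("3p_exon", gl_exon)]
        for tag, (a, b) in layout:
            seq = _fetch(genome, rec.chrom, a, b)
            if rec.strand == "-":
                seq = reverse_complement(seq)
            out.append(
                FlankRegion(
                    intron_id=rec.intron_id,
                    region_tag=tag,
                    sequence=seq,
                    width=width,
                    truncated=len(seq) < width,
                )
            )
    return out


_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; N/U handled (U as T, N as 4)."""
    idx = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        if ch == "U":
            ch = "T"
        if ch == "N":
            idx[i] = 4
        elif ch in _BASE_INDEX:
            idx[i] = _BASE_INDEX[ch]
        else:
            raise ValueError(f"invalid character {ch!r} in sequence")
    return idx


def pwm_score(window: str, pwm: PWM) -> float:
    """Log2-odds score of one window of exactly the motif length; N scores 0."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != motif length {pwm.length}")
    lo = np.hstack([pwm.log_odds, np.zeros((pwm.length, 1))])  # column 4 = N
    idx = _encode(window)
    return float(lo[np.arange(pwm.length), idx].sum())


def score_distribution(pwm: PWM, bin_width: float = 0.01, max_bins: int = 2_000_000):
    """Exact distribution of the window score under the i.i.d. background.

    Scores are discretized by flooring to multiples of ``bin_width`` bits.
    Returns (offsets, probs): P(binned score == offsets[i]*bin_width) =
    probs[i]. Raises if the DP table would exceed ``max_bins`` entries.
    """
    scale = 1.0 / bin_width
    lo = pwm.log_odds
    if not np.isfinite(lo).all():
        raise ValueError("PWM has zero-probability entries; calibrate with a positive pseudocount")
    kmat = np.floor(lo * scale).astype(np.int64)
    span = int(kmat.max(axis=1).sum() - kmat.min(axis=1).sum()) + 1
    if span > max_bins:
        raise ValueError(f"DP table of {span} bins exceeds limit {max_bins}; use coarser bins")
    probs = np.array([1.0])
    offset = 0  # bin index of probs[0]
    for i in range(pwm.length):
        ks = kmat[i]
        kmin, kmax = int(ks.min()), int(ks.max())
        new = np.zeros(len(probs) + (kmax - kmin))
        for b in range(4):
            shift = int(ks[b]) - kmin
            new[shift : shift + len(probs)] += pwm.background[b] * probs
        probs = new
        offset += kmin
    offsets = offset + np.arange(len(probs))
    return offsets, probs


def score_threshold(pwm: PWM, p_target: float = 1e-4, bin_width: float = 0.01) -> float:
    """Smallest score s with P(window score >= s | background) <= p_target.

    Computed on the discretized exact distribution; the returned value is the
    lower edge of the selected score bin (hence conservative by at most one
    bin width).
    """
    if not (0 < p_target <= 1):
        raise ValueError("p_target must lie in (0, 1]")
    offsets, probs = score_distribution(pwm, bin_width)
    survival = np.cumsum(probs[::-1])[::-1]
    # smallest attainable (mass-bearing) score bin whose upper tail is small
    # enough; empty bins below it would satisfy the bound vacuously
    ok = (survival <= p_target) & (probs > 0)
    if not ok.any():
        # p_target below the atom at the maximum: no attainable score
        # qualifies, so return a threshold just above the maximum
        return float((offsets[-1] + 1) * bin_width)
    k = offsets[np.argmax(ok)]
    return float(k * bin_width)


def scan_region(region: FlankRegion | str, pwm: PWM, threshold: float) -> int:
    """Number of sense-strand windows (step 1) scoring at or above threshold."""
    seq = region.sequence if isinstance(region, FlankRegion) else region
    L = pwm.length
    if len(seq) < L:
        return 0
    idx = _encode(seq)
    lo = np.hstack([pwm.log_odds, np.zeros((L, 1))])
    pos_scores = lo[np.arange(L)[None, :], np.lib.stride_tricks.sliding_window_view(idx, L)]
    return int(np.count_nonzero(pos_scores.sum(axis=1) >= threshold))


def region_enrichment(
    hits_ir: Sequence[float], hits_nr: Sequence[float],
    motif_id: str = "", region_tag: str = "",
) -> RegionFreqResult:
    """Two-sample pooled-variance t test on per-sequence motif hit counts.

    Both groups constant and equal -> t=0, p=1. Both constant but different
    (pooled sd 0) -> reported as a maximally significant degenerate case
    (p=0) with the ``degenerate`` flag set.
    """
    a = np.asarray(hits_ir, float)
    b = np.asarray(hits_nr, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 sequences per group")
    pooled_var = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return RegionFreqResult(motif_id, region_tag, float(a.mean()), float(b.mean()), 0.0, 1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return RegionFreqResult(
            motif_id, region_tag, float(a.mean()), float(b.mean()), float(t), 0.0, degenerate=True
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return RegionFreqResult(motif_id, region_tag, float(a.mean()), float(b.mean()), float(t), float(p))


def motif_region_enrichment(
    genome: Mapping[str, str],
    introns: Sequence[IntronRecord],
    ir_intron_ids: set,
    pwms: Sequence[PWM],
    width: int = 50,
    p_target: float = 1e-4,
) -> pd.DataFrame:
    """Full scan: flank extraction, threshold calibration, per-region t tests.

    Returns one row per (motif, region) with group means, t, p and BH q.
    """
    from .diffir import bh_adjust

    flanks = extract_flanks(genome, introns, width=width)
    by_region: dict[str, list[FlankRegion]] = {tag: [] for tag in REGION_TAGS}
    for fl in flanks:
        by_region[fl.region_tag].append(fl)
    rows = []
    for pwm in pwms:
        thr = score_threshold(pwm, p_target=p_target)
        for tag in REGION_TAGS:
            regions = by_region[tag]
            hits_ir = [scan_region(fl, pwm, thr) for fl in regions if fl.intron_id in ir_intron_ids]
            hits_nr = [scan_region(fl, pwm, thr) for fl in regions if fl.intron_id not in ir_intron_ids]
            res = region_enrichment(hits_ir, hits_nr, pwm.motif_id, tag)
            rows.append(
                {
                    "motif_id": pwm.motif_id,
                    "rbp": pwm.rbp_name,
                    "region": tag,
                    "mean_ir": res.mean_freq_ir,
                    "mean_nr": res.mean_freq_nr,
                    "t": res.t_stat,
                    "p": res.p,
                    "degenerate": res.degenerate,
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
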