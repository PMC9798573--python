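import pandas as pd
import pytest

from irkit.filters import CohortMatrix


def write_sam(path, contig_lengths, reads):
    """Minimal text SAM writer for hand-built fixtures.

    ``reads``: iterables of (qname, flag, chrom, pos0, cigar).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, ln in contig_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{ln}\n")
        for qname, flag, chrom, pos0, cigar in reads:
            fh.write(f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t*\t*\n")
    return path


SAMPLES = ["N1", "N2", "N3", "N4", "C1", "C2", "C3", "C4"]
GROUPS = pd.Series(["normal"] * 4 + ["cancer"] * 4, index=SAMPLES, name="group")


@pytest.fixture
def filter_fixture():
    """Six introns x eight samples exercising every filter boundary by hand.

    Expected flags derive from manual application of the four rules:
    balance window [0.7, 1.3] inclusive in >=50% of samples, (SL+SR)>10
    strict in >=50%, coverage>0.5 strict in >=50%, ir>0.05 strict in >=50%
    of at least one group; events need pass_all and ir>0.1 strict.
    """
    introns = [f"I{i}" for i in range(1, 7)]

    def grid(rows):
        return pd.DataFrame(rows, index=introns, columns=SAMPLES, dtype=float)

    SL = grid([
        [10] * 8,                      # I1
        [7, 7, 10, 10, 7, 7, 10, 10],  # I2: ratio 0.7 in N1,N2,C1,C2
        [6, 6, 3, 3, 6, 6, 3, 3],      # I3: sum 11 in half the samples
        [8] * 8,                       # I4
        [10] * 8,                      # I5
        [10] * 8,                      # I6
    ])
    SR = grid([
        [10] * 8,
        [10, 10, 7, 7, 10, 10, 7, 7],
        [5, 5, 2, 2, 5, 5, 2, 2],
        [8] * 8,
        [10] * 8,
        [10] * 8,
    ])
    coverage = grid([
        [0.9] * 8,
        [0.6] * 8,
        [0.4] * 8,
        [0.6, 0.6, 0.6, 0.5, 0.5, 0.5, 0.5, 0.5],  # I4: >0.5 in only 3/8
        [0.8] * 8,
        [0.8] * 8,
    ])
    ir = grid([
        [0.2] * 7 + [0.1],                                   # I1: C4 at the 0.1 boundary
        [0.06, 0.06, 0.06, 0.06, 0.01, 0.01, 0.01, 0.01],    # I2: floor via normals
        [0.2] * 8,
        [0.15] * 8,
        [0.05] * 8,                                          # I5: at the floor, strict fail
        [0.2, 0.2, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01],      # I6: floor via 2/4 normals
    ])
    zeros = grid([[0] * 8] * 6)
    cohort = CohortMatrix(
        {"ID": zeros, "coverage": coverage, "SL": SL, "SR": SR, "SE": zeros, "ir_ratio": ir},
        GROUPS,
    )
    expected_mask = pd.DataFrame(
        {
            "pass_balance": [True] * 6,
            "pass_junction_support": [True, True, True, True, True, True],
            "pass_coverage": [True, True, False, False, True, True],
            "pass_ir_floor": [True, True, True, True, False, True],
        },
        index=pd.Index(introns, name="intron_id"),
    )
    expected_mask["pass_all"] = expected_mask.all(axis=1)
    expected_events = pd.Series(
        [2, 2, 1, 1, 1, 1, 1, 0], index=SAMPLES, name="n_ir_events"
    )
    return cohort, expected_mask, expected_events
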