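"""Shared construction helpers for the test suite."""

import numpy as np

from hetdissect.ld_panel import HaplotypePanel
from hetdissect.summary_io import SummaryRecord


def panel_from(columns: dict[str, list[int]], positions=None, chroms=None):
    """Build a panel from named 0/1 haplotype columns (alleles G->A)."""
    names = list(columns)
    mat = np.array([columns[m] for m in names], dtype=np.uint8).T
    return HaplotypePanel(
        marker_ids=names,
        chroms=chroms or ["1"] * len(names),
        positions=np.asarray(positions or [100 * (k + 1) for k in range(len(names))]),
        alleles=[("G", "A")] * len(names),
        haplotypes=mat,
    )


def rec(marker, pos, p=1e-9, chrom="1"):
    """A harmonized summary record at a position."""
    return SummaryRecord(
        marker, "A", "G", p, 1, 1000, freq=0.5, chrom=chrom, pos=pos
    )
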