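"""Clustering significant SNPs into loci by physical adjacency.

Significant SNPs (p < alpha) on the same chromosome are chained into one
locus whenever consecutive SNPs lie within a window length L of each other
(single linkage on positions).  Chaining, rather than distance-to-lead,
lets a locus span several megabases when dense significant SNPs bridge the
gaps — the behaviour observed at strongly associated regions.

The default window length shrinks as the significance level is relaxed,
because relaxing alpha sharply increases the density of significant SNPs:

====== ==========
alpha  window (kb)
====== ==========
5e-8   500
5e-7   400
5e-6   300
5e-5   200
5e-4   100
5e-3   50
====== ==========
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import DomainError, InputError
from .summary_io import SummaryRecord

log = logging.getLogger(__name__)

#: significance level -> adjacency window length in kb
WINDOW_TABLE_KB: dict[float, float] = {
    5e-8: 500.0,
    5e-7: 400.0,
    5e-6: 300.0,
    5e-5: 200.0,
    5e-4: 100.0,
    5e-3: 50.0,
}


@dataclass
class Locus:
    """A cluster of significant SNPs on one chromosome.

    ``members`` are ordered by position; ``lead`` is the member with the
    smallest p (ties broken by smaller position, then marker id).
    """

    locus_id: str
    chrom: str
    members: list[SummaryRecord]
    lead: str
    span: tuple[int, int]

    @property
    def n_snps(self) -> int:
        return len(self.members)

    @property
    def lead_record(self) -> SummaryRecord:
        return next(m for m in self.members if m.marker_id == self.lead)


def default_window(alpha: float) -> float:
    """Window length (kb) for a significance level.

    Levels listed in :data:`WINDOW_TABLE_KB` map directly; any other alpha
    maps to the nearest listed level on the log10 scale (ties go to the
    more stringent level, i.e. the larger window).
    """
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0,1), got {alpha}")
    if alpha in WINDOW_TABLE_KB:
        return WINDOW_TABLE_KB[alpha]
    la = math.log10(alpha)
    best = min(WINDOW_TABLE_KB, key=lambda lv: (abs(math.log10(lv) - la), lv))
    return WINDOW_TABLE_KB[best]


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def cluster_loci(
    records: list[SummaryRecord],
    alpha: float,
    window_kb: float | None = None,
) -> list[Locus]:
    """Cluster harmonized records with p < alpha into loci.

    ``window_kb`` defaults to :func:`default_window`; a gap exactly equal
    to the window still joins.  Output is sorted by chromosome then span
    start, with locus ids assigned in that order.
    """
    if window_kb is None:
        window_kb = default_window(alpha)
    if window_kb <= 0:
        raise DomainError(f"window_kb must be positive, got {window_kb}")
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must be in (0,1), got {alpha}")
    window_bp = int(round(window_kb * 1000))

    sig = [r for r in records if r.p < alpha]
    if any(r.chrom is None or r.pos is None for r in sig):
        raise InputError("records must be harmonized (chrom/pos set) before clustering")

    by_chrom: dict[str, list[SummaryRecord]] = {}
    for r in sig:
        by_chrom.setdefault(r.chrom, []).append(r)

    loci: list[Locus] = []
    for chrom in sorted(by_chrom, key=_chrom_key):
        members = sorted(by_chrom[chrom], key=lambda r: (r.pos, r.marker_id))
        start = 0
        for k in range(1, len(members) + 1):
            if k == len(members) or members[k].pos - members[k - 1].pos > window_bp:
                chunk = members[start:k]
                lead = min(chunk, key=lambda r: (r.p, r.pos, r.marker_id))
                loci.append(
                    Locus(
                        locus_id="",
                        chrom=chrom,
                        members=chunk,
                        lead=lead.marker_id,
                        span=(chunk[0].pos, chunk[-1].pos),
                    )
                )
                start = k
    loci.sort(key=lambda lc: (_chrom_key(lc.chrom), lc.span[0]))
    for i, lc in enumerate(loci, start=1):
        lc.locus_id = f"L{i:04d}"
    log.info(
        "clustered %d significant SNPs (p<%g) into %d loci (window %g kb)",
        len(sig), alpha, len(loci), window_kb,
    )
    return loci


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [lc.locus_id for lc in loci],
            "chrom": [lc.chrom for lc in loci],
            "start": [lc.span[0] for lc in loci],
            "end": [lc.span[1] for lc in loci],
            "n_snps": [lc.n_snps for lc in loci],
            "lead_marker": [lc.lead for lc in loci],
            "lead_p": [lc.lead_record.p for lc in loci],
        }
    )


def loci_to_tsv(loci: list[Locus], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        loci_to_frame(loci).to_csv(fh, sep="\t", index=False)


def loci_to_bed(loci: list[Locus], path: str | Path) -> None:
    """Write spans as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for lc in loci:
            fh.write(f"{lc.chrom}\t{lc.span[0] - 1}\t{lc.span[1]}\t{lc.locus_id}\n")
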