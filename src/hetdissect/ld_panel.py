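"""Phased haplotype reference panels: allele frequencies and pairwise LD.

A :class:`HaplotypePanel` stores a binary haplotype matrix (rows =
haplotypes, columns = biallelic SNPs) in which ``1`` means the panel's
*effect-orientation* allele is present.  For VCF input that allele is ALT;
for the HapMap Phase 2 legend/phased dialect it is the legend's second
allele column.  All frequencies and LD coefficients used downstream are
computed from this matrix, matching the practice of taking f and D from an
external phased reference panel rather than from the association study
itself.

The LD coefficient D is the haplotype-frequency covariance
``D = p_11 - f_i * f_j`` and ``r^2 = D^2 / (f_i (1-f_i) f_j (1-f_j))``.
Under Hardy-Weinberg equilibrium the genotype (dosage) covariance between
two linked SNPs is ``2D`` and the dosage variance is ``2 f (1-f)``; the
conditional-analysis core relies on that correspondence.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DomainError, InputError, PanelLookupError

log = logging.getLogger(__name__)

#: pairs farther apart than this return D = 0 with the out_of_window flag
DEFAULT_MAX_DISTANCE_BP = 5_000_000

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class PairLD:
    """Pairwise linkage disequilibrium between two panel SNPs.

    ``d`` is signed relative to the effect-orientation alleles of both
    markers; ``f_i``/``f_j`` are their panel allele frequencies.
    ``out_of_window`` marks pairs beyond the maximum LD distance, for which
    d and r2 are reported as 0 by construction.
    """

    d: float
    r2: float
    f_i: float
    f_j: float
    out_of_window: bool = False


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom`` or ``chrom:start-end`` (1-based, closed) strings."""
    m = re.fullmatch(r"([^:]+)(?::(\d+)-(\d+))?", region.strip())
    if not m:
        raise DomainError(f"malformed region string: {region!r}")
    chrom = m.group(1)
    if m.group(2) is None:
        return chrom, 1, 2**62
    start, end = int(m.group(2)), int(m.group(3))
    if start > end:
        raise DomainError(f"region start exceeds end: {region!r}")
    return chrom, start, end


@dataclass
class HaplotypePanel:
    """Ordered biallelic SNPs plus a (n_haplotypes x n_variants) 0/1 matrix."""

    marker_ids: list[str]
    chroms: list[str]
    positions: np.ndarray  # int64, 1-based
    alleles: list[tuple[str, str]]  # (other, effect) per marker
    haplotypes: np.ndarray  # uint8, shape (n_hap, n_variants)
    n_dropped_monomorphic: int = 0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.marker_ids):
            raise InputError("haplotype matrix shape does not match variant list")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise InputError("haplotype matrix entries must be 0/1")
        # positions must be non-decreasing within each chromosome
        for chrom in set(self.chroms):
            idx = [k for k, c in enumerate(self.chroms) if c == chrom]
            pos = self.positions[idx]
            if np.any(np.diff(pos) < 0):
                raise InputError(f"positions not sorted on chromosome {chrom}")
        self._index = {m: k for k, m in enumerate(self.marker_ids)}
        if len(self._index) != len(self.marker_ids):
            raise InputError("duplicate marker ids in panel")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._index

    def column(self, marker_id: str) -> np.ndarray:
        try:
            return self.haplotypes[:, self._index[marker_id]]
        except KeyError:
            raise PanelLookupError(f"marker not in panel: {marker_id}") from None

    def variant_info(self, marker_id: str) -> tuple[str, int, str, str]:
        """Return (chrom, pos, other_allele, effect_allele)."""
        try:
            k = self._index[marker_id]
        except KeyError:
            raise PanelLookupError(f"marker not in panel: {marker_id}") from None
        other, effect = self.alleles[k]
        return self.chroms[k], int(self.positions[k]), other, effect

    # -- statistics --------------------------------------------------------

    def allele_freq(self, marker_id: str) -> float:
        """Effect-orientation allele frequency: the haplotype column mean."""
        return float(self.column(marker_id).mean())

    def pair_ld(
        self,
        marker_i: str,
        marker_j: str,
        max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
        cross_chrom: str = "error",
    ) -> PairLD:
        """LD between two panel markers on the same chromosome.

        Parameters
        ----------
        cross_chrom:
            ``"error"`` raises for markers on different chromosomes;
            ``"zero"`` opts in to treating their LD as 0.
        """
        ki, kj = self._index.get(marker_i), self._index.get(marker_j)
        if ki is None or kj is None:
            missing = marker_i if ki is None else marker_j
            raise PanelLookupError(f"marker not in panel: {missing}")
        ci, cj = self.column(marker_i), self.column(marker_j)
        f_i, f_j = float(ci.mean()), float(cj.mean())
        if self.chroms[ki] != self.chroms[kj]:
            if cross_chrom == "zero":
                return PairLD(0.0, 0.0, f_i, f_j, out_of_window=True)
            raise DomainError(
                f"markers on different chromosomes: {marker_i} "
                f"({self.chroms[ki]}) vs {marker_j} ({self.chroms[kj]})"
            )
        if abs(int(self.positions[ki]) - int(self.positions[kj])) > max_distance_bp:
            return PairLD(0.0, 0.0, f_i, f_j, out_of_window=True)
        p11 = float(np.mean(ci & cj))
        d = p11 - f_i * f_j
        denom = f_i * (1.0 - f_i) * f_j * (1.0 - f_j)
        r2 = (d * d / denom) if denom > 0 else 0.0
        return PairLD(d, min(r2, 1.0), f_i, f_j)


# -- loading ---------------------------------------------------------------


def load_panel(
    path: str | Path,
    fmt: str = "vcf",
    region: str | None = None,
    chrom: str | None = None,
) -> HaplotypePanel:
    """Load a phased panel from VCF or the HapMap Phase 2 text dialect.

    ``fmt="vcf"`` reads phased diploid GT fields (ALT is the
    effect-orientation allele).  ``fmt="hapmap_phased"`` expects three files
    sharing a prefix: ``<prefix>_legend.txt``, ``<prefix>_phased`` and
    ``<prefix>_sample.txt`` (the legend's second allele column is the
    effect-orientation allele; ``chrom`` names the chromosome the files
    cover, defaulting to the region's chromosome or "1").  Monomorphic
    columns are dropped and counted.
    """
    if fmt == "vcf":
        panel = _load_vcf(Path(path), region)
    elif fmt == "hapmap_phased":
        panel = _load_hapmap(Path(path), region, chrom)
    else:
        raise DomainError(f"unknown panel format: {fmt!r}")
    log.info(
        "panel loaded: %d variants, %d haplotypes, %d monomorphic dropped",
        panel.n_variants, panel.n_haplotypes, panel.n_dropped_monomorphic,
    )
    return panel


def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and ref in _VALID_BASES
        and alts[0] in _VALID_BASES
        and ref != alts[0]
    )


def _load_vcf(path: Path, region: str | None) -> HaplotypePanel:
    from cyvcf2 import VCF

    if not path.exists():
        raise InputError(f"panel file not found: {path}")
    want = parse_region(region) if region else None

    marker_ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    alleles: list[tuple[str, str]] = []
    columns: list[np.ndarray] = []
    n_mono = 0

    vcf = VCF(str(path))
    for v in vcf:
        if want is not None:
            c, s, e = want
            if v.CHROM != c or not (s <= v.POS <= e):
                continue
        if not _is_biallelic_snp(v.REF, v.ALT):
            continue
        col = []
        for g in v.genotypes:  # [allele_a, allele_b, phased]
            if len(g) != 3:
                raise InputError(
                    f"non-diploid genotype at {v.CHROM}:{v.POS} ({v.ID})"
                )
            a, b, phased = g
            if a < 0 or b < 0:
                raise InputError(
                    f"missing allele in panel at {v.CHROM}:{v.POS} ({v.ID})"
                )
            if not phased:
                raise InputError(
                    f"unphased genotype at {v.CHROM}:{v.POS} ({v.ID})"
                )
            col.extend((a, b))
        arr = np.asarray(col, dtype=np.uint8)
        if arr.min() == arr.max():
            n_mono += 1
            continue
        marker_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        positions.append(v.POS)
        alleles.append((v.REF, v.ALT[0]))
        columns.append(arr)
    vcf.close()

    if not columns:
        raise InputError(f"no biallelic SNPs loaded from {path} (region={region})")
    return HaplotypePanel(
        marker_ids, chroms, np.asarray(positions), alleles,
        np.column_stack(columns), n_dropped_monomorphic=n_mono,
    )


def _open_text(path: Path):
    gz = path.with_name(path.name + ".gz")
    if path.exists():
        return open(path, "rt")
    if gz.exists():
        return gzip.open(gz, "rt")
    raise InputError(f"panel file not found: {path}")


def _load_hapmap(prefix: Path, region: str | None, chrom: str | None) -> HaplotypePanel:
    legend_path = prefix.with_name(prefix.name + "_legend.txt")
    phased_path = prefix.with_name(prefix.name + "_phased")
    sample_path = prefix.with_name(prefix.name + "_sample.txt")

    want = parse_region(region) if region else None
    if chrom is None:
        chrom = want[0] if want else "1"

    with _open_text(legend_path) as fh:
        header = fh.readline()
        if not header.strip():
            raise InputError(f"empty legend file: {legend_path}")
        legend = []
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                raise InputError(f"malformed legend line: {line.strip()!r}")
            legend.append((parts[0], int(parts[1]), parts[2], parts[3]))

    with _open_text(phased_path) as fh:
        rows = []
        for line in fh:
            vals = line.split()
            if not vals:
                continue
            if len(vals) != len(legend):
                raise InputError(
                    f"phased row has {len(vals)} entries, legend has "
                    f"{len(legend)} markers"
                )
            rows.append(np.asarray(vals, dtype=np.uint8))
    if not rows:
        raise InputError(f"empty phased file: {phased_path}")
    hap = np.vstack(rows)

    if sample_path.exists() or sample_path.with_name(sample_path.name + ".gz").exists():
        with _open_text(sample_path) as fh:
            samples = [ln.split()[0] for ln in fh if ln.strip()]
        if samples and hap.shape[0] != 2 * len(samples):
            raise InputError(
                f"{hap.shape[0]} haplotypes but {len(samples)} samples "
                f"in {sample_path}"
            )

    keep, n_mono = [], 0
    for k, (_, pos, a0, a1) in enumerate(legend):
        if want is not None and not (want[1] <= pos <= want[2]):
            continue
        if a0 not in _VALID_BASES or a1 not in _VALID_BASES or a0 == a1:
            continue
        col = hap[:, k]
        if col.min() == col.max():
            n_mono += 1
            continue
        keep.append(k)
    if not keep:
        raise InputError(f"no polymorphic SNPs loaded from {prefix} (region={region})")

    return HaplotypePanel(
        [legend[k][0] for k in keep],
        [chrom] * len(keep),
        np.asarray([legend[k][1] for k in keep]),
        [(legend[k][2], legend[k][3]) for k in keep],
        hap[:, keep],
        n_dropped_monomorphic=n_mono,
    )
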