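"""Reading and harmonizing GWAS summary statistics.

Summary files carry, per SNP, a marker id, the two alleles, a two-sided
p-value, a direction of effect and the number of observations N; an
effect-allele frequency column is optional.  Positions and frequencies are
deliberately NOT trusted from the summary file: after marker-id matching
they are always taken from the LD reference panel, which is also the source
of every LD coefficient used downstream.

Column layouts differ between consortia, so the reader is driven by a
:class:`ColumnMap`; the ``"giant"`` preset covers the whitespace-delimited
MarkerName/Allele1/Allele2/Direction/p/N dialect distributed for the large
height meta-analysis.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .ld_panel import HaplotypePanel

log = logging.getLogger(__name__)

_TINY = float(np.finfo(np.float64).tiny)
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_BASES = frozenset("ACGT")
# a p-value string that underflowed to 0.0 but carries a nonzero digit
_NONZERO_DIGITS = re.compile(r"[1-9]")


@dataclass
class SummaryRecord:
    """One SNP's association summary.

    ``direction`` is +1/-1; ``n_obs`` is the meta-analysis N.  ``chrom``,
    ``pos`` and ``freq`` are unset until :func:`harmonize` fills them from
    the panel, after which ``effect_allele`` is guaranteed to be the panel's
    effect-orientation allele (direction is flipped when alleles had to be
    swapped).
    """

    marker_id: str
    effect_allele: str
    other_allele: str
    p: float
    direction: int
    n_obs: int
    freq: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p must be in (0,1], got {self.p}")
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +1/-1, got {self.direction}")
        if self.n_obs < 1:
            raise ValueError(f"n_obs must be >= 1, got {self.n_obs}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"alleles must differ at {self.marker_id}")


@dataclass(frozen=True)
class ColumnMap:
    """Maps column roles to header names; ``freq`` may be absent."""

    marker: str
    effect_allele: str
    other_allele: str
    p: str
    direction: str
    n: str
    freq: str | None = None


PRESETS: dict[str, ColumnMap] = {
    "giant": ColumnMap(
        marker="MarkerName",
        effect_allele="Allele1",
        other_allele="Allele2",
        p="p",
        direction="Direction",
        n="N",
        freq="Freq.Allele1",
    ),
}


def _parse_direction(value) -> int | None:
    s = str(value).strip()
    if s in {"+", "+1", "1"}:
        return 1
    if s in {"-", "−", "–", "-1"}:
        return -1
    try:
        x = float(s)
    except ValueError:
        return None
    if x > 0:
        return 1
    if x < 0:
        return -1
    return None


def _parse_p(raw) -> float | None:
    s = str(raw).strip()
    try:
        p = float(s)
    except ValueError:
        return None
    if p > 1.0 or p < 0.0:
        return None
    if p == 0.0:
        # "1e-400" underflows to 0.0 in double precision: clamp such values
        # to the smallest positive normal; a literal zero is a domain error.
        if _NONZERO_DIGITS.search(s.split("e")[0].split("E")[0]):
            log.warning("p-value %s underflows double precision; clamped to %g", s, _TINY)
            return _TINY
        return None
    if p < _TINY:
        log.warning("p-value %g below %g; clamped", p, _TINY)
        return _TINY
    return p


def read_summary(
    path: str | Path,
    column_map: ColumnMap | str = "giant",
) -> tuple[list[SummaryRecord], int]:
    """Read a whitespace/tab-delimited summary file (optionally gzipped).

    Returns the parsed records and the number of rows skipped because a
    mandatory field was missing or outside its domain.
    """
    if isinstance(column_map, str):
        try:
            column_map = PRESETS[column_map]
        except KeyError:
            raise ConfigError(f"unknown column-map preset: {column_map!r}") from None
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary file not found: {path}")

    df = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    if df.empty:
        raise InputError(f"summary file has no data rows: {path}")

    roles = {
        "marker": column_map.marker,
        "effect_allele": column_map.effect_allele,
        "other_allele": column_map.other_allele,
        "p": column_map.p,
        "direction": column_map.direction,
        "n": column_map.n,
    }
    for role, col in roles.items():
        if col not in df.columns:
            raise ConfigError(
                f"summary file {path} lacks column {col!r} for role {role!r}"
            )
    has_freq = column_map.freq is not None and column_map.freq in df.columns

    records: list[SummaryRecord] = []
    skipped = 0
    freq_col = df[column_map.freq] if has_freq else None
    for i in range(len(df)):
        row = {col: df.at[i, col] for col in roles.values()}
        try:
            marker = str(row[column_map.marker]).strip()
            ea = str(row[column_map.effect_allele]).strip().upper()
            oa = str(row[column_map.other_allele]).strip().upper()
            p = _parse_p(row[column_map.p])
            direction = _parse_direction(row[column_map.direction])
            n_obs = int(float(row[column_map.n]))
            if (
                not marker or marker.lower() == "nan"
                or ea not in _VALID_BASES or oa not in _VALID_BASES or ea == oa
                or p is None or direction is None or n_obs < 1
            ):
                skipped += 1
                continue
            freq = None
            if freq_col is not None:
                try:
                    f = float(freq_col.iat[i])
                    if 0.0 < f < 1.0:
                        freq = f
                except (TypeError, ValueError):
                    freq = None
            records.append(
                SummaryRecord(marker, ea, oa, p, direction, n_obs, freq=freq)
            )
        except (KeyError, TypeError, ValueError):
            skipped += 1
    log.info("read %d summary records from %s (%d rows skipped)", len(records), path, skipped)
    return records, skipped


@dataclass
class HarmonizeReport:
    """Disposition counts; the five categories partition the input."""

    n_input: int = 0
    matched: int = 0
    flipped: int = 0
    complemented: int = 0
    dropped_ambiguous: int = 0
    unmatched: int = 0

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [dataclasses.asdict(self)]
        ).to_csv(path, sep="\t", index=False)

    def log_lines(self) -> list[str]:
        return [
            f"harmonize: {self.n_input} records in",
            f"  matched (same orientation): {self.matched}",
            f"  flipped (alleles swapped, direction negated): {self.flipped}",
            f"  complemented (opposite strand): {self.complemented}",
            f"  dropped strand-ambiguous (A/T, C/G): {self.dropped_ambiguous}",
            f"  unmatched (absent from panel): {self.unmatched}",
        ]


def harmonize(
    records: list[SummaryRecord],
    panel: HaplotypePanel,
    drop_ambiguous: bool = True,
) -> tuple[list[SummaryRecord], HarmonizeReport]:
    """Align summary records to the panel's effect-allele orientation.

    Markers absent from the panel are dropped (counted ``unmatched``).
    Matching tries, in order: same orientation, swapped alleles (direction
    negated), strand complement of either.  Strand-ambiguous A/T and C/G
    SNPs are removed when ``drop_ambiguous`` because a strand flip is
    indistinguishable from an allele swap for them.  Chrom, pos and freq
    are always overwritten from the panel.
    """
    report = HarmonizeReport(n_input=len(records))
    out: list[SummaryRecord] = []
    for rec in records:
        if rec.marker_id not in panel:
            report.unmatched += 1
            continue
        ea, oa = rec.effect_allele, rec.other_allele
        if drop_ambiguous and _COMPLEMENT[ea] == oa:
            report.dropped_ambiguous += 1
            continue
        chrom, pos, p_other, p_effect = panel.variant_info(rec.marker_id)
        freq = panel.allele_freq(rec.marker_id)

        if (ea, oa) == (p_effect, p_other):
            report.matched += 1
            new = dataclasses.replace(rec, chrom=chrom, pos=pos, freq=freq)
        elif (ea, oa) == (p_other, p_effect):
            report.flipped += 1
            new = dataclasses.replace(
                rec,
                effect_allele=p_effect,
                other_allele=p_other,
                direction=-rec.direction,
                chrom=chrom,
                pos=pos,
                freq=freq,
            )
        else:
            cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
            if (cea, coa) == (p_effect, p_other):
                report.complemented += 1
                new = dataclasses.replace(
                    rec,
                    effect_allele=p_effect,
                    other_allele=p_other,
                    chrom=chrom,
                    pos=pos,
                    freq=freq,
                )
            elif (cea, coa) == (p_other, p_effect):
                report.complemented += 1
                new = dataclasses.replace(
                    rec,
                    effect_allele=p_effect,
                    other_allele=p_other,
                    direction=-rec.direction,
                    chrom=chrom,
                    pos=pos,
                    freq=freq,
                )
            else:
                report.unmatched += 1
                continue
        out.append(new)

    if not out:
        raise InputError("no summary records could be matched to the panel")
    for line in report.log_lines():
        log.info(line)
    return out, report
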