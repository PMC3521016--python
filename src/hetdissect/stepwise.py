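"""Per-locus stepwise extraction of primary and conditional signals.

At each locus the lead SNP (smallest marginal p) is the primary signal.
Every later round computes, for each non-selected member, the conditional
effect after subtracting the LD-projected contributions of all selected
signals (each projecting with its *assigned* effect: marginal for the
primary, conditional for later ranks — a sequential-residual scheme that
considers LD one pair of SNPs at a time rather than re-solving a joint
model).  The member with the smallest conditional p is accepted as the
next signal if that p falls below the per-locus Bonferroni cutoff
0.05 / m, with m the number of clustered SNPs at the locus; otherwise the
locus is finished.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .conditional import (
    EffectEstimate,
    conditional_effect,
    conditional_p,
    effect_from_summary,
    projected_effect,
    z_from_p,
)
from .errors import DomainError
from .ld_panel import HaplotypePanel
from .locus_cluster import Locus
from .summary_io import SummaryRecord

log = logging.getLogger(__name__)

DEFAULT_MAX_RANK = 4  # primary through quaternary
DEFAULT_BONFERRONI_BASE = 0.05
#: candidates in near-perfect LD with a selected signal are skipped
R2_GUARD = 0.99


@dataclass
class Signal:
    """A selected SNP at a locus.

    ``rank`` 1 is the primary (lead) signal with its marginal effect and
    marginal p; ranks >= 2 carry conditional effects and the conditional p
    that selected them.  ``threshold`` is the Bonferroni cutoff applied
    (None for the primary, which is selected by the clustering alpha).
    """

    locus_id: str
    marker_id: str
    rank: int
    effect: EffectEstimate
    cond_p: float
    threshold: float | None
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str


def _marginal(rec: SummaryRecord, panel: HaplotypePanel) -> EffectEstimate:
    f = rec.freq if rec.freq is not None else panel.allele_freq(rec.marker_id)
    return effect_from_summary(z_from_p(rec.p, rec.direction), f, rec.n_obs)


def dissect_locus(
    locus: Locus,
    panel: HaplotypePanel,
    max_rank: int = DEFAULT_MAX_RANK,
    bonferroni_base: float = DEFAULT_BONFERRONI_BASE,
    conditioning: str = "assigned",
) -> list[Signal]:
    """Extract up to ``max_rank`` signals from one locus.

    ``conditioning="assigned"`` projects each selected signal with its
    assigned effect (marginal for rank 1, conditional for later ranks);
    ``"marginal"`` projects every selected signal with its marginal effect
    instead.
    """
    if max_rank < 1:
        raise DomainError(f"max_rank must be >= 1, got {max_rank}")
    if conditioning not in ("assigned", "marginal"):
        raise DomainError(f"unknown conditioning mode: {conditioning!r}")
    if not locus.members:
        raise DomainError(f"locus {locus.locus_id} has no members")

    members = []
    for rec in locus.members:
        if rec.marker_id in panel:
            members.append(rec)
        else:
            warnings.warn(
                f"locus {locus.locus_id}: member {rec.marker_id} absent from "
                f"panel; excluded from candidacy",
                stacklevel=2,
            )
    if not members:
        raise DomainError(f"locus {locus.locus_id}: no members present in panel")

    m = locus.n_snps  # Bonferroni denominator: clustered SNPs at the locus
    threshold = bonferroni_base / m
    by_id = {r.marker_id: r for r in members}
    marginals = {r.marker_id: _marginal(r, panel) for r in members}

    lead = by_id.get(locus.lead)
    if lead is None:  # lead dropped for panel absence: re-derive
        lead = min(members, key=lambda r: (r.p, r.pos, r.marker_id))
    signals = [
        Signal(
            locus_id=locus.locus_id,
            marker_id=lead.marker_id,
            rank=1,
            effect=marginals[lead.marker_id],
            cond_p=lead.p,
            threshold=None,
            chrom=lead.chrom,
            pos=lead.pos,
            effect_allele=lead.effect_allele,
            other_allele=lead.other_allele,
        )
    ]
    selected = {lead.marker_id}

    while len(signals) < min(max_rank, len(members)):
        best: tuple[float, int, str] | None = None
        best_est: EffectEstimate | None = None
        for rec in members:
            t = rec.marker_id
            if t in selected:
                continue
            lds = [panel.pair_ld(sig.marker_id, t) for sig in signals]
            if any(ld.r2 > R2_GUARD for ld in lds):
                continue
            projections = []
            for sig, ld in zip(signals, lds):
                beta_src = (
                    sig.effect.beta
                    if conditioning == "assigned"
                    else marginals[sig.marker_id].beta
                )
                projections.append(projected_effect(beta_src, ld))
            est = conditional_effect(marginals[t], projections)
            p = conditional_p(est)
            key = (p, rec.pos, t)
            if best is None or key < best:
                best, best_est = key, est
        if best is None or best[0] >= threshold:
            break
        p, _, t = best
        rec = by_id[t]
        signals.append(
            Signal(
                locus_id=locus.locus_id,
                marker_id=t,
                rank=len(signals) + 1,
                effect=best_est,
                cond_p=p,
                threshold=threshold,
                chrom=rec.chrom,
                pos=rec.pos,
                effect_allele=rec.effect_allele,
                other_allele=rec.other_allele,
            )
        )
        selected.add(t)
    return signals


def dissect_all(
    loci: list[Locus],
    panel: HaplotypePanel,
    max_rank: int = DEFAULT_MAX_RANK,
    bonferroni_base: float = DEFAULT_BONFERRONI_BASE,
    conditioning: str = "assigned",
) -> tuple[list[Signal], dict]:
    """Dissect every locus; summarize the extent of allelic heterogeneity.

    The summary counts loci with secondary (>=2 signals) and tertiary
    (>=3) signals, with percentages over all loci.
    """
    signals: list[Signal] = []
    n_secondary = n_tertiary = 0
    for locus in loci:
        sigs = dissect_locus(
            locus, panel, max_rank=max_rank,
            bonferroni_base=bonferroni_base, conditioning=conditioning,
        )
        signals.extend(sigs)
        if len(sigs) >= 2:
            n_secondary += 1
        if len(sigs) >= 3:
            n_tertiary += 1
    n_loci = len(loci)
    summary = {
        "n_loci": n_loci,
        "n_with_secondary": n_secondary,
        "pct_with_secondary": 100.0 * n_secondary / n_loci if n_loci else 0.0,
        "n_with_tertiary": n_tertiary,
        "pct_with_tertiary": 100.0 * n_tertiary / n_loci if n_loci else 0.0,
        "n_signals": len(signals),
    }
    log.info(
        "dissected %d loci: %d (%.1f%%) with secondary, %d (%.1f%%) with tertiary",
        n_loci, n_secondary, summary["pct_with_secondary"],
        n_tertiary, summary["pct_with_tertiary"],
    )
    return signals, summary


# -- serialization ---------------------------------------------------------


def signals_to_frame(signals: list[Signal]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [s.locus_id for s in signals],
            "rank": [s.rank for s in signals],
            "marker_id": [s.marker_id for s in signals],
            "chrom": [s.chrom for s in signals],
            "pos": [s.pos for s in signals],
            "effect_allele": [s.effect_allele for s in signals],
            "other_allele": [s.other_allele for s in signals],
            "beta": [s.effect.beta for s in signals],
            "se": [s.effect.se for s in signals],
            "cond_p": [s.cond_p for s in signals],
            "threshold": [s.threshold if s.threshold is not None else float("nan") for s in signals],
        }
    )


def signals_to_tsv(signals: list[Signal], path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        signals_to_frame(signals).to_csv(fh, sep="\t", index=False, float_format="%.10g")


def signals_from_tsv(path: str | Path) -> list[Signal]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        est = EffectEstimate(
            beta=float(row.beta), se=float(row.se),
            z=float(row.beta) / float(row.se),
            source="marginal" if row.rank == 1 else "conditional",
        )
        thr = None if pd.isna(row.threshold) else float(row.threshold)
        out.append(
            Signal(
                locus_id=str(row.locus_id), marker_id=str(row.marker_id),
                rank=int(row.rank), effect=est, cond_p=float(row.cond_p),
                threshold=thr, chrom=str(row.chrom), pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
            )
        )
    return out


def summary_to_json(summary: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
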