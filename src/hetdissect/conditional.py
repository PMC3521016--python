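"""Math core of the approximate conditional analysis.

All quantities live on the standardized-phenotype scale (trait variance 1).
From a two-sided p-value and a reported direction of effect the signed
z-score is

    z = direction * Phi^{-1}(1 - p/2)

and, with effect-allele frequency f and sample size N, the allelic effect
and its standard error are approximated by

    beta = z / sqrt(2 f (1-f) N),    se = 1 / sqrt(2 f (1-f) N)

since under Hardy-Weinberg equilibrium the dosage variance is 2f(1-f) and
the sampling variance of a regression slope on a standardized trait is
approximately 1 / (Var(g) N).

Part of the apparent (marginal) effect at a SNP t can be induced by LD
with another SNP s carrying effect beta_s.  Under an additive model that
projected effect is

    beta_s * Cov(g_s, g_t) / Var(g_t) = beta_s * 2D / (2 f_t (1-f_t))
                                      = beta_s * D / (f_t (1-f_t)),

with D the haplotype LD coefficient.  The conditional effect of t is the
observed effect minus the sum of projected effects of already-selected
SNPs; its p-value reuses the marginal standard error:

    p_cond = 2 (1 - Phi(|beta_cond / se|)).

Keeping se fixed after conditioning is an approximation: the exact joint
standard error is se / sqrt(1 - r^2), so the conditional z is slightly
deflated (conservative) when LD with the conditioning SNP is appreciable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy.stats import norm

from .errors import DomainError
from .ld_panel import PairLD

MARGINAL = "marginal"
CONDITIONAL = "conditional"


@dataclass(frozen=True)
class EffectEstimate:
    """Allelic effect on the standardized-phenotype scale."""

    beta: float
    se: float
    z: float
    source: str = MARGINAL

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise DomainError(f"standard error must be positive, got {self.se}")


def z_from_p(p: float, direction: int) -> float:
    """Signed z-score from a two-sided p-value and a direction of effect."""
    if not (0.0 < p <= 1.0):
        raise DomainError(f"p must be in (0,1], got {p}")
    if direction not in (-1, 1):
        raise DomainError(f"direction must be +1/-1, got {direction}")
    return float(direction * norm.isf(p / 2.0))


def effect_from_summary(
    z: float,
    f: float,
    n: int,
    denominator: str = "n",
) -> EffectEstimate:
    """Approximate the allelic effect from z, allele frequency and N.

    ``denominator="n"`` uses sqrt(2f(1-f)N); ``"n_plus_z2"`` uses the
    variant sqrt(2f(1-f)(N+z^2)) that folds the signal itself into the
    phenotypic variance (negligible difference except at extreme z).
    """
    if not (0.0 < f < 1.0):
        raise DomainError(f"allele frequency must be in (0,1), got {f}")
    if n < 2:
        raise DomainError(f"sample size must be >= 2, got {n}")
    if denominator == "n":
        scale = 2.0 * f * (1.0 - f) * n
    elif denominator == "n_plus_z2":
        scale = 2.0 * f * (1.0 - f) * (n + z * z)
    else:
        raise DomainError(f"unknown denominator choice: {denominator!r}")
    se = 1.0 / math.sqrt(scale)
    return EffectEstimate(beta=z * se, se=se, z=z, source=MARGINAL)


def projected_effect(beta_source: float, ld: PairLD) -> float:
    """Apparent effect induced at the target SNP by LD with the source.

    ``ld`` must come from ``pair_ld(source, target)`` so that ``f_j`` is
    the target's allele frequency.  Equals beta_source * Cov/Var of the
    dosages under HWE, i.e. beta_source * D / (f_t (1-f_t)).
    """
    if not (0.0 < ld.f_j < 1.0) or not (0.0 < ld.f_i < 1.0):
        raise DomainError("LD frequencies must be in (0,1)")
    return beta_source * ld.d / (ld.f_j * (1.0 - ld.f_j))


def conditional_effect(
    observed: EffectEstimate,
    projections: Iterable[float],
) -> EffectEstimate:
    """Observed effect minus the summed projected effects; se unchanged."""
    beta = observed.beta - sum(projections)
    return EffectEstimate(
        beta=beta, se=observed.se, z=beta / observed.se, source=CONDITIONAL
    )


def conditional_p(estimate: EffectEstimate) -> float:
    """Two-sided p-value 2(1 - Phi(|beta/se|)) for an effect estimate."""
    return float(2.0 * norm.sf(abs(estimate.beta / estimate.se)))
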