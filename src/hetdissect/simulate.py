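"""Synthetic study generator and exact individual-level oracles.

Emulates the three inputs the method consumes — a phased LD reference
panel, a GWAS summary file and a scoring cohort (dosages + phenotypes) —
with planted causal SNPs so that every downstream claim can be checked
against known truth or against exact least squares on the simulated
individuals.

Haplotypes follow a first-order Markov copying model along each locus: the
allele at SNP k copies SNP k-1's allele state with probability rho, and is
otherwise drawn fresh from the marginal frequency.  With equal frequencies
this yields Corr(g_k, g_{k+1}) = rho, so pairwise r^2 decays geometrically
with marker distance — enough LD structure for a method that only consumes
pairwise D, without the cost of a genealogical simulator.

Individuals pair haplotypes drawn with replacement from the panel, which
makes the panel and the cohort draws of the same population (reference-
panel mismatch is then purely sampling noise).  The phenotype is

    y = standardize(g + e) + b_age * age + b_sex * sex + b_int * age * sex

with g the additive genetic value.  When ``heritability`` is a number, the
noise is scaled so g explains exactly that fraction of Var(g + e) in
expectation and the planted betas are re-expressed on the standardized
scale in the returned truth; when it is None, Var(e) = 1 - Var_theory(g)
so the trait core is unit variance and planted betas are already on the
standardized scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError, NumericalError
from .ld_panel import HaplotypePanel
from .scoring import GenotypeMatrix
from .summary_io import SummaryRecord

_TINY = float(np.finfo(np.float64).tiny)


@dataclass
class LocusSpec:
    """One simulated locus: marker grid, LD decay, planted causal effects.

    ``causal_betas`` maps SNP index within the locus to the planted
    allelic effect (per effect allele, standardized-trait scale when the
    study's heritability is None).
    """

    chrom: str
    positions: list[int]
    freqs: list[float]
    rho: float
    causal_betas: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.freqs):
            raise ConfigError("positions and freqs must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ConfigError("positions must be strictly increasing")
        for f in self.freqs:
            if not (0.02 < f < 0.98):
                raise ConfigError(f"allele frequencies must be in (0.02, 0.98), got {f}")
        if not (0.0 <= self.rho <= 1.0):
            raise ConfigError(f"rho must be in [0,1], got {self.rho}")
        for k in self.causal_betas:
            if not (0 <= k < len(self.positions)):
                raise ConfigError(f"causal index {k} outside locus")

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def marker_ids(self) -> list[str]:
        return [f"s{self.chrom}_{p}" for p in self.positions]


def uniform_locus(
    chrom: str,
    start: int,
    n_snps: int,
    spacing_bp: int,
    freq: float | list[float],
    rho: float,
    causal_betas: dict[int, float] | None = None,
) -> LocusSpec:
    """Convenience constructor: evenly spaced markers, shared or listed freqs."""
    positions = [start + k * spacing_bp for k in range(n_snps)]
    freqs = [freq] * n_snps if np.isscalar(freq) else list(freq)
    return LocusSpec(chrom, positions, freqs, rho, causal_betas or {})


@dataclass
class SimConfig:
    """Study conditions for one synthetic data set."""

    n_haplotypes: int
    n_individuals: int
    loci: list[LocusSpec]
    heritability: float | None = None  # None: unit-variance trait core
    seed: int = 0
    age_beta: float = 0.02
    sex_beta: float = 1.0
    interaction_beta: float = 0.01

    def __post_init__(self) -> None:
        if self.n_haplotypes < 4 or self.n_haplotypes % 2:
            raise ConfigError("n_haplotypes must be an even number >= 4")
        if self.n_individuals < 2:
            raise ConfigError("n_individuals must be >= 2")
        if self.heritability is not None and not (0.0 <= self.heritability < 1.0):
            raise ConfigError(f"heritability must be in [0,1), got {self.heritability}")
        if not self.loci:
            raise ConfigError("at least one locus required")
        ids = [m for lc in self.loci for m in lc.marker_ids()]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate marker ids across loci")


@dataclass
class SimTruth:
    """Planted ground truth on the standardized-trait scale."""

    causal_markers: list[str]
    true_betas: list[float]
    realized_fraction_total: float
    realized_fraction_by_locus: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "causal_markers": self.causal_markers,
                    "true_betas": self.true_betas,
                    "realized_fraction_total": self.realized_fraction_total,
                    "realized_fraction_by_locus": self.realized_fraction_by_locus,
                },
                fh, indent=2,
            )
            fh.write("\n")


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def sim_panel(config: SimConfig, rng: np.random.Generator | None = None) -> HaplotypePanel:
    """Generate the phased reference panel under the Markov copying model."""
    rng = rng or _rng_for(config, 0)
    n_hap = config.n_haplotypes
    marker_ids, chroms, positions, alleles, blocks = [], [], [], [], []
    for lc in config.loci:
        block = np.empty((n_hap, lc.n_snps), dtype=np.uint8)
        block[:, 0] = rng.random(n_hap) < lc.freqs[0]
        for k in range(1, lc.n_snps):
            copy = rng.random(n_hap) < lc.rho
            fresh = (rng.random(n_hap) < lc.freqs[k]).astype(np.uint8)
            block[:, k] = np.where(copy, block[:, k - 1], fresh)
        # monomorphic columns defeat frequency/LD estimation: redraw them
        for k in range(lc.n_snps):
            tries = 0
            while block[:, k].min() == block[:, k].max():
                block[:, k] = rng.random(n_hap) < lc.freqs[k]
                tries += 1
                if tries > 100:
                    raise ConfigError(
                        f"cannot generate polymorphic column for freq {lc.freqs[k]}"
                    )
        blocks.append(block)
        marker_ids.extend(lc.marker_ids())
        chroms.extend([lc.chrom] * lc.n_snps)
        positions.extend(lc.positions)
        alleles.extend([("G", "A")] * lc.n_snps)  # effect-orientation allele: A
    return HaplotypePanel(
        marker_ids, chroms, np.asarray(positions), alleles, np.hstack(blocks)
    )


def sim_cohort(
    panel: HaplotypePanel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, SimTruth]:
    """Pair panel haplotypes into individuals; build phenotypes and truth."""
    rng = rng or _rng_for(config, 1)
    n = config.n_individuals
    pick = rng.integers(0, panel.n_haplotypes, size=(2, n))
    dosages = (
        panel.haplotypes[pick[0]].astype(np.int16)
        + panel.haplotypes[pick[1]].astype(np.int16)
    )

    col = {m: k for k, m in enumerate(panel.marker_ids)}
    causal_markers, betas, locus_of = [], [], []
    for lc in config.loci:
        mids = lc.marker_ids()
        for k, b in sorted(lc.causal_betas.items()):
            causal_markers.append(mids[k])
            betas.append(b)
            locus_of.append(lc.chrom + ":" + str(lc.positions[0]))
    betas = np.asarray(betas, dtype=np.float64)

    if causal_markers:
        X = dosages[:, [col[m] for m in causal_markers]].astype(np.float64)
        g = X @ betas
    else:
        X = np.empty((n, 0))
        g = np.zeros(n)
    var_g = float(np.var(g))

    if config.heritability is None:
        var_theory = sum(
            2.0 * f * (1.0 - f) * b * b
            for lc in config.loci
            for k, b in lc.causal_betas.items()
            for f in [lc.freqs[k]]
        )
        if var_theory >= 1.0:
            raise ConfigError(
                f"planted genetic variance {var_theory:.3f} >= 1; reduce effects"
            )
        var_e = 1.0 - var_theory
        scale = 1.0
    else:
        h2 = config.heritability
        if h2 > 0 and var_g == 0:
            raise ConfigError("heritability target > 0 but zero genetic variance")
        var_e = var_g * (1.0 - h2) / h2 if h2 > 0 else 1.0
        scale = None  # standardize below

    e = rng.normal(0.0, math.sqrt(var_e), size=n)
    core = g + e
    if scale is None:
        sd = float(np.std(core))
        core = core / sd
        true_betas = betas / sd
        g_std = g / sd
    else:
        true_betas = betas
        g_std = g

    age = rng.normal(50.0, 12.0, size=n)
    sex = rng.integers(0, 2, size=n)
    trait = (
        core
        + config.age_beta * age
        + config.sex_beta * sex
        + config.interaction_beta * age * sex
    )

    var_core = float(np.var(core))
    frac_total = float(np.var(g_std)) / var_core if var_core > 0 else 0.0
    frac_by_locus: dict[str, float] = {}
    for lid in sorted(set(locus_of)):
        idx = [i for i, l in enumerate(locus_of) if l == lid]
        g_l = X[:, idx] @ betas[idx]
        if scale is None:
            g_l = g_l / sd
        frac_by_locus[lid] = float(np.var(g_l)) / var_core if var_core > 0 else 0.0

    pheno = pd.DataFrame(
        {
            "id": [f"ind{i:06d}" for i in range(n)],
            "trait": trait,
            "age": np.round(age, 2),
            "sex": np.where(sex == 1, "M", "F"),
        }
    )
    genotypes = GenotypeMatrix(
        sample_ids=pheno["id"].tolist(),
        marker_ids=list(panel.marker_ids),
        dosages=dosages.astype(np.float64),
        effect_alleles=[a1 for _, a1 in panel.alleles],
        other_alleles=[a0 for a0, _ in panel.alleles],
    )
    truth = SimTruth(
        causal_markers=causal_markers,
        true_betas=[float(b) for b in true_betas],
        realized_fraction_total=frac_total,
        realized_fraction_by_locus=frac_by_locus,
    )
    return genotypes, pheno, truth


def sim_summary(
    genotypes: GenotypeMatrix,
    residuals: np.ndarray | pd.Series,
) -> tuple[list[SummaryRecord], int]:
    """Per-SNP simple linear regression summary statistics.

    The phenotype residuals are standardized, then each SNP's dosage is
    regressed on them; the two-sided p uses the exact t reference.  SNPs
    monomorphic in the cohort are excluded (count returned).  Output is in
    the same orientation as the genotype matrix, so harmonizing against
    the generating panel is an identity round trip.
    """
    y = np.asarray(residuals, dtype=np.float64)
    n = y.shape[0]
    if n != len(genotypes.sample_ids):
        raise InputError("residuals and genotype matrix have different sample counts")
    y = (y - y.mean()) / y.std()

    X = genotypes.dosages
    xm = X.mean(axis=0)
    Xc = X - xm
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    sxy = Xc.T @ y
    poly = sxx > 0
    n_mono = int((~poly).sum())

    records: list[SummaryRecord] = []
    syy = float(y @ y)
    for k in np.nonzero(poly)[0]:
        slope = sxy[k] / sxx[k]
        rss = syy - slope * sxy[k]
        sigma2 = max(rss, 0.0) / (n - 2)
        se = math.sqrt(sigma2 / sxx[k]) if sigma2 > 0 else _TINY
        t = slope / se
        p = float(max(2.0 * stats.t.sf(abs(t), df=n - 2), _TINY))
        records.append(
            SummaryRecord(
                marker_id=genotypes.marker_ids[k],
                effect_allele=(genotypes.effect_alleles[k]
                               if genotypes.effect_alleles else "A"),
                other_allele=(genotypes.other_alleles[k]
                              if genotypes.other_alleles else "G"),
                p=p,
                direction=1 if slope >= 0 else -1,
                n_obs=n,
                freq=float(xm[k] / 2.0),
            )
        )
    return records, n_mono


def joint_oracle(
    genotypes: GenotypeMatrix,
    residuals: np.ndarray | pd.Series,
    markers: list[str],
) -> pd.DataFrame:
    """Exact multiple least squares of residuals on selected dosage columns.

    The independent reference point for conditional-effect claims.
    Returns a frame with marker, beta, se, p (normal reference, matching
    the summary-statistic approximation's scale conventions).
    """
    y = np.asarray(residuals, dtype=np.float64)
    y = (y - y.mean()) / y.std()
    cols = []
    for m in markers:
        if m not in genotypes:
            raise InputError(f"marker not in genotype matrix: {m}")
        cols.append(genotypes.column(m))
    X = np.column_stack(cols)
    Xc = X - X.mean(axis=0)
    cond = np.linalg.cond(Xc.T @ Xc)
    if not np.isfinite(cond) or cond > 1e8:
        raise NumericalError(
            f"collinear marker set (condition number {cond:.3g}): {markers}"
        )
    n, k = Xc.shape
    xtx_inv = np.linalg.inv(Xc.T @ Xc)
    beta = xtx_inv @ (Xc.T @ y)
    resid = y - Xc @ beta
    sigma2 = float(resid @ resid) / (n - k - 1)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"marker_id": markers, "beta": beta, "se": se, "p": p})


# -- file emission (GIANT-dialect summary, VCF panel, TSV cohort) ----------


def write_summary_giant(records: list[SummaryRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MarkerName\tAllele1\tAllele2\tFreq.Allele1\tDirection\tp\tN\n")
        for r in records:
            freq = f"{r.freq:.6g}" if r.freq is not None else "NA"
            sign = "+" if r.direction > 0 else "-"
            fh.write(
                f"{r.marker_id}\t{r.effect_allele}\t{r.other_allele}\t"
                f"{freq}\t{sign}\t{r.p:.6g}\t{r.n_obs}\n"
            )


def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a phased VCF (haplotype 2i, 2i+1 -> sample i)."""
    n_samp = panel.n_haplotypes // 2
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(panel.chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"HAPS{i:04d}" for i in range(n_samp))
            + "\n"
        )
        for k, mid in enumerate(panel.marker_ids):
            a0, a1 = panel.alleles[k]
            col = panel.haplotypes[:, k]
            gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samp))
            fh.write(
                f"{panel.chroms[k]}\t{panel.positions[k]}\t{mid}\t{a0}\t{a1}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dosages_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(genotypes.dosages, columns=genotypes.marker_ids)
    df.insert(0, "id", genotypes.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%g")


def write_pheno_tsv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class SimStudy:
    """A complete synthetic study: panel, cohort, truth and summary stats."""

    config: SimConfig
    panel: HaplotypePanel
    genotypes: GenotypeMatrix
    pheno: pd.DataFrame
    truth: SimTruth
    records: list[SummaryRecord]
    n_monomorphic: int


def simulate_study(config: SimConfig) -> SimStudy:
    """Run panel -> cohort -> summary with one seed-derived RNG stream."""
    from .scoring import adjust_phenotype

    panel = sim_panel(config)
    genotypes, pheno, truth = sim_cohort(panel, config)
    resid, _ = adjust_phenotype(pheno)
    resid = resid.loc[pheno["id"].astype(str)]
    records, n_mono = sim_summary(genotypes, resid.to_numpy())
    return SimStudy(config, panel, genotypes, pheno, truth, records, n_mono)


def demo_config(seed: int = 0) -> SimConfig:
    """A small default study: 6 loci, two with planted secondary effects."""
    loci = []
    for i in range(6):
        causal = {4: 0.15}
        if i < 2:
            causal[10] = 0.12
        loci.append(
            uniform_locus(
                chrom=str(i + 1), start=1_000_000, n_snps=15,
                spacing_bp=20_000, freq=0.3, rho=0.6, causal_betas=causal,
            )
        )
    return SimConfig(
        n_haplotypes=8000, n_individuals=8000, loci=loci,
        heritability=None, seed=seed,
    )
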