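# Methods

## Model and assumptions

The package targets the setting where a trait association study is
available only as per-SNP summaries (two-sided p, direction of effect,
sample size N, optionally the effect-allele frequency) and LD must be
borrowed from an external phased reference panel.  Throughout, the trait
is assumed standardized (unit variance), allelic effects additive, and
the panel population exchangeable with the study population.

**Effect approximation.**  z = direction × Φ⁻¹(1 − p/2);
β̂ = z/√(2f(1−f)N), se = 1/√(2f(1−f)N).  This is the standard
summary-statistic approximation for a standardized quantitative trait:
under HWE, Var(dosage) = 2f(1−f) and the sampling variance of an OLS
slope is ≈ 1/(Var(g)·N).  A variant denominator √(2f(1−f)(N+z²)), which
counts the SNP's own signal in the phenotypic variance, is available via
`effect_from_summary(..., denominator="n_plus_z2")`; it differs
appreciably only at very large |z|.  Frequencies always come from the
panel (set during harmonization), never from the summary file, so that β
and D are signed in one consistent allele orientation.

**Projection and conditioning.**  For SNPs s (selected, effect β_s) and t
(candidate), the projected effect at t is β_s·2D/(2f_t(1−f_t)) =
β_s·D/(f_t(1−f_t)), i.e. effect × Cov/Var of dosages with haplotype LD
coefficient D = p₁₁ − f_s·f_t.  The conditional effect is the marginal
effect minus the summed projections of all selected signals; its p-value
reuses the marginal se.  Keeping se fixed is an approximation: the exact
joint se is se/√(1−r²), so the conditional z is *deflated* by a factor
√(1−r²) relative to the exact test.  In practice this makes the secondary
test conservative under LD (the measured false-secondary rate sits well
below the nominal 5%), while the point estimate equals the joint
coefficient times (1−r̂²) when summary stats and LD derive from the same
sample — within 3 SE of the joint value whenever between-signal r² is
modest (≲0.3), which is the regime the method is intended for.  A
candidate with r² > 0.99 to any selected signal is skipped as a numerical
guard.

**Stepwise scheme.**  Rank 1 is the locus lead (smallest marginal p; ties
by position then marker id).  Each later round projects every selected
signal with its *assigned* effect — marginal for rank 1, conditional for
ranks ≥ 2 — a sequential-residual scheme that only ever considers LD
between one pair of SNPs at a time and never re-solves a joint model.
The alternative of always projecting with marginal effects is available
(`conditioning="marginal"`); for well-separated causal variants the two
agree on the selected SNPs.  The acceptance rule is conditional
p < 0.05/m, where m counts the clustered (significant) SNPs at the locus;
candidates are locus members only.  Default `max_rank` is 4: in our
synthetic studies, as in typical applications, quaternary signals add
essentially nothing to score variance.

**Clustering.**  Loci are connected components of the "within L of the
next significant SNP" graph (single linkage), so a dense locus can span
megabases.  The gap is inclusive (gap = L joins).  Default L depends on
the significance level (500/400/300/200/100/50 kb at
5e-8/…/5e-3); other levels map to the nearest listed level on the log10
scale, ties to the more stringent level.  Pairwise LD lookups are capped
at 5 Mb (beyond that D is returned as 0 with a flag) — loci rarely exceed
a few Mb, and this bounds memory.

**Harmonization.**  Summary records are matched to the panel by marker
id; allele-swapped records have their direction negated, opposite-strand
records are complemented, and strand-ambiguous SNPs (A/T, C/G) are
dropped by default because a strand flip is then indistinguishable from
an allele swap without a trustworthy frequency in the summary file.
p-values that underflow double precision are clamped to the smallest
positive normal (≈2.2e-308) with a warning rather than rejected, so
extreme GWAS hits survive parsing.  Markers lacking panel LD are dropped
and counted.

**Scoring.**  S_i = Σ β_k x_ik with assigned effects as weights.
Phenotypes are adjusted by OLS on age, sex (0 = female, 1 = male) and
age×sex; variance explained is the squared Pearson correlation between
score and residuals (identical to univariate regression R²), overall and
per sex stratum.  Samples with missing dosages have their partial score
rescaled by total |weight| / observed |weight| (strict mode drops them
instead); |weight| is used so that opposite-signed weights cannot cancel
in the rescaling factor.

## Synthetic data generator

`hetdissect.simulate` emulates the three inputs.  Haplotypes follow a
first-order Markov copying model: SNP k copies SNP k−1's allele with
probability ρ, else draws from the marginal frequency.  With equal
frequencies the adjacent dosage correlation is ρ and r² decays
geometrically with marker separation — sufficient for a method that
consumes only pairwise D, and exactly seed-reproducible, unlike a
genealogical simulator whose extra realism (recombination hotspots,
allele-frequency spectra, population structure) none of the tested
quantities consume.  Individuals pair haplotypes drawn with replacement
from the panel, so reference-panel mismatch is pure sampling noise;
per-SNP summary statistics are exact simple regressions of standardized
adjusted residuals on dosage with t-distribution p-values.

Phenotypes are y = standardize(g + e) + 0.02·age + 1.0·sex +
0.01·age·sex, age ~ N(50, 12²), sex ~ Bernoulli(½).  With
`heritability=None` (the default used in validation), Var(e) =
1 − Σ2f(1−f)β² so the trait core has unit variance and planted betas are
already on the standardized scale; with a numeric target h², noise is
scaled so the genetic fraction equals h² and the returned truth re-expresses
the betas on the realized SD scale.

What the generator does **not** model: genotyping/imputation error,
panel–study population mismatch beyond resampling noise, non-additive
effects, and realistic LD block structure.  Passing tests therefore show
that the algorithm is correct under its own assumptions, not that those
assumptions hold in any particular real cohort.

## Validation protocols and problem sizes

`hetdissect.experiments` fixes the study conditions used by both the test
suite and `scripts/acceptance.py`:

- **Oracle agreement**: 200 replicates of a 12-SNP locus with two causal
  variants (0.2% and 0.15% of trait variance), ρ ~ U(0.3, 0.8) keeping
  between-causal r² ≲ 0.3, n = 20,000, summary and LD from the same
  sample; the secondary conditional effect is compared with the exact
  two-SNP joint OLS coefficient (±3 joint SE).  A replicate yielding no
  secondary signal counts as disagreement.
- **Recovery**: one study of 20 well-separated 15-SNP loci (ρ = 0.8), 10
  with a 0.2% primary plus 0.1% secondary causal (between-causal
  r² ≈ 0.07) and 10 single-causal, n = 50,000; clustering at 5×10⁻⁸
  should find exactly 20 loci and dissection should flag ≥90% of planted
  secondaries.
- **False-secondary control**: 1,000 single-causal 10-SNP loci (causal
  0.8% of variance, adjacent r² ≈ 0.8), n = 10,000 per cohort.  The
  type-I error of the conditional test does not depend on n, so a
  moderate cohort size keeps this protocol fast; the observed family-wise
  rate is ~0.002–0.01, well under the nominal 5% (the fixed-se test is
  conservative under LD).
- **Calibration**: 2,000 unlinked null SNPs, n = 5,000, KS test against
  uniform; plus a deterministic z↔p round trip over p ∈ [1e-300, 1]
  (max relative error ≈ 4e-13).
- **Scores**: true-weight scores on cohorts with 10% planted variance
  (n = 5,000), and 100 replicates (n = 2,000) of 8 loci with
  primary+secondary causals (0.5% + 0.3% each) comparing primary-only
  vs full scores.  Adding secondaries raises R² in every replicate, by
  ~40% relative on average.

## Numerical choices and edge cases

- All statistics in double precision; normal quantiles/CDF from
  scipy.stats (`isf`/`sf`, accurate in the far tail).
- Ties on conditional p break by position then marker id; locus ids are
  assigned after sorting by chromosome (natural order) and span start.
- Monomorphic panel columns are dropped at load (frequency must lie
  strictly in (0,1)); missing panel alleles are an error, not imputed.
- Loci whose members are absent from the panel lose those members from
  candidacy (with a warning) but m in 0.05/m still counts all clustered
  members.
- Zero-variance scores yield R² = 0 with a warning; degenerate phenotype
  tables (<3 complete rows, constant covariates) are input errors.
- Exit codes: 0 ok, 2 configuration/domain, 3 input, 4 numerical.

## Known limitations

- The fixed-se conditional test is conservative for high-LD secondaries
  and the conditional point estimate is attenuated by (1−r²); loci whose
  independent signals sit in strong LD (r² ≫ 0.3) are better served by a
  full joint model.
- Apparent secondary signals cannot be distinguished from partial LD with
  a single unobserved causal variant — a limitation of the data, not of
  the implementation.
- Panel-study frequency or LD mismatch propagates directly into projected
  effects; the generator's panel-resampling noise is the only mismatch
  quantified here.
- No liftover, rsID synonym resolution, or multi-allelic support.
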