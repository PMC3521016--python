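# hetdissect

Dissection of allelic heterogeneity at trait-associated loci from GWAS
summary statistics.

Large association studies often release only per-SNP summary data —
p-values, directions of effect, sample sizes — rather than individual-level
genotypes.  `hetdissect` implements an approximate conditional analysis
that works entirely from such summaries plus an external phased reference
panel: it recovers allelic effect sizes, groups significant SNPs into
physical loci, peels off secondary/tertiary/quaternary association signals
at each locus by subtracting LD-projected effects of already-selected SNPs,
and quantifies how much trait variance weighted genetic scores built from
those signals explain in an independent cohort.  It is aimed at
statistical geneticists who want to ask "does this locus harbour more than
one independent signal?" without access to the original cohort data.

## Method

For each SNP, the signed z-score is obtained from the reported two-sided
p-value and direction, z = ±Φ⁻¹(1 − p/2), and the allelic effect on a
standardized trait is approximated by

    β̂ = z / √(2f(1−f)N),   se = 1 / √(2f(1−f)N),

with f the effect-allele frequency and N the sample size (2f(1−f) is the
Hardy–Weinberg dosage variance).  Frequencies and LD come from phased
reference haplotypes (VCF, or the HapMap Phase 2 legend/phased dialect).

SNPs with p < α are clustered into loci by single-linkage chaining with a
level-dependent window (500 kb at α = 5×10⁻⁸ down to 50 kb at 5×10⁻³).
At each locus the lead SNP is the primary signal.  The effect another SNP
t appears to carry purely through LD with a selected SNP s is the
*projected effect* β_s·D/(f_t(1−f_t)), D being the haplotype LD
coefficient; subtracting the projected effects of all selected signals
from t's marginal effect gives its *conditional effect*, with p-value
2(1 − Φ(|β_cond/se|)).  The smallest conditional p wins the next rank if
it beats the per-locus Bonferroni cutoff 0.05/m (m = clustered SNPs at
the locus); iterating yields secondary, tertiary and quaternary signals.

Scores S_i = Σ_k β_k x_ik (x = effect-allele dosage; β the assigned
marginal or conditional effect) are regressed against age-, sex- and
age×sex-adjusted trait residuals; the squared correlation is the variance
explained, reported overall and per sex stratum.

## Worked example

A synthetic study (3 loci, two of which carry a planted secondary effect;
n = 6,000) can be generated and analysed entirely from the command line:

```
hetdissect simulate --config sim.yaml --out data
hetdissect run --summary data/summary.txt --panel data/panel.vcf \
    --genotypes data/dosages.tsv --pheno data/pheno.tsv \
    --alpha 5e-6 --out out
```

`out/heterogeneity.json` then reports

```json
{"alpha": 5e-06, "n_loci": 3, "n_signals": 5,
 "n_with_secondary": 2, "pct_with_secondary": 66.7}
```

— all 3 planted loci are found and exactly the 2 loci with two causal
variants are flagged as allelically heterogeneous.  The first locus's
signals (from `out/signals.tsv`):

```
locus_id rank marker_id   beta    se      cond_p
L0001    1    s1_1060000  0.1635  0.0200  2.8e-16
L0001    2    s1_1160000  0.0915  0.0200  4.9e-06
```

The planted effects were 0.16 (primary) and 0.12 (secondary): the primary
is recovered directly and the secondary's conditional estimate is
attenuated slightly by its LD with the lead, as expected of the fixed-se
approximation.  The score report shows the payoff of modelling
heterogeneity — adding rank-2 signals raises the variance explained from
3.3% to 4.4% (a ~30% relative gain):

```
ranks_included stratum r2       n     n_snps
1              all     0.0335   6000  3
2              all     0.0436   6000  5
```

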