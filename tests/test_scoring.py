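import numpy as np
import pandas as pd
import pytest

from hetdissect.conditional import EffectEstimate
from hetdissect.errors import InputError
from hetdissect.scoring import (
    GenotypeMatrix,
    adjust_phenotype,
    build_score,
    genotypes_from_tsv,
    score_report,
    variance_explained,
)
from hetdissect.stepwise import Signal


def signal(marker, beta, rank=1, effect_allele="A", other_allele="G"):
    return Signal(
        locus_id="L0001", marker_id=marker, rank=rank,
        effect=EffectEstimate(beta=beta, se=1.0, z=beta),
        cond_p=0.0, threshold=None, chrom="1", pos=1,
        effect_allele=effect_allele, other_allele=other_allele,
    )


def geno(markers, dosages, ids=None, eff=None, oth=None):
    dosages = np.asarray(dosages, dtype=float)
    ids = ids or [f"i{k}" for k in range(dosages.shape[0])]
    return GenotypeMatrix(ids, markers, dosages, eff, oth)


class TestAdjustPhenotype:
    def make(self, n=200, seed=0, age_b=0.5, sex_b=3.0, noise=1.0):
        rng = np.random.default_rng(seed)
        age = rng.uniform(20, 70, n)
        sex = rng.integers(0, 2, n)
        e = rng.normal(0, noise, n)
        trait = age_b * age + sex_b * sex + e
        return pd.DataFrame(
            {"id": [f"i{k}" for k in range(n)], "trait": trait,
             "age": age, "sex": np.where(sex == 1, "M", "F")}
        ), e

    def test_exactly_linear_trait_gives_zero_residuals(self):
        pheno, _ = self.make(noise=0.0)
        resid, dropped = adjust_phenotype(pheno)
        assert dropped == 0
        assert np.allclose(resid.to_numpy(), 0.0, atol=1e-8)

    def test_row_order_invariance(self):
        pheno, _ = self.make(seed=3)
        r1, _ = adjust_phenotype(pheno)
        r2, _ = adjust_phenotype(pheno.sample(frac=1.0, random_state=1))
        assert np.allclose(r1.sort_index(), r2.sort_index())

    def test_residual_variance_matches_noise(self):
        pheno, e = self.make(n=1000, seed=5, noise=2.0)
        resid, _ = adjust_phenotype(pheno)
        assert np.var(resid) == pytest.approx(np.var(e), rel=0.10)

    def test_incomplete_rows_dropped_and_counted(self):
        pheno, _ = self.make(n=10)
        pheno.loc[0, "age"] = np.nan
        pheno.loc[1, "sex"] = None
        resid, dropped = adjust_phenotype(pheno)
        assert dropped == 2 and len(resid) == 8

    def test_too_few_rows_or_constant_covariate(self):
        pheno, _ = self.make(n=10)
        with pytest.raises(InputError):
            adjust_phenotype(pheno.head(2))
        pheno["sex"] = "F"
        with pytest.raises(InputError):
            adjust_phenotype(pheno)


class TestBuildScore:
    def test_weighted_sum(self):
        g = geno(["a", "b"], [[2, 1]])
        score = build_score([signal("a", 0.1), signal("b", -0.2)], g)
        assert score.iloc[0] == pytest.approx(0.0)

    def test_zero_weights_zero_scores(self):
        g = geno(["a", "b"], [[2, 1], [0, 1]])
        assert (build_score([signal("a", 0.0), signal("b", 0.0)], g) == 0).all()

    def test_split_weight_linearity(self):
        g = geno(["a"], [[2], [1], [0]])
        full = build_score([signal("a", 0.3)], g)
        halves = build_score([signal("a", 0.15), signal("a", 0.15)], g)
        assert np.allclose(full, halves)

    def test_effect_allele_mismatch_reflects_dosage(self):
        g = geno(["a"], [[2], [0]], eff=["A"], oth=["G"])
        forward = build_score([signal("a", 0.5)], g)
        swapped = build_score([signal("a", 0.5, effect_allele="G",
                                      other_allele="A")], g)
        assert np.allclose(swapped.to_numpy(), 0.5 * (2 - np.array([2, 0])))
        assert np.allclose(forward + swapped, 1.0)

    def test_missing_marker_warns_no_overlap_raises(self):
        g = geno(["a"], [[1]])
        with pytest.warns(UserWarning):
            build_score([signal("a", 0.1), signal("zz", 0.5)], g)
        with pytest.raises(InputError):
            build_score([signal("zz", 0.5)], g)

    def test_missing_dosage_rescaled_or_dropped(self):
        g = geno(["a", "b"], [[2, np.nan], [2, 2]])
        rescaled = build_score([signal("a", 0.1), signal("b", 0.1)], g)
        # sample 0: observed weight 0.1 of 0.2 -> score 0.2 * (0.2/0.1) = 0.4
        assert rescaled.iloc[0] == pytest.approx(0.4)
        assert rescaled.iloc[1] == pytest.approx(0.4)
        strict = build_score([signal("a", 0.1), signal("b", 0.1)], g,
                             missing_policy="strict")
        assert np.isnan(strict.iloc[0]) and strict.iloc[1] == pytest.approx(0.4)


class TestVarianceExplained:
    def test_identical_series_r2_one(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        assert variance_explained(s, s)[0].r2 == pytest.approx(1.0)

    def test_independent_score_near_zero(self):
        rng = np.random.default_rng(8)
        idx = [f"i{k}" for k in range(10_000)]
        score = pd.Series(rng.normal(size=10_000), index=idx)
        resid = pd.Series(rng.normal(size=10_000), index=idx)
        assert variance_explained(score, resid)[0].r2 < 0.01

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        idx = [f"i{k}" for k in range(500)]
        score = pd.Series(rng.normal(size=500), index=idx)
        resid = pd.Series(score.to_numpy() + rng.normal(size=500), index=idx)
        base = variance_explained(score, resid)[0].r2
        scaled = variance_explained(3.0 * score + 7.0, resid)[0].r2
        assert scaled == pytest.approx(base, abs=1e-12)

    def test_zero_variance_score_warns_r2_zero(self):
        idx = list("abcde")
        score = pd.Series(1.0, index=idx)
        resid = pd.Series([1, 2, 3, 4, 5.0], index=idx)
        with pytest.warns(UserWarning):
            assert variance_explained(score, resid)[0].r2 == 0.0

    def test_strata_use_only_their_samples(self):
        rng = np.random.default_rng(6)
        idx = [f"i{k}" for k in range(400)]
        sex = pd.Series(["F"] * 200 + ["M"] * 200, index=idx)
        score = pd.Series(rng.normal(size=400), index=idx)
        # residuals track the score only in females
        resid = score.copy()
        resid.iloc[200:] = rng.normal(size=200)
        results = {r.stratum: r for r in variance_explained(score, resid, sex=sex)}
        assert results["female"].n == 200 and results["male"].n == 200
        assert results["female"].r2 > 0.95
        assert results["male"].r2 < 0.05
        assert 0.0 <= results["all"].r2 <= 1.0

    def test_planted_variance_fraction_recovered_and_grows_with_n(self):
        """True-weight score converges to the planted variance fraction."""
        for n, tol in ((500, 0.06), (5000, 0.02)):
            rng = np.random.default_rng(n)
            g = rng.binomial(2, 0.5, size=(n, 4)).astype(float)
            w = np.array([0.15, 0.12, -0.1, 0.08])
            gen = g @ w
            target = 0.10
            noise_sd = np.sqrt(np.var(gen) * (1 - target) / target)
            y = gen + rng.normal(0, noise_sd, n)
            idx = [f"i{k}" for k in range(n)]
            score = pd.Series(gen, index=idx)
            resid = pd.Series(y - y.mean(), index=idx)
            assert variance_explained(score, resid)[0].r2 == pytest.approx(
                target, abs=tol
            )


class TestScoreReport:
    def test_rank_one_matches_primary_only_score(self):
        rng = np.random.default_rng(2)
        n = 300
        dos = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        g = geno(["a", "b"], dos)
        y = 0.3 * dos[:, 0] + 0.2 * dos[:, 1] + rng.normal(size=n)
        resid = pd.Series(y - y.mean(), index=g.sample_ids)
        signals = [signal("a", 0.3, rank=1), signal("b", 0.2, rank=2)]
        report = score_report({5e-8: signals}, g, resid)
        primary_score = build_score([signals[0]], g)
        expected = variance_explained(primary_score, resid)[0].r2
        assert report.loc[0, "r2_all_rank1"] == pytest.approx(expected)
        assert report.loc[0, "n_snps_rank1"] == 1
        assert report.loc[0, "n_snps_rank2"] == 2

    def test_zero_effect_secondary_leaves_r2_unchanged(self):
        rng = np.random.default_rng(13)
        n = 300
        dos = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        g = geno(["a", "b"], dos)
        y = 0.3 * dos[:, 0] + rng.normal(size=n)
        resid = pd.Series(y - y.mean(), index=g.sample_ids)
        signals = [signal("a", 0.3, rank=1), signal("b", 0.0, rank=2)]
        report = score_report({5e-8: signals}, g, resid)
        assert report.loc[0, "r2_all_rank2"] == pytest.approx(
            report.loc[0, "r2_all_rank1"]
        )


def test_genotypes_from_tsv_roundtrip(tmp_path):
    path = tmp_path / "dos.tsv"
    path.write_text("id\ta\tb\ni0\t2\t0.5\ni1\t0\t1.5\n")
    g = genotypes_from_tsv(path)
    assert g.sample_ids == ["i0", "i1"] and g.marker_ids == ["a", "b"]
    assert g.dosages[0, 1] == pytest.approx(0.5)
    with pytest.raises(InputError):
        GenotypeMatrix(["i0"], ["a"], np.array([[3.0]]))
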