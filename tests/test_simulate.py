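import numpy as np
import pytest
from scipy import stats

from hetdissect.errors import ConfigError, NumericalError
from hetdissect.scoring import adjust_phenotype
from hetdissect.simulate import (
    SimConfig,
    joint_oracle,
    sim_cohort,
    sim_panel,
    sim_summary,
    simulate_study,
    uniform_locus,
)


def config_of(loci, n_hap=2000, n_ind=1000, seed=0, h2=None):
    return SimConfig(
        n_haplotypes=n_hap, n_individuals=n_ind, loci=loci,
        heritability=h2, seed=seed,
    )


class TestSimPanel:
    def test_same_seed_identical_panel(self):
        cfg = config_of([uniform_locus("1", 1000, 10, 100, 0.4, 0.5)])
        a, b = sim_panel(cfg), sim_panel(cfg)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)

    def test_perfect_copying_gives_adjacent_r2_one(self):
        cfg = config_of([uniform_locus("1", 1000, 5, 100, 0.4, 1.0)])
        panel = sim_panel(cfg)
        ids = panel.marker_ids
        for i in range(4):
            assert panel.pair_ld(ids[i], ids[i + 1]).r2 == pytest.approx(1.0)

    def test_no_copying_gives_near_independent_pairs(self):
        cfg = config_of(
            [uniform_locus("1", 1000, 30, 100, 0.4, 0.0)], n_hap=10_000
        )
        panel = sim_panel(cfg)
        ids = panel.marker_ids
        ds = [
            abs(panel.pair_ld(ids[i], ids[j]).d)
            for i in range(30) for j in range(i + 1, 30)
        ]
        assert np.mean(np.array(ds) < 0.02) > 0.95
        assert np.mean(np.array(ds) < 3 * np.sqrt(0.24 * 0.24 / 10_000)) > 0.9

    def test_copying_decay_is_monotone_in_distance(self):
        cfg = config_of([uniform_locus("1", 1000, 8, 100, 0.5, 0.8)],
                        n_hap=20_000)
        panel = sim_panel(cfg)
        ids = panel.marker_ids
        r2s = [panel.pair_ld(ids[0], ids[k]).r2 for k in range(1, 8)]
        assert all(np.diff(r2s) < 0.05)  # decaying, allowing sampling noise

    def test_frequencies_respect_bounds(self):
        with pytest.raises(ConfigError):
            uniform_locus("1", 1000, 3, 100, 0.01, 0.5)


class TestSimCohort:
    def test_no_causals_zero_genetic_variance(self):
        cfg = config_of([uniform_locus("1", 1000, 5, 100, 0.4, 0.5)])
        panel = sim_panel(cfg)
        _, _, truth = sim_cohort(panel, cfg)
        assert truth.realized_fraction_total == 0.0
        assert truth.causal_markers == []

    def test_single_causal_hits_planted_variance_fraction(self):
        beta = np.sqrt(0.05 / (2 * 0.5 * 0.5))  # 5% of unit variance
        locus = uniform_locus("1", 1000, 5, 100, 0.5, 0.3,
                              causal_betas={2: beta})
        cfg = config_of([locus], n_hap=20_000, n_ind=10_000, seed=4)
        panel = sim_panel(cfg)
        _, _, truth = sim_cohort(panel, cfg)
        assert truth.realized_fraction_total == pytest.approx(0.05, abs=0.01)

    def test_heritability_target_mode_rescales(self):
        locus = uniform_locus("1", 1000, 5, 100, 0.5, 0.3,
                              causal_betas={2: 1.0})
        cfg = config_of([locus], n_hap=20_000, n_ind=10_000, seed=4, h2=0.2)
        panel = sim_panel(cfg)
        _, _, truth = sim_cohort(panel, cfg)
        assert truth.realized_fraction_total == pytest.approx(0.2, abs=0.02)
        assert truth.true_betas[0] != 1.0  # re-expressed on the SD scale

    def test_unreachable_heritability_rejected(self):
        locus = uniform_locus("1", 1000, 5, 100, 0.5, 0.3)
        cfg = config_of([locus], h2=0.3)
        panel = sim_panel(cfg)
        with pytest.raises(ConfigError):
            sim_cohort(panel, cfg)

    def test_fixed_seed_reproducible_phenotypes(self):
        locus = uniform_locus("1", 1000, 5, 100, 0.5, 0.3,
                              causal_betas={2: 0.1})
        cfg = config_of([locus], seed=9)
        panel = sim_panel(cfg)
        _, p1, _ = sim_cohort(panel, cfg)
        _, p2, _ = sim_cohort(panel, cfg)
        assert p1.equals(p2)


class TestSimSummary:
    def test_null_pvalues_uniform(self):
        cfg = config_of(
            [uniform_locus("1", 1000, 500, 1000, 0.3, 0.0)],
            n_hap=2000, n_ind=2000, seed=17,
        )
        study = simulate_study(cfg)
        pvals = [r.p for r in study.records]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_causal_reaches_extreme_significance(self):
        beta = np.sqrt(0.01 / (2 * 0.3 * 0.7))  # 1% of variance
        ps = []
        for seed in range(11):
            locus = uniform_locus("1", 1000, 3, 1000, 0.3, 0.0,
                                  causal_betas={1: beta})
            cfg = config_of([locus], n_hap=20_000, n_ind=10_000, seed=seed)
            study = simulate_study(cfg)
            causal = next(r for r in study.records
                          if r.marker_id == study.truth.causal_markers[0])
            ps.append(causal.p)
        assert np.median(ps) < 1e-15

    def test_direction_sign_matches_planted_effect(self):
        up = uniform_locus("1", 1000, 3, 1000, 0.3, 0.0, causal_betas={1: 0.3})
        down = uniform_locus("2", 1000, 3, 1000, 0.3, 0.0,
                             causal_betas={1: -0.3})
        cfg = config_of([up, down], n_hap=8000, n_ind=4000, seed=2)
        study = simulate_study(cfg)
        by_id = {r.marker_id: r for r in study.records}
        assert by_id[study.truth.causal_markers[0]].direction == 1
        assert by_id[study.truth.causal_markers[1]].direction == -1

    def test_freq_and_n_filled_from_cohort(self):
        cfg = config_of([uniform_locus("1", 1000, 4, 100, 0.3, 0.5)],
                        n_ind=500)
        study = simulate_study(cfg)
        assert all(r.n_obs == 500 for r in study.records)
        assert all(0 < r.freq < 1 for r in study.records)


class TestJointOracle:
    def make_study(self, seed=3):
        locus = uniform_locus("1", 1000, 6, 10_000, 0.4, 0.4,
                              causal_betas={1: 0.1, 4: 0.08})
        cfg = config_of([locus], n_hap=20_000, n_ind=10_000, seed=seed)
        panel = sim_panel(cfg)
        genotypes, pheno, truth = sim_cohort(panel, cfg)
        resid, _ = adjust_phenotype(pheno)
        return genotypes, resid.to_numpy(), truth

    def test_single_marker_reduces_to_simple_regression(self):
        import statsmodels.api as sm

        genotypes, resid, truth = self.make_study()
        m = truth.causal_markers[0]
        ours = joint_oracle(genotypes, resid, [m])
        y = (resid - resid.mean()) / resid.std()
        X = sm.add_constant(genotypes.column(m))
        ref = sm.OLS(y, X).fit()
        assert ours.loc[0, "beta"] == pytest.approx(ref.params[1], rel=1e-6)
        assert ours.loc[0, "se"] == pytest.approx(ref.bse[1], rel=1e-2)

    def test_orthogonal_markers_joint_equals_marginal(self):
        loci = [
            uniform_locus("1", 1000, 1, 100, 0.4, 0.0, causal_betas={0: 0.1}),
            uniform_locus("2", 1000, 1, 100, 0.4, 0.0, causal_betas={0: 0.1}),
        ]
        cfg = config_of(loci, n_hap=40_000, n_ind=20_000, seed=5)
        panel = sim_panel(cfg)
        genotypes, pheno, truth = sim_cohort(panel, cfg)
        resid, _ = adjust_phenotype(pheno)
        joint = joint_oracle(genotypes, resid.to_numpy(), truth.causal_markers)
        for k, m in enumerate(truth.causal_markers):
            single = joint_oracle(genotypes, resid.to_numpy(), [m])
            assert joint.loc[k, "beta"] == pytest.approx(
                single.loc[0, "beta"], abs=3 * single.loc[0, "se"] * 0.2
            )

    def test_recovers_planted_betas_within_3se(self):
        genotypes, resid, truth = self.make_study(seed=8)
        joint = joint_oracle(genotypes, resid, truth.causal_markers)
        for k, b in enumerate(truth.true_betas):
            assert abs(joint.loc[k, "beta"] - b) < 3 * joint.loc[k, "se"]

    def test_collinear_set_raises_numerical_error(self):
        locus = uniform_locus("1", 1000, 3, 100, 0.4, 1.0)  # identical columns
        cfg = config_of([locus], seed=1)
        panel = sim_panel(cfg)
        genotypes, pheno, _ = sim_cohort(panel, cfg)
        resid, _ = adjust_phenotype(pheno)
        with pytest.raises(NumericalError):
            joint_oracle(genotypes, resid.to_numpy(), panel.marker_ids[:2])


def test_duplicate_marker_ids_rejected():
    loci = [
        uniform_locus("1", 1000, 3, 100, 0.4, 0.5),
        uniform_locus("1", 1000, 3, 100, 0.4, 0.5),
    ]
    with pytest.raises(ConfigError):
        config_of(loci)
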