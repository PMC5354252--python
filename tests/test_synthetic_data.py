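"""Ground-truth recovery and construction invariants of the generators."""

import numpy as np
import pandas as pd
import pytest

from qstfst import fst, qst
from qstfst import synthetic_data as sim


class TestSimulateGenotypes:
    def test_seeded_runs_identical(self):
        cfg = sim.SimConfig(n_per_pop=(20,) * 4, n_snps=200, seed=3)
        g1 = sim.simulate_genotypes(cfg)
        g2 = sim.simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        np.testing.assert_array_equal(g1.populations, g2.populations)

    def test_zero_fst_gives_near_zero_theta(self):
        """No drift: multi-locus theta vanishes at 20k SNPs."""
        cfg = sim.SimConfig(
            n_pops=4, n_per_pop=(50,) * 4, n_snps=20_000, target_fst=0.0,
            seed=1,
        )
        d = fst.wc_theta(sim.simulate_genotypes(cfg))
        assert abs(d.theta_multilocus) < 0.005

    def test_dosages_in_range_and_labels_attached(self):
        cfg = sim.SimConfig(n_per_pop=(10, 20, 5, 8), n_snps=100, seed=2)
        g = sim.simulate_genotypes(cfg)
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        assert list(pd.Series(g.populations).value_counts().sort_index()) == [
            10, 20, 5, 8
        ]

    @pytest.mark.parametrize(
        "bad",
        [
            {"target_fst": 1.0},
            {"target_fst": -0.1},
            {"maf_range": (0.0, 0.0)},
            {"maf_range": (0.2, 0.1)},
            {"n_per_pop": (0, 10, 10, 10)},
            {"h2": 1.5},
            {"c": 0.5, "sigma2_gb": 0.0},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            sim.SimConfig(**bad)


class TestSimulatePhenotype:
    def _qst_replicates(self, n_reps, **kw):
        vals = []
        for rep in range(n_reps):
            cfg = sim.SimConfig(n_snps=60, seed=10_000 + rep, **kw)
            g = sim.simulate_genotypes(cfg)
            ph = sim.simulate_phenotype(g, cfg)
            vc = qst.variance_components(ph, "trait")
            vals.append(qst.qst_value(vc).qst)
        return np.array(vals)

    def test_no_between_signal_gives_near_zero_qst(self):
        """sigma2_gb=0: at least 95% of 200 replicates estimate Qst < 0.05."""
        vals = self._qst_replicates(
            200, n_pops=4, n_per_pop=(100,) * 4, sigma2_gb=0.0, c=0.0,
            sigma2_gw=1.0, h2=0.5,
        )
        assert (vals < 0.05).mean() >= 0.95

    def test_equal_components_give_one_third(self):
        """sigma2_gb = sigma2_gw and c = h2: true Qst is 1/3."""
        vals = self._qst_replicates(
            200, n_pops=4, n_per_pop=(100,) * 4, sigma2_gb=1.0,
            sigma2_gw=1.0, h2=0.5, c=0.5,
        )
        assert vals.mean() == pytest.approx(1 / 3, abs=0.03)

    def test_high_divergence_recovered(self):
        """Components set so the true Qst is 0.64."""
        vals = self._qst_replicates(
            200, n_pops=4, n_per_pop=(100,) * 4, sigma2_gb=32 / 9,
            sigma2_gw=1.0, h2=0.6, c=0.6,
        )
        true = (32 / 9) / (32 / 9 + 2)
        assert true == pytest.approx(0.64, abs=0.001)
        assert vals.mean() == pytest.approx(true, abs=0.05)

    def test_covariate_effects_recoverable_by_regression(self):
        cfg = sim.SimConfig(
            n_per_pop=(200,) * 4, n_snps=60,
            covariate_effects={"sex": 2.0, "age": 0.1, "bmi": 0.3}, seed=5,
        )
        ph = sim.simulate_phenotype(sim.simulate_genotypes(cfg), cfg)
        import statsmodels.formula.api as smf

        fit = smf.ols("trait ~ C(population) + C(sex) + age + bmi", ph).fit()
        assert fit.params["C(sex)[T.M]"] == pytest.approx(2.0, abs=0.3)
        assert fit.params["age"] == pytest.approx(0.1, abs=0.03)
        assert fit.params["bmi"] == pytest.approx(0.3, abs=0.06)

    def test_h2_zero_budget_becomes_noise(self):
        cfg = sim.SimConfig(
            n_per_pop=(300,), n_pops=1, sigma2_gb=0.0, c=0.0,
            sigma2_gw=2.0, h2=0.0, covariate_effects={}, seed=6,
        )
        ph = sim.simulate_phenotype(sim.simulate_genotypes(cfg), cfg)
        assert ph["trait"].var(ddof=1) == pytest.approx(2.0, rel=0.3)

    def test_truth_sidecar_records_generating_model(self):
        cfg = sim.SimConfig(n_per_pop=(20,) * 4, n_snps=50, seed=7)
        ph = sim.simulate_phenotype(sim.simulate_genotypes(cfg), cfg)
        truth = ph.attrs["truth"]
        assert truth["true_qst"] == pytest.approx(1 / 3)
        assert truth["c_over_h2"] == 1.0


class TestSimulateAdmixedCohort:
    def test_row_mean_reproduces_global_ancestry(self):
        """Average local ancestry over SNPs tracks each individual's drawn
        global ancestry (r^2 > 0.99 with many short tracts)."""
        cfg = sim.AdmixSimConfig(
            n_ind=100, n_snps=20_000, tract_mean_snps=10, seed=8
        )
        la, _, ph = sim.simulate_admixed_cohort(cfg)
        r = np.corrcoef(la.global_ancestry(), ph["global_ancestry"])[0, 1]
        assert r**2 > 0.99

    def test_zero_target_gives_near_zero_estimates(self):
        """h_y2 target 0: the REML median over 50 cohorts stays below 0.05."""
        from qstfst import heritability as her

        vals = []
        for rep in range(50):
            cfg = sim.AdmixSimConfig(
                n_ind=200, n_snps=500, h_y2_target=0.0, seed=20_000 + rep
            )
            la, _, ph = sim.simulate_admixed_cohort(cfg)
            K = her.ancestry_grm(la)
            X = np.column_stack(
                [np.ones(200), ph["global_ancestry"].to_numpy()]
            )
            vals.append(her.reml_h2(ph["trait"].to_numpy(), X, K).h2)
        assert np.median(vals) < 0.05

    def test_tract_structure_present(self):
        cfg = sim.AdmixSimConfig(n_ind=30, n_snps=2_000, tract_mean_snps=100,
                                 seed=9)
        la, _, _ = sim.simulate_admixed_cohort(cfg)
        # adjacent SNPs agree far more often than distant ones
        same_adj = (la.dosages[:, 1:] == la.dosages[:, :-1]).mean()
        same_far = (la.dosages[:, : 1000] == la.dosages[:, 1000:]).mean()
        assert same_adj > same_far + 0.1

    def test_genotypes_reflect_local_ancestry(self):
        """Parental populations drifted apart: genotype frequency differs by
        local ancestry state at a typical SNP."""
        cfg = sim.AdmixSimConfig(n_ind=400, n_snps=300, parental_fst=0.3,
                                 seed=10)
        la, gm, _ = sim.simulate_admixed_cohort(cfg)
        corrs = []
        for j in range(0, 300, 10):
            if la.dosages[:, j].std() > 0 and gm.dosages[:, j].std() > 0:
                corrs.append(
                    np.corrcoef(la.dosages[:, j], gm.dosages[:, j])[0, 1]
                )
        assert np.mean(np.abs(corrs)) > 0.05

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sim.AdmixSimConfig(ancestry_mean=0.0)
        with pytest.raises(ValueError):
            sim.AdmixSimConfig(tract_mean_snps=0)
        with pytest.raises(ValueError):
            sim.AdmixSimConfig(h_y2_target=1.2)


class TestSimulateLandmarks:
    def test_zero_noise_replicates_identical(self):
        lm = sim.simulate_landmarks(5, noise_sd=0.0, n_observers=2, n_reps=3,
                                    seed=11)
        spread = lm.groupby(["id", "landmark"])[["x", "y", "z"]].std()
        assert float(spread.max().max()) == 0.0

    def test_population_offset_moves_only_targeted_distance(self):
        """Widening al_l/al_r shifts nares width between populations while
        alar base width stays put."""
        from qstfst.morphometrics import replicate_mean_traits

        offsets = {
            "narrow": {},
            "wide": {"al_l": (-3.0, 0, 0), "al_r": (3.0, 0, 0)},
        }
        lm = sim.simulate_landmarks(
            40, pop_offsets=offsets, noise_sd=0.1, n_observers=1, n_reps=1,
            seed=12, subject_sd=0.5,
        )
        traits = replicate_mean_traits(lm)
        traits = traits.merge(
            lm[["id", "population"]].drop_duplicates(), on="id"
        )
        means = traits.groupby("population")[
            ["nares_width", "alar_base_width"]
        ].mean()
        assert means.loc["wide", "nares_width"] - means.loc[
            "narrow", "nares_width"
        ] == pytest.approx(6.0, abs=0.5)
        assert means.loc["wide", "alar_base_width"] - means.loc[
            "narrow", "alar_base_width"
        ] == pytest.approx(0.0, abs=0.5)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            sim.simulate_landmarks(0)


class TestSimulateClimate:
    def _pheno(self):
        return pd.DataFrame(
            {"id": [f"i{k}" for k in range(6)],
             "population": ["a"] * 3 + ["b"] * 3}
        )

    def test_zero_spread_shares_population_values(self):
        clim = sim.simulate_climate(
            self._pheno(),
            {"a": {"temperature": 5.0}, "b": {"temperature": 25.0}},
            within_sd=0.0, seed=13,
        )
        assert clim["temperature"].tolist() == [5.0] * 3 + [25.0] * 3

    def test_within_spread_varies_around_mean(self):
        clim = sim.simulate_climate(
            self._pheno(),
            {"a": {"temperature": 5.0}, "b": {"temperature": 25.0}},
            within_sd=1.0, seed=13,
        )
        assert clim["temperature"].iloc[:3].std() > 0
        assert clim["temperature"].iloc[:3].mean() == pytest.approx(5.0, abs=2)

    def test_missing_population_rejected(self):
        with pytest.raises(ValueError, match="b"):
            sim.simulate_climate(
                self._pheno(), {"a": {"temperature": 5.0}}, seed=1
            )
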