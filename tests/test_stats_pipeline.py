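import math

import numpy as np
import pandas as pd
import pytest

from rheoflume.stats_pipeline import (
    ModelSpec,
    StatsError,
    default_model_spec,
    exclude_outliers,
    fit_lm,
    fit_temporal_smooth,
    planned_contrasts,
    select_model_aic,
)
from rheoflume.trajectory_metrics import TemporalProfile


def make_table(rng, n_per_cell=5, effects=None, sigma=1.0):
    """Factorial river x pool x generation table with known response effects.

    ``effects`` maps term -> additive contribution: callables of the row dict
    or constants keyed by factor levels.
    """
    effects = effects or {}
    rows = []
    i = 0
    for river in ("Aripo", "Turure"):
        for pool in ("Above", "Between", "Below"):
            for gen in ("F0", "F1"):
                for _ in range(n_per_cell):
                    row = dict(
                        trial_id=f"t{i:03d}", river=river, pool=pool, generation=gen,
                        mass_g=float(rng.normal(0.3, 0.1)),
                        mean_temp_c=float(rng.normal(23, 1)),
                    )
                    y = float(rng.normal(0, sigma))
                    for key, eff in effects.items():
                        if callable(eff):
                            y += eff(row)
                        else:
                            y += eff.get(row[key], 0.0)
                    row["net_displacement_cm"] = y
                    rows.append(row)
                    i += 1
    return pd.DataFrame(rows)


class TestExcludeOutliers:
    def test_fifteen_times_mean_is_excluded(self):
        t = pd.DataFrame(
            dict(trial_id=list("abcd"), net_displacement_cm=[10.0, 10.0, 10.0, 150.0])
        )
        kept, report = exclude_outliers(t, k=4)
        assert list(kept["trial_id"]) == ["a", "b", "c"]
        assert report["ratio"].iloc[0] == pytest.approx(15.0)

    def test_equal_responses_untouched(self):
        t = pd.DataFrame(dict(trial_id=list("abcd"), net_displacement_cm=[5.0] * 4))
        kept, report = exclude_outliers(t, k=4)
        assert len(kept) == 4 and report.empty

    def test_infinite_k_disables_filter(self):
        t = pd.DataFrame(
            dict(trial_id=list("abcd"), net_displacement_cm=[1.0, 1.0, 1.0, 1e6])
        )
        kept, _ = exclude_outliers(t, k=math.inf)
        assert len(kept) == 4

    def test_tiny_table_skipped_with_warning(self, caplog):
        t = pd.DataFrame(dict(trial_id=["a", "b"], net_displacement_cm=[1.0, 99.0]))
        with caplog.at_level("WARNING", logger="rheoflume.stats_pipeline"):
            kept, _ = exclude_outliers(t, k=4)
        assert len(kept) == 2
        assert "skipped" in caplog.text


class TestModelSelection:
    def test_empty_candidate_list_is_noop(self, rng):
        table = make_table(rng)
        spec = ModelSpec("net_displacement_cm", covariates=())
        assert select_model_aic(spec, table) == spec

    def test_strong_mass_effect_retained(self):
        kept = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table = make_table(rng, effects={"mass": lambda r: 10.0 * r["mass_g"]})
            spec = select_model_aic(default_model_spec("net_displacement_cm"), table)
            kept += "mass_g" in spec.covariates
        assert kept >= 18

    def test_null_covariates_usually_dropped(self):
        # the AIC <= rule drops a null 1-df covariate with P(chi2_1 <= 2) ~ 0.84
        drops = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            spec = select_model_aic(
                default_model_spec("net_displacement_cm"), make_table(rng)
            )
            drops += "mean_temp_c" not in spec.covariates
        assert drops >= 30 * 0.6

    def test_selected_aic_never_worse_than_full(self, rng):
        table = make_table(rng)
        full = default_model_spec("net_displacement_cm")
        reduced = select_model_aic(full, table)
        assert fit_lm(reduced, table).aic <= fit_lm(full, table).aic + 1e-9


class TestFitLm:
    def test_single_factor_f_equals_t_squared(self, rng):
        y = np.concatenate([rng.normal(0, 1, 10), rng.normal(1, 1, 10)])
        g = np.array(["Aripo"] * 10 + ["Turure"] * 10)
        table = pd.DataFrame(
            dict(
                trial_id=[f"t{i}" for i in range(20)], river=g,
                pool=["Above"] * 20, generation=["F0"] * 20,
                mass_g=0.3, mean_temp_c=23.0, net_displacement_cm=y,
            )
        )
        spec = ModelSpec("net_displacement_cm", covariates=())
        # pool/interaction are constant here -> fit river alone via a 1-factor table
        import statsmodels.formula.api as smf
        from scipy import stats as sps

        fit = smf.ols("net_displacement_cm ~ C(river)", table).fit()
        t_stat = sps.ttest_ind(y[g == "Aripo"], y[g == "Turure"]).statistic
        f_from_anova = float(
            __import__("statsmodels.stats.anova", fromlist=["anova_lm"])
            .anova_lm(fit, typ=2)
            .loc["C(river)", "F"]
        )
        assert f_from_anova == pytest.approx(t_stat**2)

    def test_constant_response_rejected(self, rng):
        table = make_table(rng)
        table["net_displacement_cm"] = 3.0
        with pytest.raises(StatsError, match="residual variance"):
            fit_lm(ModelSpec("net_displacement_cm", covariates=()), table)

    def test_log_transform_requires_positive_values(self, rng):
        table = make_table(rng)
        table["cumulative_upstream_cm"] = np.abs(table["net_displacement_cm"]) + 1
        table.loc[3, "cumulative_upstream_cm"] = 0.0
        with pytest.raises(StatsError, match="t003"):
            fit_lm(default_model_spec("cumulative_upstream_cm"), table)

    def test_shift_invariance_of_term_tests(self, rng):
        table = make_table(rng, effects={"river": {"Turure": 1.0}})
        spec = ModelSpec("net_displacement_cm", covariates=())
        a = fit_lm(spec, table)
        shifted = table.copy()
        shifted["net_displacement_cm"] += 100.0
        b = fit_lm(spec, shifted)
        pd.testing.assert_frame_equal(a.anova, b.anova, rtol=1e-8)

    def test_rank_deficiency_named(self, rng):
        table = make_table(rng)
        table["mean_temp_c"] = table["mass_g"] * 2  # aliased covariates
        with pytest.raises(StatsError, match="aliased"):
            fit_lm(default_model_spec("net_displacement_cm"), table)

    def test_sequential_and_marginal_agree_when_balanced(self, rng):
        table = make_table(rng, effects={"pool": {"Above": 2.0}})
        f1 = fit_lm(ModelSpec("net_displacement_cm", covariates=(), anova_type="sequential"), table)
        f2 = fit_lm(ModelSpec("net_displacement_cm", covariates=(), anova_type="marginal"), table)
        for term in ("C(pool)", "C(river)", "C(pool):C(river)"):
            assert f1.anova.loc[term, "F"] == pytest.approx(f2.anova.loc[term, "F"])


class TestPlannedContrasts:
    @staticmethod
    def cellmean_table(means, ns, rng):
        rows = []
        i = 0
        for mean, n, pool in zip(means, ns, ("Above", "Between", "Below")):
            for _ in range(n):
                rows.append(
                    dict(
                        trial_id=f"c{i}", river="Aripo" if i % 2 else "Turure",
                        pool=pool, generation="F0", mass_g=0.3, mean_temp_c=23.0,
                        net_displacement_cm=mean + float(rng.normal(0, 1)),
                    )
                )
                i += 1
        return pd.DataFrame(rows)

    def test_exact_cell_mean_arithmetic(self, rng):
        table = self.cellmean_table([10.0, 4.0, 4.0], [6, 6, 6], rng)
        # overwrite noise so the cell means are exact
        for pool, mean in zip(("Above", "Between", "Below"), (10.0, 4.0, 4.0)):
            table.loc[table["pool"] == pool, "net_displacement_cm"] = mean
        table.loc[0, "net_displacement_cm"] += 1e-3  # avoid zero residual variance
        fit = fit_lm(ModelSpec("net_displacement_cm", covariates=()), table)
        c1, c2 = planned_contrasts(fit, table)
        assert c1.estimate == pytest.approx(6.0, abs=1e-3)
        assert c2.estimate == pytest.approx(0.0, abs=1e-3)

    def test_symmetric_downstream_pools_null_second_contrast(self, rng):
        table = self.cellmean_table([7.0, 3.0, 3.0], [5, 8, 8], rng)
        for pool, mean in zip(("Above", "Between", "Below"), (7.0, 3.0, 3.0)):
            sel = table["pool"] == pool
            y = table.loc[sel, "net_displacement_cm"]
            table.loc[sel, "net_displacement_cm"] = y - y.mean() + mean
        fit = fit_lm(ModelSpec("net_displacement_cm", covariates=()), table)
        _, c2 = planned_contrasts(fit, table)
        assert c2.estimate == pytest.approx(0.0, abs=1e-9)

    def test_unbalanced_matches_matrix_algebra_oracle(self, rng):
        ns = [4, 7, 11]
        table = self.cellmean_table([2.0, -1.0, 0.5], ns, rng)
        fit = fit_lm(ModelSpec("net_displacement_cm", covariates=()), table)
        y = table["net_displacement_cm"].to_numpy()
        x = np.column_stack(
            [(table["pool"] == p).to_numpy(float) for p in ("Above", "Between", "Below")]
        )
        beta = np.linalg.solve(x.T @ x, x.T @ y)  # cell-means GLS oracle
        for (label, w), got in zip(
            ((None, (1.0, -0.5, -0.5)), (None, (0.0, 1.0, -1.0))),
            planned_contrasts(fit, table),
        ):
            w = np.asarray(w)
            assert got.estimate == pytest.approx(float(w @ beta))
            se = math.sqrt(fit.mse_resid * float(w @ np.linalg.inv(x.T @ x) @ w))
            assert got.se == pytest.approx(se)

    def test_weights_sum_to_zero_and_orthogonal(self, rng):
        table = self.cellmean_table([1.0, 2.0, 3.0], [6, 6, 6], rng)
        fit = fit_lm(ModelSpec("net_displacement_cm", covariates=()), table)
        c1, c2 = planned_contrasts(fit, table)
        assert sum(c1.weights) == 0 and sum(c2.weights) == 0
        assert np.dot(c1.weights, c2.weights) == 0

    def test_missing_pool_level_rejected(self, rng):
        table = self.cellmean_table([1.0, 2.0, 3.0], [6, 6, 0], rng)
        with pytest.raises(StatsError, match="Below"):
            fit = fit_lm(ModelSpec("net_displacement_cm", covariates=()), table)
            planned_contrasts(fit, table)


class TestTemporalSmoothApi:
    def test_profiles_must_share_grid(self):
        a = TemporalProfile("A", np.zeros(100), np.zeros(100), 1)
        b = TemporalProfile("B", np.zeros(90), np.zeros(90), 1)
        with pytest.raises(StatsError):
            fit_temporal_smooth([a, b])

    def test_result_fields(self, rng):
        n = 200
        t = np.arange(n)
        a = TemporalProfile("Aripo", 1.5 + 0.01 * t + rng.normal(0, 0.1, n), np.zeros(n), 5)
        b = TemporalProfile("Turure", 1.0 + 0.02 * t + rng.normal(0, 0.1, n), np.zeros(n), 5)
        res = fit_temporal_smooth([a, b], "zone", basis_dim=8, ar1=True)
        assert set(res.curves) == {"Aripo", "Turure"}
        assert -1 < res.ar1_rho < 1
        assert 0 <= res.river_p <= 1
        frames, fitted, lo, hi = res.curves["Aripo"]
        assert np.all(lo <= fitted) and np.all(fitted <= hi)
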