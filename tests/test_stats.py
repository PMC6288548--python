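import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from eventarena import (AgentParams, ModelSpec, RandomTerm, activity_models,
                        assemble_model_table, build_knowledge,
                        condition_block_anova, fit_lme, prune_random_effects,
                        rm_anova, schema_benefit_model, simulate_cohort,
                        simulate_roi_activity)
from eventarena import decompose_block1_cohort


def crossed_dataset(seed=0, nP=12, nR=20, slope_sd=0.2, beta=0.4,
                    resid_sd=0.4):
    rng = np.random.default_rng(seed)
    bP = rng.normal(0, 0.5, nP)
    bR = rng.normal(0, 0.3, nR)
    sP = rng.normal(0, slope_sd, nP)
    rows = []
    for i in range(nP):
        for j in range(nR):
            x = rng.normal()
            y = 1.0 + beta * x + bP[i] + bR[j] + sP[i] * x \
                + rng.normal(0, resid_sd)
            rows.append((f"p{i}", f"r{j}", x, y))
    return pd.DataFrame(rows, columns=["participant", "room", "x", "y"])


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------

class TestRmAnova:
    def test_two_levels_forces_epsilon_one(self):
        rng = np.random.default_rng(0)
        table = rng.normal(size=(10, 2)) + [0.0, 0.5]
        res = rm_anova(table)
        assert res.epsilon == pytest.approx(1.0)
        assert res.df1 == 1 and res.df2 == 9

    def test_epsilon_respects_analytic_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n, k = rng.integers(4, 11), rng.integers(2, 6)
            res = rm_anova(rng.normal(size=(n, k)))
            assert 1.0 / (k - 1) - 1e-12 <= res.epsilon <= 1.0 + 1e-12

    @pytest.mark.parametrize("shape", [(8, 4), (10, 5), (6, 3)])
    def test_matches_independent_oracle(self, shape):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(shape[0] * 100 + shape[1])
        table = rng.normal(size=shape) + rng.normal(0, 0.5, size=shape[1])
        res = rm_anova(table)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(shape[0]), shape[1]),
            "cond": np.tile(np.arange(shape[1]), shape[0]),
            "y": table.ravel()})
        aov = pingouin.rm_anova(data=long, dv="y", within="cond",
                                subject="subject", correction=True)
        assert res.F == pytest.approx(aov["F"].iloc[0], abs=1e-8)
        assert res.epsilon == pytest.approx(aov["eps"].iloc[0], abs=1e-8)
        assert res.p_corrected == pytest.approx(aov["p_GG_corr"].iloc[0],
                                                abs=1e-8)

    def test_missing_cells_rejected(self):
        table = np.random.default_rng(0).normal(size=(6, 4))
        table[2, 1] = np.nan
        with pytest.raises(ValueError):
            rm_anova(table)

    def test_condition_block_comparison_detects_faster_learning(self):
        rng = np.random.default_rng(3)
        opa = rng.normal(2.5, 0.2, size=(12, 2))
        npa = rng.normal(1.4, 0.2, size=(12, 2))
        out = condition_block_anova(opa, npa)
        assert out["condition"].p_corrected < 0.001


# ---------------------------------------------------------------------------
# Mixed-effects engine
# ---------------------------------------------------------------------------

class TestFitLme:
    def test_matches_lmer_satterthwaite_oracle(self, tmp_path):
        """Estimates, SEs, variance components and Satterthwaite df
        against R lme4/lmerTest on the same crossed-design data."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        data = crossed_dataset(seed=42)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lmerTest))
            d <- read.csv('{csv}')
            m <- lmer(y ~ x + (1|participant) + (1|room) +
                      (0+x|participant), data=d, REML=TRUE)
            s <- summary(m)$coefficients
            write.csv(s, '{tmp_path}/coef.csv')
        """))
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        oracle = pd.read_csv(tmp_path / "coef.csv", index_col=0)

        spec = ModelSpec(response="y", fixed=("x",),
                         random_slopes=(RandomTerm("participant", "x"),))
        res = fit_lme(data, spec)
        for term in ("(Intercept)", "x"):
            mine = res.term(term)
            ref = oracle.loc[term]
            assert mine["estimate"] == pytest.approx(ref["Estimate"],
                                                     rel=1e-4)
            assert mine["se"] == pytest.approx(ref["Std. Error"], rel=1e-3)
            assert mine["df"] == pytest.approx(ref["df"], rel=0.05)
            assert mine["p"] == pytest.approx(ref["Pr(>|t|)"], rel=0.05,
                                              abs=1e-6)

    def test_matches_statsmodels_estimates(self):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        data = crossed_dataset(seed=7, slope_sd=0.0)
        data["one"] = 1
        md = statsmodels.mixedlm(
            "y ~ x", data, groups="one",
            vc_formula={"participant": "0 + C(participant)",
                        "room": "0 + C(room)"})
        sm_res = md.fit(reml=True)
        spec = ModelSpec(response="y", fixed=("x",))
        res = fit_lme(data, spec)
        assert res.term("x")["estimate"] == pytest.approx(
            sm_res.params["x"], rel=1e-4)
        assert res.term("x")["se"] == pytest.approx(
            sm_res.bse["x"], rel=1e-3)

    def test_zero_group_variance_reduces_to_ols(self):
        rng = np.random.default_rng(12)
        n = 300
        data = pd.DataFrame({
            "participant": np.repeat([f"p{i}" for i in range(10)], 30),
            "room": np.tile([f"r{j}" for j in range(30)], 10),
            "x": rng.normal(size=n)})
        data["y"] = 2.0 + 0.7 * data["x"] + rng.normal(0, 0.5, n)
        res = fit_lme(data, ModelSpec(response="y", fixed=("x",)))
        X = np.column_stack([np.ones(n), data["x"]])
        ols = np.linalg.lstsq(X, data["y"], rcond=None)[0]
        assert res.term("(Intercept)")["estimate"] == pytest.approx(
            ols[0], abs=1e-4)
        assert res.term("x")["estimate"] == pytest.approx(ols[1], abs=1e-4)

    def test_single_level_grouping_rejected(self):
        data = crossed_dataset(seed=1).assign(participant="p0")
        with pytest.raises(ValueError, match="single level"):
            fit_lme(data, ModelSpec(response="y", fixed=("x",)))

    def test_rank_deficient_fixed_effects_rejected(self):
        data = crossed_dataset(seed=1)
        data["x2"] = 2 * data["x"]
        with pytest.raises(ValueError, match="rank"):
            fit_lme(data, ModelSpec(response="y", fixed=("x", "x2")))

    def test_type_one_error_calibrated_small(self):
        """Quick null calibration on 60 replicates (the full 200-replicate
        study-scale calibration lives in the acceptance suite)."""
        hits = 0
        for rep in range(60):
            data = crossed_dataset(seed=10_000 + rep, beta=0.0,
                                   slope_sd=0.0, nP=10, nR=12)
            res = fit_lme(data, ModelSpec(response="y", fixed=("x",)))
            hits += res.term("x")["p"] < 0.05
        assert hits / 60 <= 0.14

    def test_parameter_recovery_within_two_se(self):
        inside = 0
        for rep in range(30):
            data = crossed_dataset(seed=20_000 + rep, beta=0.4, slope_sd=0.0)
            res = fit_lme(data, ModelSpec(response="y", fixed=("x",)))
            row = res.term("x")
            inside += abs(row["estimate"] - 0.4) <= 2 * row["se"]
        assert inside / 30 >= 0.9


class TestPruning:
    def test_well_conditioned_maximal_model_keeps_slopes(self):
        data = crossed_dataset(seed=3, slope_sd=0.6, resid_sd=0.3)
        spec = ModelSpec(response="y", fixed=("x",),
                         random_slopes=(RandomTerm("participant", "x"),))
        final, res = prune_random_effects(data, spec)
        assert res.pruning_trace == ()
        assert len(final.random_slopes) == 1

    def test_zero_slope_variance_pruned_intercepts_kept(self):
        data = crossed_dataset(seed=2, slope_sd=0.0, nP=6, nR=6)
        spec = ModelSpec(response="y", fixed=("x",),
                         random_slopes=(RandomTerm("participant", "x"),))
        final, res = prune_random_effects(data, spec)
        assert "(0+x|participant)" in res.pruning_trace
        assert final.random_slopes == ()
        assert set(final.random_intercepts) == {"participant", "room"}

    def test_interaction_slopes_pruned_first(self):
        data = crossed_dataset(seed=2, slope_sd=0.0, nP=6, nR=6)
        data["z"] = np.random.default_rng(0).normal(size=len(data))
        spec = ModelSpec(
            response="y", fixed=("x", "z", "x:z"),
            random_slopes=(RandomTerm("participant", "x"),
                           RandomTerm("participant", "z"),
                           RandomTerm("participant", "x:z",
                                      is_interaction=True)))
        final, res = prune_random_effects(data, spec)
        if len(res.pruning_trace) >= 2:
            assert res.pruning_trace[0] == "(0+x:z|participant)"

    def test_pruning_is_deterministic(self):
        data = crossed_dataset(seed=3, slope_sd=0.0, nP=6, nR=6)
        spec = ModelSpec(response="y", fixed=("x",),
                         random_slopes=(RandomTerm("participant", "x"),))
        t1 = prune_random_effects(data, spec)[1].pruning_trace
        t2 = prune_random_effects(data, spec)[1].pruning_trace
        assert t1 == t2


# ---------------------------------------------------------------------------
# Paradigm-level models
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort_table():
    params = AgentParams(seed=18, coupling_beta=0.8)
    df = simulate_cohort(16, 36, params, seed=18)
    kdf = build_knowledge(df)
    b1 = decompose_block1_cohort(df)
    npa2 = df[(df["phase"] == "NPA") & (df["block"] == 2)]
    return assemble_model_table(kdf, b1, npa2), df


class TestSchemaBenefitModel:
    def test_positive_coupling_recovered(self, cohort_table):
        table, _ = cohort_table
        res = schema_benefit_model(table, "recent")
        row = res.term("opa_recent")
        assert row["estimate"] > 0
        assert row["p"] < 0.05

    def test_prior_toggle_changes_predictor_only(self, cohort_table):
        table, _ = cohort_table
        res = schema_benefit_model(table, "average")
        assert "opa_average" in res.coef.index
        assert "opa_recent" not in res.coef.index
        assert {"lucky", "residual_pe"} <= set(res.coef.index)

    def test_unknown_prior_rejected(self, cohort_table):
        table, _ = cohort_table
        with pytest.raises(ValueError):
            schema_benefit_model(table, "median")


class TestActivityModels:
    def test_activity_coupling_recovered(self, cohort_table):
        table, df = cohort_table
        act = simulate_roi_activity(df, activity_beta=0.8, noise_sd=0.6,
                                    seed=5, roi_label="hippocampus_body")
        out = activity_models(table, act)
        row = out["hippocampus_body"].term("value")
        assert row["estimate"] < 0  # higher activity -> lower (better) PE
        assert row["p"] < 0.05

    def test_activity_sign_recovered_across_replicates(self):
        """A moderate activity->performance coupling has its sign
        recovered in nearly all replicate cohorts."""
        correct = 0
        n_reps = 25
        for rep in range(n_reps):
            params = AgentParams(seed=70_000 + rep)
            df = simulate_cohort(16, 36, params, seed=70_000 + rep)
            kdf = build_knowledge(df)
            b1 = decompose_block1_cohort(df)
            npa2 = df[(df["phase"] == "NPA") & (df["block"] == 2)]
            table = assemble_model_table(kdf, b1, npa2)
            act = simulate_roi_activity(df, activity_beta=0.5, noise_sd=1.0,
                                        seed=rep)
            merged = table.merge(act[["participant", "room", "value"]],
                                 on=["participant", "room"])
            spec = ModelSpec(response="npa2_pe",
                             fixed=("value", "lucky", "residual_pe"))
            res = fit_lme(merged, spec, compute_df=False)
            correct += res.term("value")["estimate"] < 0
        assert correct / n_reps >= 0.9

    def test_permuted_activity_is_null(self, cohort_table):
        table, df = cohort_table
        act = simulate_roi_activity(df, activity_beta=0.8, noise_sd=0.6,
                                    seed=6)
        act = act.assign(value=np.random.default_rng(0).permutation(
            act["value"].to_numpy()))
        out = activity_models(table, act)
        assert out["roi"].term("value")["p"] > 0.05

    def test_omnibus_recovers_both_signals(self, cohort_table):
        table, df = cohort_table
        act = simulate_roi_activity(df, activity_beta=1.0, noise_sd=0.5,
                                    seed=7)
        out = activity_models(table, act, omnibus=True)
        res = out["roi"]
        assert res.term("value")["estimate"] < 0
        assert "opa_recent" in res.coef.index

    def test_reverse_model_includes_interaction(self, cohort_table):
        table, df = cohort_table
        act = simulate_roi_activity(df, activity_beta=0.5, seed=8)
        out = activity_models(table, act, reverse=True,
                              which_prior="average")
        res = out["roi"]
        assert "opa_average:residual_pe" in res.coef.index
        assert res.spec.response == "value"

    def test_roi_with_missing_trials_skipped(self, cohort_table):
        table, df = cohort_table
        act = simulate_roi_activity(df, activity_beta=0.5, seed=9)
        act = act.iloc[:-5]
        with pytest.warns(UserWarning, match="missing trials"):
            out = activity_models(table, act)
        assert out == {}
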