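"""Group-level models: recovery, calibration, FDR, degenerate inputs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from singtrack.stats import (
    BetaMixedModel,
    adjust_proportions,
    fdr_correct,
    fit_accuracy_model,
    fit_acoustic_models,
    fit_movement_model,
    fit_vocabulary_models,
)
from singtrack.synth import BehaviorSpec, make_cohort_accuracy, make_dyad_table


def bh_oracle(p):
    """Direct Benjamini–Hochberg step-up recursion."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        val = min(prev, p[idx] * m / rank)
        q[idx] = val
        prev = val
    return q


class TestFDR:
    def test_printed_examples(self):
        assert fdr_correct([0.03]) == pytest.approx([0.03])
        assert fdr_correct([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert fdr_correct([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_validation(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_correct([-0.1])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_step_up_oracle_and_dominates_p(self, p):
        q = fdr_correct(p)
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)
        # monotone nondecreasing in p-rank
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestAccuracyModel:
    def test_interaction_power_on_builtin_effects(self):
        """True>shifted with a lullaby>playsong gap only in the true pairing:
        the song-type x data-type interaction is detected in >=80% of 100
        cohorts of 30 dyads."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            table = make_cohort_accuracy(30, channels=4, seed=rep)
            report = fit_accuracy_model(table, channel_mode="mean")
            p = report.lrt.set_index("term").loc["condition:data_type", "p"]
            hits += p < 0.05
        assert hits / n_rep >= 0.80

    def test_zero_effect_cohort_calibrated(self):
        """With no condition or pairing effects the fixed-effect CIs cover 0
        in >=90% of replicates."""
        covered = []
        n_rep = 100
        for rep in range(n_rep):
            table = make_cohort_accuracy(
                30,
                channels=2,
                true_mean={"lullaby": 0.0, "playsong": 0.0},
                shifted_mean=0.0,
                seed=10_000 + rep,
            )
            report = fit_accuracy_model(table, channel_mode="mean")
            params = report.params.drop(index="Intercept", errors="ignore")
            slopes = params.loc[[i for i in params.index if "Group" not in i]]
            covered.append(((slopes["ci_low"] <= 0) & (slopes["ci_high"] >= 0)).to_numpy())
        # each fixed effect's 95% CI covers 0 in >= 90% of replicates
        assert np.vstack(covered).mean(axis=0).min() >= 0.90

    def test_constant_data_type_is_informative_error(self):
        table = make_cohort_accuracy(8, channels=2, seed=0)
        table = table[table["data_type"] == "true"]
        with pytest.raises(ValueError, match="data_type"):
            fit_accuracy_model(table)

    def test_posthoc_contrasts_recover_generator_gaps(self):
        table = make_cohort_accuracy(60, channels=4, seed=7)
        report = fit_accuracy_model(table, channel_mode="mean")
        contrasts = report.contrasts.set_index("name")
        # true-pairing mean near (0.074 + 0.057)/2, shifted near 0.001
        assert contrasts.loc["true-shifted", "estimate"] == pytest.approx(0.0645, abs=0.01)
        assert contrasts.loc["lullaby-playsong|true", "estimate"] == pytest.approx(
            0.017, abs=0.008
        )
        assert contrasts.loc["lullaby-playsong|true", "p"] < 0.05
        assert contrasts.loc["lullaby-playsong|shifted", "p"] > 0.05

    def test_channel_factor_variant_runs(self):
        table = make_cohort_accuracy(12, channels=3, seed=3)
        report = fit_accuracy_model(table, channel_mode="factor")
        assert report.converged
        assert any("channel" in str(ix) for ix in report.params.index)

    def test_order_invariance(self):
        table = make_cohort_accuracy(15, channels=2, seed=9)
        r1 = fit_accuracy_model(table, channel_mode="mean")
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        r2 = fit_accuracy_model(shuffled, channel_mode="mean")
        assert np.allclose(r1.params["estimate"], r2.params["estimate"], atol=1e-8)


class TestAcousticModels:
    def test_negative_rms_slope_recovered_in_playsong_only(self):
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            table = make_cohort_accuracy(
                40,
                channels=2,
                acoustic_effects={("rms_mean", "playsong"): -0.02},
                seed=100 + rep,
            )
            means_report, _ = fit_acoustic_models(table)
            trends = means_report.contrasts.set_index("name")
            tr = trends.loc["trend[rms_mean|playsong]"]
            hits += (tr["estimate"] < 0) and (tr["ci_high"] < 0)
        assert hits / n_rep > 0.5

    def test_uncorrelated_feature_trend_covers_zero(self):
        covered = 0
        n_rep = 10
        for rep in range(n_rep):
            table = make_cohort_accuracy(30, channels=2, seed=300 + rep)
            means_report, _ = fit_acoustic_models(table)
            tr = means_report.contrasts.set_index("name").loc["trend[pitch_hz|lullaby]"]
            covered += tr["ci_low"] <= 0 <= tr["ci_high"]
        assert covered / n_rep >= 0.7

    def test_constant_features_dropped_with_warning(self):
        table = make_cohort_accuracy(10, channels=2, seed=5)
        for col in ("tempo_bpm", "pitch_hz", "pulse_clarity", "rms_mean",
                    "tempo_sd", "pitch_sd", "pulse_clarity_sd", "rms_sd"):
            table[col] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            means_report, sd_report = fit_acoustic_models(table)
        assert means_report.contrasts.empty
        assert any("constant" in n for n in means_report.notes)

    def test_sd_model_uses_sd_columns(self):
        table = make_cohort_accuracy(15, channels=2, seed=6)
        _, sd_report = fit_acoustic_models(table)
        assert "tempo_sd" in sd_report.formula


class TestBetaGLMM:
    def test_requires_open_interval(self):
        with pytest.raises(ValueError, match="strictly"):
            BetaMixedModel(
                np.array([0.0, 0.5]), np.ones((2, 1)), np.array([0, 1])
            )

    def test_boundary_adjustment(self):
        y = np.array([0.0, 0.2, 1.0, 0.4])
        adj, changed = adjust_proportions(y)
        assert changed
        assert np.all((adj > 0) & (adj < 1))
        n = y.size
        assert adj[0] == pytest.approx(0.5 / n)
        same, changed2 = adjust_proportions(np.array([0.2, 0.4]))
        assert not changed2 and np.array_equal(same, [0.2, 0.4])

    def test_recovers_condition_effect(self):
        table = make_dyad_table(60, BehaviorSpec(seed=0), seed=3)
        report = fit_movement_model(table)
        assert report.family == "beta-glmm"
        est = report.contrasts.iloc[0]
        # generator: playsong 0.3 vs lullaby 0.1 -> logit gap ~ +1.35
        assert est["estimate"] == pytest.approx(1.35, abs=0.4)
        assert report.lrt.iloc[-1]["p"] < 0.05

    def test_equal_means_calibrated(self):
        spec = BehaviorSpec(movement_mean={"playsong": 0.2, "lullaby": 0.2}, seed=0)
        covered = 0
        n_rep = 100
        for rep in range(n_rep):
            table = make_dyad_table(40, spec, seed=rep)
            report = fit_movement_model(table)
            est = report.contrasts.iloc[0]
            covered += est["ci_low"] <= 0 <= est["ci_high"]
        assert covered / n_rep >= 0.90

    def test_boundary_proportion_handled_in_model(self):
        table = make_dyad_table(12, BehaviorSpec(seed=1), seed=2)
        table.loc[0, "movement_prop"] = 0.0
        report = fit_movement_model(table)
        assert any("adjusted" in n for n in report.notes)

    def test_study_interaction_variant(self):
        t1 = make_dyad_table(12, BehaviorSpec(seed=2), seed=3, study=1)
        t2 = make_dyad_table(12, BehaviorSpec(seed=3), seed=4, study=2)
        t2["dyad_id"] = "S2" + t2["dyad_id"]
        report = fit_movement_model(pd.concat([t1, t2], ignore_index=True))
        assert "study" in report.formula
        assert {"condition", "condition:study"} <= set(report.lrt["term"])


class TestVocabularyModels:
    def _table(self, slope, seed, n=40):
        rng = np.random.default_rng(seed)
        # small dyad intercepts: shared dyad variance would otherwise bleed a
        # playsong-only vocabulary effect into the lullaby trend estimate
        acc = make_cohort_accuracy(n, channels=2, dyad_sd=0.003, seed=seed)
        vocab_z = rng.standard_normal(n)
        dyads = sorted(acc["dyad_id"].unique())
        vmap = dict(zip(dyads, np.rint(150 * np.exp(0.3 * vocab_z)).astype(int)))
        acc["vocabulary"] = acc["dyad_id"].map(vmap)
        vz = (acc["vocabulary"] - acc["vocabulary"].mean()) / acc["vocabulary"].std()
        play_true = (acc["condition"] == "playsong") & (acc["data_type"] == "true")
        acc.loc[play_true, "z_accuracy"] += slope * vz[play_true]
        table = make_dyad_table(n, BehaviorSpec(seed=seed), seed=seed)
        acc = acc.merge(table[["dyad_id", "condition", "movement_prop"]],
                        on=["dyad_id", "condition"])
        return acc

    def test_playsong_only_slope_recovered(self):
        table = self._table(slope=0.03, seed=0)
        tracking, _ = fit_vocabulary_models(table, which="tracking")
        trends = tracking.contrasts.set_index("name")
        play = trends.loc["trend[vocabulary|playsong]"]
        lull = trends.loc["trend[vocabulary|lullaby]"]
        assert play["estimate"] > 0 and play["ci_low"] > 0
        assert lull["ci_low"] <= 0 <= lull["ci_high"]

    def test_zero_slope_interaction_calibrated(self):
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            table = self._table(slope=0.0, seed=500 + rep)
            tracking, _ = fit_vocabulary_models(table, which="tracking")
            hits += tracking.lrt.iloc[0]["p"] < 0.05
        assert hits / n_rep <= 0.15  # ~alpha with binomial slack

    def test_movement_side_fits(self):
        table = self._table(slope=0.0, seed=77)
        tracking, movement = fit_vocabulary_models(table)
        assert movement.family == "beta-glmm"
        assert len(movement.contrasts) == 2

    def test_all_missing_refused(self):
        table = self._table(slope=0.0, seed=3)
        table["vocabulary"] = np.nan
        with pytest.raises(ValueError, match="vocabulary"):
            fit_vocabulary_models(table)

    def test_too_few_complete_cases_refused(self):
        table = self._table(slope=0.0, seed=4, n=10)
        keep = table["dyad_id"].isin(sorted(table["dyad_id"].unique())[:3])
        table.loc[~keep, "vocabulary"] = np.nan
        with pytest.raises(ValueError, match="5 dyads"):
            fit_vocabulary_models(table)
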