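import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import guildnet as gn
from guildnet.evaluate import CVSpec, assign_folds, report_table, summarize_report


def brute_force_auc(labels, scores):
    """Pair-counting oracle: fraction of positive-negative pairs ranked
    correctly, ties counting one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        assert gn.compute_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_complete_tie(self):
        assert gn.compute_auc([0, 1], [0.5, 0.5]) == 0.5

    def test_small_example_against_pair_counting(self):
        labels, scores = [0, 1, 0, 1], [0.4, 0.3, 0.2, 0.6]
        expected = brute_force_auc(labels, scores)
        assert expected == 0.75
        assert gn.compute_auc(labels, scores) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 50))
    def test_matches_pair_counting_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        labels = np.zeros(n, int)
        labels[: rng.integers(1, n)] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid forces ties
        assert gn.compute_auc(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            gn.compute_auc([1, 1, 1], [0.1, 0.5, 0.9])


class TestR2:
    def test_perfect_prediction(self):
        assert gn.compute_r2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        assert gn.compute_r2([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_anti_prediction_is_negative(self):
        assert gn.compute_r2([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == pytest.approx(-3.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            gn.compute_r2([1.0, 2.0], [1.0, 2.0])


class TestFolds:
    def test_study_size_splits_evenly(self):
        folds = assign_folds(118, 2, seed=1)
        assert sorted(np.bincount(folds)) == [59, 59]

    def test_seeded_assignment_is_stable(self):
        assert np.array_equal(assign_folds(50, 2, 7), assign_folds(50, 2, 7))
        assert not np.array_equal(assign_folds(50, 2, 7), assign_folds(50, 2, 8))


class TestConditionalPrediction:
    def test_empty_conditioning_set_equals_unconditional(self, small_fit, small_design):
        """Conditioning on nothing must reproduce the covariate-only
        prediction up to Monte-Carlo error."""
        pu, au = small_fit.predict_unconditional(small_design, seed=1, n_eta=4)
        focal = np.ones(small_fit.p_, bool)  # every species focal -> no conditioning data
        n = small_design.values.shape[0]
        pc, ac = small_fit.predict_conditional(
            small_design, np.zeros((n, small_fit.p_)), np.full((n, small_fit.p_), np.nan),
            focal, outer_draws=80, inner_burn=0, inner_draws=10, seed=2)
        assert np.abs(pu - pc).mean() < 0.01
        assert np.abs(pu - pc).max() < 0.06

    def test_zero_information_nonfocal_changes_nothing(self, small_design, small_response):
        """If the non-focal species carry (almost) no loading on the shared
        factors, their data cannot inform the focal predictions."""
        cfg = gn.SimulationConfig(n_samples=60, n_species_fungi=8, n_species_bacteria=8,
                                  n_factors=1, loading_scale_fungi=0.0,
                                  loading_scale_bacteria=0.0, seed=17)
        study = gn.simulate_community(cfg)
        resp = gn.concat_hurdle_responses(
            *[gn.assemble_hurdle_response(study.tables[g]) for g in ("fungi", "bacteria")])
        design = gn.build_joint_design(study.metadata, "full")
        fit = gn.HurdleLatentFactorJSDM(n_factors=1, n_chains=1, n_iter=800, n_burn=300,
                                        thin=5, random_state=3).fit(design, resp)
        focal = (resp.guild == "bacteria").to_numpy()
        pu, _ = fit.predict_unconditional(design, seed=4, n_eta=4)
        pc, _ = fit.predict_conditional(design, resp.pa.to_numpy(), resp.abund.to_numpy(),
                                        focal, outer_draws=60, inner_burn=10,
                                        inner_draws=15, seed=5)
        assert np.abs(pu[:, focal] - pc).mean() < 0.03


class TestEvaluationReports:
    @pytest.fixture(scope="class")
    def small_eval(self, small_study, small_response):
        est = gn.HurdleLatentFactorJSDM(n_factors=2, n_chains=1, n_iter=600, n_burn=200,
                                        thin=5, random_state=19)
        cv = CVSpec(seed=23, outer_draws=20, inner_burn=10, inner_draws=20)
        return gn.evaluate_models(small_study.metadata, small_response,
                                  models=("full",), cv=cv, estimator=est)

    def test_report_is_tidy_and_complete(self, small_eval):
        assert set(small_eval.columns) == {"model", "regime", "otu", "guild", "part",
                                           "metric", "value"}
        assert set(small_eval["regime"]) == {"explanatory", "unconditional", "conditional"}
        assert set(small_eval["metric"]) == {"auc", "r2"}

    def test_explanatory_beats_unconditional_occurrence(self, small_eval):
        s = summarize_report(small_eval)
        occ = s[(s.part == "occurrence")].pivot_table(index="guild", columns="regime",
                                                      values="value")
        assert (occ["explanatory"] > occ["unconditional"]).all()

    def test_auc_bounds(self, small_eval):
        auc = small_eval[small_eval.metric == "auc"]["value"]
        assert ((auc >= 0) & (auc <= 1)).all()

    def test_directionality_gain_layout(self, small_eval):
        gains = gn.directionality_gain(small_eval)
        assert {"guild", "part", "metric", "conditional_gain"} <= set(gains.columns)
        assert len(gains[gains.part == "occurrence"]) == 2

    def test_report_table_handles_missing_regime(self, small_eval):
        partial = small_eval[small_eval.regime != "conditional"]
        table = report_table(partial)
        assert table["conditional"].isna().all()
        assert table["explanatory"].notna().all()


class TestDiversityDiagnostics:
    def test_identical_tables_have_unit_beta_correlation(self, small_study):
        tf = small_study.tables["fungi"]
        tb = gn.CommunityTable(tf.counts.copy(), guild="bacteria")
        out = gn.diversity_diagnostics(tf, tb, permutations=99)
        assert out["beta_diversity_correlation"]["r"] == pytest.approx(1.0)

    def test_depth_confounded_richness_is_corrected(self):
        """Richness proportional to depth in both guilds, otherwise
        independent: raw correlation is positive, residual correlation near 0."""
        rng = np.random.default_rng(31)
        n, p = 80, 40
        depth_scale = rng.uniform(0.2, 1.0, n)
        tables = {}
        for guild in ("fungi", "bacteria"):
            occupancy = rng.random((n, p)) < depth_scale[:, None] * 0.9
            counts = occupancy * rng.integers(1, 50, (n, p))
            counts[:, 0] += 1
            tables[guild] = gn.CommunityTable(
                pd.DataFrame(counts, index=[f"s{i}" for i in range(n)]), guild)
        out = gn.diversity_diagnostics(tables["fungi"], tables["bacteria"], permutations=99)
        assert out["richness_raw_correlation"]["r"] > 0.3
        assert abs(out["richness_residual_correlation"]["r"]) < 0.25

    def test_mismatched_samples_rejected(self, small_study):
        tf = small_study.tables["fungi"]
        tb = small_study.tables["bacteria"]
        shuffled = gn.CommunityTable(tb.counts.iloc[::-1], "bacteria")
        with pytest.raises(ValueError, match="same samples"):
            gn.diversity_diagnostics(tf, shuffled)
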