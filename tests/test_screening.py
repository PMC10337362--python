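import numpy as np
import pandas as pd
import pytest

from tmtrace import (
    anova_screen,
    assemble_feature_table,
    cross_validate_table,
    evaluate_holdout,
    extract_all_keypoints,
    feature_group,
    fit_model,
    fit_templates,
    grouped_importance,
)
from tmtrace.screening import normalize_task, table_labels


@pytest.fixture(scope="module")
def cohort_templates(small_cohort):
    records, _ = small_cohort
    keypoints = extract_all_keypoints(records, seed=0)
    templates = fit_templates(
        [r for r in records if r.group == "HC"], seed=0, keypoints=keypoints
    )
    return records, keypoints, templates


class TestAssembleFeatureTable:
    def test_conventional_columns(self, cohort_templates):
        records, _, _ = cohort_templates
        table = assemble_feature_table(records, feature_set="conventional")
        cols = set(table.columns) - {"group"}
        assert sum(c.startswith("completion_") for c in cols) == 4
        assert {"sex", "age", "education"} <= cols
        assert sum(c.startswith(("errors", "penup", "prompts")) for c in cols) == 6
        assert len(cols) == 13

    def test_proposed_has_no_interaction_counts(self, cohort_templates):
        records, keypoints, templates = cohort_templates
        table = assemble_feature_table(
            records, templates, "proposed", keypoints=keypoints
        )
        assert not any(
            c.startswith(("errors", "penup", "prompts")) for c in table.columns
        )
        for pre in ("completion_", "prep_", "exec_", "pmean_", "pmin_", "pmax_",
                    "jerk_", "tmpl_dtwd_", "tmpl_vq_", "tmpl_vqw_"):
            assert sum(c.startswith(pre) for c in table.columns) >= 4
        assert {"tdiff_A2B2", "tratio_A2B2", "sex", "age", "education"} <= set(
            table.columns
        )

    def test_followup_mode_drops_identity_columns(self, cohort_templates):
        records, keypoints, templates = cohort_templates
        table = assemble_feature_table(
            records, templates, "proposed", followup_mode=True, keypoints=keypoints
        )
        assert not {"sex", "age", "education"} & set(table.columns)

    def test_missing_block_flags_not_fails(self, cohort_templates):
        records, keypoints, templates = cohort_templates
        partial = records[0]
        partial = type(partial)(
            subject_id="partial", group=partial.group,
            trajectories={("A", 2): partial.trajectories[("A", 2)]},
        )
        table = assemble_feature_table(
            [partial], templates, "proposed", keypoints=keypoints
        )
        assert np.isnan(table.loc["partial", "completion_B2"])
        assert not np.isnan(table.loc["partial", "completion_A2"])

    def test_templates_required_for_proposed(self, cohort_templates):
        records, _, _ = cohort_templates
        with pytest.raises(ValueError, match="template"):
            assemble_feature_table(records, None, "proposed")


class TestAnovaScreen:
    def test_worked_two_group_example(self):
        """Groups [1,2,3] vs [2,3,4]: SSB=1.5, SSW=4 over df (1,4) gives
        F = 1.5, p = 1 - CDF_F(1,4)(1.5) ~ 0.2879."""
        table = pd.DataFrame(
            {"group": ["HC"] * 3 + ["AD"] * 3, "feat": [1, 2, 3, 2, 3, 4]}
        )
        out = anova_screen(table)
        assert out.loc["feat", "F_HC_vs_AD"] == pytest.approx(1.5, abs=1e-12)
        assert out.loc["feat", "p_HC_vs_AD"] == pytest.approx(0.28786, abs=1e-4)

    def test_identical_groups_give_p_near_one(self):
        table = pd.DataFrame(
            {"group": ["HC"] * 3 + ["AD"] * 3, "feat": [1, 2, 3, 1, 2, 3]}
        )
        out = anova_screen(table)
        assert out.loc["feat", "p_HC_vs_AD"] > 0.99

    def test_degenerate_zero_variance_marked(self):
        table = pd.DataFrame(
            {"group": ["HC"] * 3 + ["AD"] * 3, "feat": [5.0] * 6}
        )
        out = anova_screen(table)
        assert np.isnan(out.loc["feat", "p_HC_vs_AD"])

    def test_all_pairs_reported(self, cohort_templates):
        records, keypoints, templates = cohort_templates
        table = assemble_feature_table(
            records, templates, "proposed", keypoints=keypoints
        )
        out = anova_screen(table)
        for pair in ("HC_vs_MCI", "HC_vs_AD", "MCI_vs_AD"):
            assert f"p_{pair}" in out.columns
        # simulated pressure separates the groups sharply
        assert out.loc["pmean_A2", "p_HC_vs_AD"] < 1e-4

    def test_bh_extension_columns(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        table["group"] = ["HC"] * 10 + ["AD"] * 10
        out = anova_screen(table, bh_correct=True)
        assert "p_bh_HC_vs_AD" in out.columns
        assert np.all(
            out["p_bh_HC_vs_AD"].to_numpy() >= out["p_HC_vs_AD"].to_numpy() - 1e-12
        )


def _toy_table(n=60, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["HC"] * (n // 2) + ["AD"] * (n // 2))
    X = pd.DataFrame(rng.normal(size=(n, 5)), columns=[f"noise{i}" for i in range(5)])
    if informative:
        X["completion_B2"] = np.where(y == "AD", 5.0, 0.0) + rng.normal(0, 0.1, n)
    X["group"] = y
    X.index = [f"s{i:03d}" for i in range(n)]
    X.index.name = "subject_id"
    return X


class TestCrossValidateTable:
    def test_separable_features_classify_perfectly(self):
        rep = cross_validate_table(_toy_table(), "hc-vs-ad", folds=5, seed=1)
        assert rep.accuracy == 1.0 and rep.auc == 1.0

    def test_metrics_bounded_and_fold_means(self):
        rep = cross_validate_table(_toy_table(informative=False), "hc-vs-ad",
                                   folds=5, seed=1)
        pf = rep.per_fold
        assert len(pf) == 5
        for m in ("accuracy", "auc", "sensitivity", "specificity"):
            assert 0 <= getattr(rep, m) <= 1
            assert getattr(rep, m) == pytest.approx(pf[m].mean())

    def test_deterministic_for_fixed_seed(self):
        a = cross_validate_table(_toy_table(), "hc-vs-ad", folds=5, seed=7)
        b = cross_validate_table(_toy_table(), "hc-vs-ad", folds=5, seed=7)
        assert a.as_dict() == b.as_dict()

    def test_class_smaller_than_folds_rejected(self):
        t = _toy_table(n=8)
        with pytest.raises(ValueError, match="folds"):
            cross_validate_table(t, "hc-vs-ad", folds=5, seed=0)

    @pytest.mark.parametrize("model", ["svc", "adaboost", "gbdt", "lightgbm"])
    def test_model_zoo_runs(self, model):
        rep = cross_validate_table(_toy_table(n=30), "hc-vs-ad", model=model,
                                   folds=3, seed=0)
        assert 0 <= rep.accuracy <= 1

    def test_positive_class_is_more_impaired(self):
        """All-AD predictions have sensitivity 1 and specificity 0."""
        t = _toy_table()
        X, y = table_labels(t, "hc-vs-ad")
        assert set(t.loc[y == 1, "group"].index) == set(
            t[t.group == "AD"].index
        )


class TestHoldout:
    def test_resubstitution_sanity(self):
        t = _toy_table()
        fitted = fit_model(t, "hc-vs-ad", seed=0)
        rep = evaluate_holdout(fitted, t)
        assert rep.accuracy >= 0.99

    def test_ad_vs_others_relabels(self):
        rng = np.random.default_rng(1)
        t = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        t["group"] = ["HC"] * 10 + ["MCI"] * 10 + ["AD"] * 10
        fitted = fit_model(t, "ad-vs-others", seed=0)
        X, y = table_labels(t, "ad-vs-others")
        assert y.sum() == 10 and len(y) == 30

    def test_column_mismatch_rejected(self):
        t = _toy_table()
        fitted = fit_model(t, "hc-vs-ad", seed=0)
        with pytest.raises(ValueError, match="columns"):
            evaluate_holdout(fitted, t.drop(columns=["noise0"]))

    def test_distributional_stability(self, small_cohort):
        """A follow-up cohort drawn from the same generative profiles scores
        close to the training cohort."""
        from tmtrace import simulate_cohort

        records, _ = small_cohort
        follow, _ = simulate_cohort({"HC": 8, "MCI": 8, "AD": 8}, seed=77)
        keypoints = extract_all_keypoints(records + follow, seed=0)
        templates = fit_templates(
            [r for r in records if r.group == "HC"], seed=0, keypoints=keypoints
        )
        kw = dict(feature_set="proposed", followup_mode=True, keypoints=keypoints)
        train = assemble_feature_table(records, templates, **kw)
        test = assemble_feature_table(follow, templates, **kw)
        fitted = fit_model(train, "hc-vs-ad", seed=0)
        rep = evaluate_holdout(fitted, test)
        assert rep.accuracy >= 0.8


class TestGroupedImportance:
    def test_planted_feature_ranks_first(self):
        t = _toy_table(n=80, seed=3)
        fitted = fit_model(t, "hc-vs-ad", seed=0)
        imp = grouped_importance(fitted, t)
        assert imp.backend == "tree"
        assert imp.per_feature.index[0] == "completion_B2"

    def test_constant_feature_near_zero(self):
        t = _toy_table(n=40, seed=4)
        t["const"] = 1.0
        fitted = fit_model(t, "hc-vs-ad", seed=0)
        imp = grouped_importance(fitted, t)
        assert imp.per_feature["const"] < 1e-12

    def test_group_aggregates_sum_exactly(self):
        t = _toy_table(n=40, seed=5)
        fitted = fit_model(t, "hc-vs-ad", seed=0)
        imp = grouped_importance(fitted, t)
        assert imp.per_group.sum() == pytest.approx(imp.per_feature.sum(), abs=0)
        grp = imp.per_feature.groupby(
            imp.per_feature.index.map(feature_group)
        ).sum()
        for g, v in imp.per_group.items():
            assert v == grp[g]

    def test_permutation_backend_for_svc(self):
        t = _toy_table(n=40, seed=6)
        fitted = fit_model(t, "hc-vs-ad", model="svc", seed=0)
        imp = grouped_importance(fitted, t, seed=0)
        assert imp.backend == "permutation"
        assert imp.per_feature["completion_B2"] == imp.per_feature.max()


class TestTaskNames:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("hc-vs-ad", "HCvsAD"),
            ("HC_vs_MCI", "HCvsMCI"),
            ("mcivsad", "MCIvsAD"),
            ("ad-vs-others", "ADvsOthers"),
        ],
    )
    def test_normalization(self, raw, expected):
        assert normalize_task(raw) == expected

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            normalize_task("hc-vs-banana")
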