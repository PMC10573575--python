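import numpy as np
import pandas as pd
import pytest

from choroquant.stats import (
    ClusterRobustOLS,
    change_scores,
    cluster_robust_fit,
    group_difference_test,
    paired_mean_test,
    summarize_tables,
)
from choroquant.synthetic import CohortParams, cohort_to_records, generate_cohort


def _records(values_by_visit, metric="thickness_um", region="circle5"):
    """Long records for eyes indexed by integer; values_by_visit maps
    visit -> array of per-eye values."""
    rows = []
    n = len(next(iter(values_by_visit.values())))
    for i in range(n):
        for visit, vals in values_by_visit.items():
            rows.append(
                {
                    "patient_id": f"P{i:03d}",
                    "eye_id": f"P{i:03d}-OD",
                    "mnv_type": 1,
                    "visit": visit,
                    "region": region,
                    "metric": metric,
                    "value": vals[i],
                    "eligible": True,
                }
            )
    return pd.DataFrame(rows)


def test_change_scores_identical_visits_zero():
    vals = np.array([200.0, 250.0, 180.0])
    rec = _records({"pretreatment": vals, "exudation": vals})
    ch = change_scores(rec, "pretreatment", "exudation")
    np.testing.assert_allclose(ch["change"], 0.0)


def test_change_mean_equals_difference_of_visit_means(rng):
    pre = rng.normal(200.7, 69.5, size=27)
    exu = rng.normal(213.4, 86.4, size=27)
    rec = _records({"pretreatment": pre, "exudation": exu})
    ch = change_scores(rec, "pretreatment", "exudation")
    assert ch["change"].mean() == pytest.approx(exu.mean() - pre.mean(), abs=1e-10)


def test_change_single_eye_example():
    rec = _records({"pretreatment": [200.7], "exudation": [213.4]})
    ch = change_scores(rec, "pretreatment", "exudation")
    assert ch["change"].iloc[0] == pytest.approx(12.7)


def test_missing_visit_drops_eye_with_reason():
    rec = _records({"pretreatment": [200.0, 210.0], "exudation": [205.0, 215.0]})
    rec = rec[~((rec.eye_id == "P001-OD") & (rec.visit == "exudation"))]
    ch = change_scores(rec, "pretreatment", "exudation")
    assert len(ch) == 1
    assert ch.attrs["dropped"] == ["P001-OD"]


def test_zero_residual_fit_degenerate():
    y = np.full(10, 5.0)
    res = cluster_robust_fit(y, np.ones((10, 1)), np.arange(10))
    assert res.bse[0] == 0.0
    assert res.pvalues[0] == 0.0  # nonzero mean, zero SE


def test_singleton_clusters_cr0_equals_hc0(rng):
    sm = pytest.importorskip("statsmodels.api")
    n = 60
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    y = X @ np.array([0.5, 1.0, -2.0]) + rng.standard_normal(n)
    ours = ClusterRobustOLS(y, X, np.arange(n)).fit("CR0")
    ref = sm.OLS(y, X).fit(cov_type="HC0")
    np.testing.assert_allclose(ours.bse, ref.bse, rtol=1e-12)


def test_sandwich_matches_brute_force(rng):
    n, k, g = 80, 3, 10
    X = np.column_stack([np.ones(n), rng.standard_normal((n, k - 1))])
    y = rng.standard_normal(n)
    groups = rng.integers(0, g, size=n)
    res = ClusterRobustOLS(y, X, groups).fit("CR0")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    e = y - X @ beta
    meat = np.zeros((k, k))
    for lab in np.unique(groups):
        s = X[groups == lab].T @ e[groups == lab]
        meat += np.outer(s, s)
    expected = xtx_inv @ meat @ xtx_inv
    np.testing.assert_allclose(res.cov_params, expected, rtol=1e-10)


def test_degenerate_designs_rejected(rng):
    y = rng.standard_normal(10)
    with pytest.raises(np.linalg.LinAlgError):
        ClusterRobustOLS(y, np.column_stack([np.ones(10), np.ones(10)]), np.arange(10)).fit()
    with pytest.raises(ValueError, match="cluster"):
        ClusterRobustOLS(y, np.ones((10, 1)), np.zeros(10)).fit()


def test_results_summary_mentions_terms(rng):
    y = rng.standard_normal(20)
    res = ClusterRobustOLS(
        y, np.ones((20, 1)), np.repeat(np.arange(5), 4), exog_names=["mean_change"]
    ).fit()
    text = res.summary()
    assert "mean_change" in text and "clusters=5" in text


def test_cohort_zero_sd_deltas_exact():
    p = CohortParams(
        between_patient_sd=0.0,
        between_eye_sd=0.0,
        residual_sd=0.0,
        cvi_between_patient_sd=0.0,
        cvi_between_eye_sd=0.0,
        cvi_residual_sd=0.0,
        delta_exudation_um=10.0,
        delta_treatment_um=-10.0,
        seed=5,
    )
    df = generate_cohort(p)
    wide = df.pivot_table(index="eye_id", columns="visit", values="thickness_um")
    np.testing.assert_allclose(wide["exudation"] - wide["pretreatment"], 10.0)
    np.testing.assert_allclose(wide["post_treatment"] - wide["exudation"], -10.0)


def test_cohort_no_fellow_eyes():
    df = generate_cohort(CohortParams(p_fellow_eye=0.0, seed=2))
    assert df["eye_id"].nunique() == df["patient_id"].nunique()


def test_cohort_eye_count_expectation():
    # E[eyes] = n_patients * (1 + p_fellow_eye) ~ 41
    counts = [
        generate_cohort(CohortParams(seed=s))["eye_id"].nunique() for s in range(300)
    ]
    assert np.mean(counts) == pytest.approx(37 * (1 + 4 / 37), abs=0.5)


def test_cohort_mean_change_converges():
    p = CohortParams(n_patients=400, seed=9)
    rec = cohort_to_records(generate_cohort(p))
    ch = change_scores(rec, "pretreatment", "exudation")
    se = ch["change"].std(ddof=1) / np.sqrt(len(ch))
    assert abs(ch["change"].mean() - 12.7) <= 3 * se


def test_cohort_requires_two_patients():
    with pytest.raises(ValueError, match="2 patients"):
        generate_cohort(CohortParams(n_patients=1))


def test_group_difference_indicator_coefficient():
    ch = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(8)],
            "eye_id": [f"P{i}-OD" for i in range(8)],
            "mnv_type": [1, 1, 2, 1, 3, 3, 3, 3],
            "change": [10.0, 12.0, 11.0, 9.0, 4.0, 6.0, 5.0, 5.0],
        }
    )
    res = group_difference_test(ch)
    g12 = ch[ch.mnv_type.isin([1, 2])]["change"].mean()
    g3 = ch[ch.mnv_type == 3]["change"].mean()
    assert res.params[0] == pytest.approx(g12)
    assert res.params[1] == pytest.approx(g3 - g12)


def test_summarize_constant_records():
    vals = np.full(6, 222.0)
    rec = _records(
        {"pretreatment": vals, "exudation": vals, "post_treatment": vals}
    )
    tables = summarize_tables(rec)
    t1 = tables["all_eyes_pretreatment_to_exudation"]
    row = t1[t1.region == "circle5"].iloc[0]
    assert row["increase_mean"] == 0.0
    assert row["increase_sd"] == 0.0


def test_summarize_decrease_sign_convention():
    # exudation -> post_treatment rows report the positive decrease
    rec = cohort_to_records(generate_cohort(CohortParams(seed=3)))
    tables = summarize_tables(rec)
    t3 = tables["all_eyes_exudation_to_post_treatment"]
    row = t3[(t3.region == "circle5") & (t3.metric == "thickness_um")].iloc[0]
    assert row["decrease_mean"] > 0  # programmed thinning of 19.5 um


def test_summarize_recovers_programmed_delta():
    rec = cohort_to_records(generate_cohort(CohortParams(seed=7)))
    tables = summarize_tables(rec)
    t1 = tables["all_eyes_pretreatment_to_exudation"]
    row = t1[(t1.region == "circle5") & (t1.metric == "thickness_um")].iloc[0]
    se = row["increase_sd"] / np.sqrt(row["n_eyes"])
    assert abs(row["increase_mean"] - 12.7) <= 3 * se


def test_summarize_insufficient_group_marked():
    vals = np.arange(5, dtype=float) + 200.0
    rec = _records({"pretreatment": vals, "exudation": vals + 10.0})
    # all eyes type 1 -> type-3 group has < 2 eyes
    tables = summarize_tables(rec)
    bt = tables["by_type_pretreatment_to_exudation"]
    assert bt[bt.region == "circle5"].iloc[0]["insufficient"]


def test_null_effect_type_one_error_rate():
    # with all deltas zero the paired test should reject at ~ the nominal rate
    null = dict(delta_exudation_um=0.0, delta_treatment_um=0.0,
                cvi_delta_exudation=0.0, cvi_delta_treatment=0.0)
    rejections = 0
    trials = 200
    for s in range(trials):
        rec = cohort_to_records(generate_cohort(CohortParams(seed=20000 + s, **null)))
        ch = change_scores(rec, "pretreatment", "exudation")
        fit = paired_mean_test(ch)
        rejections += fit.pvalues[0] < 0.05
    assert rejections / trials <= 0.11  # nominal 5% with Monte-Carlo slack
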