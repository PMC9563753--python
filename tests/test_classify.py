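"""Preprocessing, ridge logistic fitting, ROC machinery, and task runs."""

import json

import numpy as np
import pandas as pd
import pytest

from sulfascreen import classify as cl
from sulfascreen import workflow


# ---------------------------------------------------------------- preprocess


def test_preprocess_log_pareto_example():
    df = pd.DataFrame({"lip": [1.0, 10.0, 100.0]}, index=list("abc"))
    out, fit = cl.preprocess(df, fit_on=list("abc"), lipid_columns=["lip"])
    np.testing.assert_allclose(out["lip"], [-1.0, 0.0, 1.0])  # mean 1, sqrt(sd)=1


def test_preprocess_drops_constant_features():
    df = pd.DataFrame({"lip": [2.0, 2.0, 2.0], "ok": [1.0, 2.0, 3.0]})
    out, fit = cl.preprocess(df, fit_on=df.index, lipid_columns=["lip"])
    assert fit.dropped == ["lip"]
    assert list(out.columns) == ["ok"]


def test_preprocess_test_rows_use_train_statistics():
    df = pd.DataFrame({"lip": [1.0, 10.0, 100.0, 1000.0]}, index=list("abcd"))
    out, fit = cl.preprocess(df, fit_on=list("abc"), lipid_columns=["lip"])
    # row d transformed with the a-c statistics: (3 - 1)/1 = 2
    assert out.loc["d", "lip"] == pytest.approx(2.0)


def test_preprocess_rejects_nonpositive_lipids():
    df = pd.DataFrame({"lip": [1.0, -1.0]})
    with pytest.raises(ValueError, match="nonpositive"):
        cl.preprocess(df, fit_on=df.index, lipid_columns=["lip"])


# ------------------------------------------------------------------ splitting


def test_split_upsample_cohort_arithmetic():
    labels = pd.Series(["N"] * 207 + ["T"] * 143, index=range(350))
    spec = cl.ModelSpec(seed=3)
    train, test, up = cl.split_upsample(labels, spec)
    counts = labels.loc[train].value_counts()
    assert counts["N"] == 124 and counts["T"] == 86
    up_counts = labels.loc[up].value_counts()
    assert up_counts["N"] == up_counts["T"] == 124
    assert set(train).isdisjoint(test)
    assert set(train) | set(test) == set(labels.index)
    # test rows are never duplicated or reused for training
    assert len(set(test)) == len(test) == 140
    assert set(up).isdisjoint(test)


def test_split_upsample_balanced_input_noop():
    labels = pd.Series(["N"] * 50 + ["T"] * 50)
    train, test, up = cl.split_upsample(labels, cl.ModelSpec(seed=0))
    assert sorted(up) == sorted(train)


# ---------------------------------------------------------------- ridge IRLS


def test_large_lambda_shrinks_to_prevalence(rng):
    X = rng.normal(size=(200, 4))
    y = (rng.random(200) < 0.3).astype(float)
    beta, conv = cl._newton_ridge(X, y, lam=1e6)
    assert conv
    np.testing.assert_allclose(beta[1:], 0.0, atol=1e-4)
    from scipy.special import expit

    assert expit(beta[0]) == pytest.approx(y.mean(), abs=1e-3)


def test_unpenalized_separable_guarded_by_iteration_cap(rng):
    # the MLE diverges on separable data; the solver must stop at the cap
    # (or at numerical saturation) with finite coefficients, not loop or raise
    X = np.concatenate([-1 - rng.random(20), 1 + rng.random(20)])[:, None]
    y = np.concatenate([np.zeros(20), np.ones(20)])
    beta, _ = cl._newton_ridge(X, y, lam=0.0, max_iter=25)
    assert np.isfinite(beta).all()
    assert abs(beta[1]) > 5.0  # driven far toward the boundary


def test_coefficient_direction_matches_bayes_oracle(rng):
    # two Gaussian classes with equal covariance: Bayes discriminant is
    # linear with direction Sigma^-1 (mu1 - mu0) = mu1 - mu0 here (identity)
    n = 2000
    mu = np.array([1.0, 0.5])
    X = np.vstack([rng.normal(0, 1, size=(n // 2, 2)), mu + rng.normal(0, 1, size=(n // 2, 2))])
    y = np.concatenate([np.zeros(n // 2), np.ones(n // 2)])
    beta, conv = cl._newton_ridge(X, y, lam=1e-4)
    assert conv
    cos = beta[1:] @ mu / (np.linalg.norm(beta[1:]) * np.linalg.norm(mu))
    assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5.0


def test_ridge_norm_shrinks_monotonically(rng):
    X = rng.normal(size=(120, 6))
    y = (rng.random(120) < cl.expit(X @ rng.normal(size=6))).astype(float)
    grid = np.logspace(-4, 2, 25)
    norms = []
    for lam in grid:
        beta, conv = cl._newton_ridge(X, y, lam)
        assert conv
        norms.append(np.linalg.norm(beta[1:]))
    assert all(b <= a + 1e-8 for a, b in zip(norms, norms[1:]))


def test_parameter_recovery_small_lambda(rng):
    # generating log-odds recovered within 15% at n = 1000 and small penalty
    n = 1000
    beta_true = np.array([1.2, -0.8, 0.5])
    X = rng.normal(size=(n, 3))
    y = (rng.random(n) < cl.expit(0.3 + X @ beta_true)).astype(float)
    beta, conv = cl._newton_ridge(X, y, lam=1e-4)
    assert conv
    np.testing.assert_allclose(beta[1:], beta_true, rtol=0.15)


def test_cv_selects_lambda_and_refits(rng):
    n = 300
    X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
    y = (rng.random(n) < cl.expit(X.values @ np.array([1.0, -1.0, 0.5, 0, 0]))).astype(float)
    spec = cl.ModelSpec(seed=2, lambda_grid=np.logspace(-3, 1, 10))
    model = cl.fit_ridge_logistic(X, y, spec)
    assert model.lam in spec.lambda_grid
    assert model.converged
    assert len(model.cv_auc) == 10
    assert model.cv_auc["cv_auc"].max() > 0.7


# ------------------------------------------------------------------- ROC/CIs


def test_auc_examples():
    assert cl.auc_rank([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0
    assert cl.auc_rank([0.2, 0.3, 0.8, 0.9], [1, 1, 0, 0]) == 0.0
    assert cl.auc_rank([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5


def pair_count_auc(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auc_rank_equals_pair_counting_and_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(30):
        n = rng.integers(4, 40)
        scores = rng.choice(np.round(rng.normal(size=8), 2), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            continue
        auc = cl.auc_rank(scores, labels)
        assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_delong_ci_orders_and_null_behavior(rng):
    scores = rng.normal(size=400)
    labels = rng.integers(0, 2, size=400)
    auc, lo, hi = cl.delong_ci(scores, labels)
    assert lo <= auc <= hi
    assert lo <= 0.5 <= hi  # label-independent scores
    auc, lo, hi = cl.delong_ci([1, 2, 3, 4], [0, 0, 1, 1])
    assert auc == 1.0 and hi == 1.0


def test_confusion_cis_closed_form():
    probs = np.ones(25) * 0.9
    labels = np.concatenate([np.ones(20), np.zeros(5)])  # 5 false positives
    out = cl.confusion_with_cis(probs, labels)
    sens = out["sensitivity"]
    assert sens["value"] == 1.0
    assert sens["ci"][0] == pytest.approx(0.025 ** (1 / 20), abs=1e-9)
    assert sens["ci"][1] == 1.0


def test_confusion_polarity_swap(rng):
    probs = rng.random(60)
    labels = rng.integers(0, 2, size=60)
    a = cl.confusion_with_cis(probs, labels)
    b = cl.confusion_with_cis(1 - probs + 1e-12, 1 - labels)
    assert a["sensitivity"]["value"] == pytest.approx(b["specificity"]["value"])


# ------------------------------------------------------------------ run_task


@pytest.fixture(scope="module")
def small_run(plasma_small, plasma_small_quant):
    spec = cl.ModelSpec(seed=5, lambda_grid=np.logspace(-3, 1, 12))
    cohort = plasma_small.cohort.loc[plasma_small_quant.relative.index]
    report = cl.run_task(plasma_small_quant.relative, cohort, "plasma-all", spec)
    return report, spec, cohort, plasma_small_quant.relative


def test_run_task_report_structure(small_run):
    report, spec, _, _ = small_run
    assert report["task"] == "plasma-all"
    assert 0 <= report["test"]["auc"]["value"] <= 1
    conf = report["test"]["confusion"]
    assert sum(conf.values()) == report["n_test"] == report["test"]["n"]
    lo, hi = report["test"]["auc"]["ci"]
    assert lo <= report["test"]["auc"]["value"] <= hi
    json.dumps(report)  # serializable


def test_run_task_deterministic(small_run):
    report, spec, cohort, relative = small_run
    again = cl.run_task(relative, cohort, "plasma-all", spec)
    assert json.dumps(report, sort_keys=True) == json.dumps(again, sort_keys=True)


def test_run_task_no_test_leakage(small_run):
    """Perturbing test rows must leave the fitted model unchanged."""
    report, spec, cohort, relative = small_run
    labels = (cohort["group"] == "T").astype(int)
    rng_ids = np.random.default_rng(spec.seed)
    train, test, _ = cl.split_upsample(labels, spec, rng=rng_ids)
    perturbed = relative.copy()
    perturbed.loc[test] = perturbed.loc[test] * 1.7  # positive, so still valid
    again = cl.run_task(perturbed, cohort, "plasma-all", spec)
    assert report["coefficients"] == again["coefficients"]
    assert report["lambda"] == again["lambda"]
    assert report["intercept"] == again["intercept"]


def test_run_task_stage_subsets(plasma_small, plasma_small_quant):
    spec = cl.ModelSpec(seed=5, lambda_grid=np.logspace(-2, 1, 6))
    cohort = plasma_small.cohort.loc[plasma_small_quant.relative.index]
    early = cl.run_task(plasma_small_quant.relative, cohort, "plasma-early", spec)
    stages = cohort.loc[cohort["group"] == "T", "stage"]
    n_early = int(stages.isin(["T1", "T2"]).sum())
    n_controls = int((cohort["group"] == "N").sum())
    assert early["n_train"] + early["n_test"] == n_early + n_controls


def test_run_task_unknown_task(plasma_small, plasma_small_quant):
    cohort = plasma_small.cohort.loc[plasma_small_quant.relative.index]
    with pytest.raises(ValueError, match="unknown task"):
        cl.run_task(plasma_small_quant.relative, cohort, "tissue-all", cl.ModelSpec())
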