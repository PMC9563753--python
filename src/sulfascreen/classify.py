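"""Ridge-penalized logistic classification of cases vs controls.

The diagnostic workflow: 33 relative lipid concentrations plus BMI and
gender enter a logistic regression with an L2 (ridge) penalty.  The data
are split 60/40 into training and testing sets (stratified), lipid
features are log10-transformed and Pareto scaled with statistics from the
training rows only, the minority class of the training set is upsampled
with replacement, and the penalty strength is chosen by 5-fold
cross-validated AUC.  Reports carry ROC points, AUC with DeLong 95% CI,
and accuracy/sensitivity/specificity with exact binomial CIs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ModelSpec",
    "PreprocessFit",
    "preprocess",
    "split_upsample",
    "fit_ridge_logistic",
    "RidgeLogisticModel",
    "roc_points",
    "auc_rank",
    "delong_ci",
    "confusion_with_cis",
    "run_task",
    "TASKS",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Classification task configuration."""

    split_fraction: float = 0.6
    cv_folds: int = 5
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-4, 2, 50)
    )
    seed: int = 0
    threshold: float = 0.5
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.lambda_grid.size == 0:
            raise ValueError("lambda_grid must be nonempty")
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class PreprocessFit:
    """Fitted log10 + Pareto transform (training statistics only)."""

    columns: list[str]
    log_columns: list[str]
    mean: pd.Series
    sqrt_sd: pd.Series
    dropped: list[str]

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table[self.columns].astype(float).copy()
        for col in self.log_columns:
            if (out[col] <= 0).any():
                raise ValueError(f"nonpositive value in lipid feature {col!r}")
            out[col] = np.log10(out[col])
        return (out - self.mean) / self.sqrt_sd


def preprocess(
    table: pd.DataFrame,
    fit_on: Sequence,
    lipid_columns: Sequence[str],
) -> tuple[pd.DataFrame, PreprocessFit]:
    """Fit log10 + Pareto scaling on the training rows and transform all.

    Pareto scaling divides the centered value by the square root of the
    standard deviation.  Constant features (sd = 0 on the training rows)
    are dropped with a warning.  Test rows are transformed with training
    statistics only.
    """
    lipid_cols = [c for c in lipid_columns if c in table.columns]
    work = table.astype(float).copy()
    for col in lipid_cols:
        if (work[col] <= 0).any():
            raise ValueError(f"nonpositive value in lipid feature {col!r}")
        work[col] = np.log10(work[col])
    train = work.loc[fit_on]
    sd = train.std(ddof=1)
    dropped = sd.index[(sd == 0) | sd.isna()].tolist()
    if dropped:
        logger.warning("dropping constant features: %s", dropped)
    kept = [c for c in table.columns if c not in dropped]
    fit = PreprocessFit(
        columns=kept,
        log_columns=[c for c in lipid_cols if c in kept],
        mean=train[kept].mean(),
        sqrt_sd=np.sqrt(sd[kept]),
        dropped=dropped,
    )
    return fit.transform(table), fit


def split_upsample(
    labels: pd.Series,
    spec: ModelSpec,
    rng: np.random.Generator | None = None,
) -> tuple[list, list, list]:
    """Stratified 60/40 split plus minority upsampling of the training set.

    Returns (train_ids, test_ids, train_ids_upsampled).  The training
    minority class is resampled with replacement up to the majority count;
    test rows are never duplicated or reused.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present before splitting")
    train_ids: list = []
    test_ids: list = []
    for cls in sorted(map(str, classes)):
        ids = labels.index[labels.astype(str) == cls].to_numpy()
        perm = rng.permutation(len(ids))
        n_train = int(round(spec.split_fraction * len(ids)))
        if n_train == 0 or n_train == len(ids):
            raise ValueError(f"class {cls!r} would be absent from one partition")
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    train_labels = labels.loc[train_ids]
    counts = train_labels.value_counts()
    majority = counts.max()
    upsampled = list(train_ids)
    for cls, cnt in counts.items():
        if cnt < majority:
            pool = train_labels.index[train_labels == cls].to_numpy()
            extra = rng.choice(pool, size=majority - cnt, replace=True)
            upsampled.extend(extra)
    return train_ids, test_ids, upsampled


def _newton_ridge(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, bool]:
    """Minimize mean logistic NLL + lam * ||slopes||^2 / 2 by damped Newton.

    The intercept (first coefficient) is unpenalized.  Returns the
    coefficient vector (intercept first) and a convergence flag (gradient
    norm below ``tol``).
    """
    n, p = X.shape
    Xb = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1) if beta0 is None else beta0.copy()
    pen = np.full(p + 1, lam)
    pen[0] = 0.0

    def objective(b: np.ndarray) -> float:
        eta = Xb @ b
        # log(1 + exp(eta)) - y*eta, computed stably
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        return nll + 0.5 * lam * np.sum(b[1:] ** 2)

    obj = objective(beta)
    converged = False
    for _ in range(max_iter):
        eta = Xb @ beta
        mu = expit(eta)
        grad = Xb.T @ (mu - y) / n + pen * beta
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        hess = (Xb * w[:, None]).T @ Xb / n + np.diag(pen)
        hess[0, 0] += 1e-12  # keep the unpenalized intercept block invertible
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # backtracking line search for robustness near separation
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            cand_obj = objective(cand)
            if cand_obj <= obj:
                break
            t *= 0.5
        beta = beta - t * step
        obj = objective(beta)
    return beta, converged


@dataclass
class RidgeLogisticModel:
    """Fitted ridge-logistic model with its CV trace."""

    intercept: float
    coef: np.ndarray
    feature_names: list[str]
    lam: float
    cv_auc: pd.DataFrame  # lambda, mean out-of-fold AUC
    converged: bool

    def decision(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision(X))


def fit_ridge_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
) -> RidgeLogisticModel:
    """Fit ridge logistic regression with lambda chosen by 5-fold CV AUC.

    For each lambda on the grid the mean out-of-fold AUC over the CV folds
    is computed; the maximizing lambda is refit on the full training set.
    Non-converged lambdas are skipped with a log message.
    """
    Xv = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(Xv.shape[1])]
    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(Xv, y))
    grid = np.sort(spec.lambda_grid)
    cv_rows = []
    warm: dict[int, np.ndarray | None] = {i: None for i in range(len(folds))}
    for lam in grid:
        aucs = []
        ok = True
        for fi, (tr, te) in enumerate(folds):
            beta, conv = _newton_ridge(
                Xv[tr], y[tr], lam, beta0=warm[fi], tol=spec.tol, max_iter=spec.max_iter
            )
            if not conv:
                logger.warning("lambda=%.4g fold=%d did not converge; lambda skipped", lam, fi)
                ok = False
                break
            warm[fi] = beta
            scores = Xv[te] @ beta[1:] + beta[0]
            aucs.append(auc_rank(scores, y[te]))
        cv_rows.append({"lambda": lam, "cv_auc": np.mean(aucs) if ok else np.nan})
    cv = pd.DataFrame(cv_rows)
    if cv["cv_auc"].isna().all():
        raise RuntimeError("no lambda on the grid converged")
    best = int(cv["cv_auc"].idxmax())
    lam = float(cv.loc[best, "lambda"])
    beta, conv = _newton_ridge(Xv, y, lam, tol=spec.tol, max_iter=spec.max_iter)
    return RidgeLogisticModel(
        intercept=float(beta[0]),
        coef=beta[1:],
        feature_names=names,
        lam=lam,
        cv_auc=cv,
        converged=conv,
    )


def auc_rank(scores, labels) -> float:
    """AUC via the Mann-Whitney rank statistic (ties count one half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_points(scores, labels) -> pd.DataFrame:
    """ROC points (FPR, TPR) at every distinct score threshold."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with DeLong 95% confidence interval.

    Uses the structural-component (midrank) formulation; the interval is
    clipped to [0, 1].  Degenerate variance yields a zero-width interval.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) / m if m > 1 else 0.0
    s01 = v01.var(ddof=1) / n if n > 1 else 0.0
    se = float(np.sqrt(s10 + s01))
    z = sps.norm.ppf(0.5 + level / 2.0)
    lo = float(max(0.0, auc - z * se))
    hi = float(min(1.0, auc + z * se))
    return auc, lo, hi


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def confusion_with_cis(
    probabilities,
    labels,
    threshold: float = 0.5,
    level: float = 0.95,
) -> dict[str, object]:
    """Confusion counts at a probability threshold with exact binomial CIs.

    Sensitivity and specificity get Clopper-Pearson intervals; accuracy an
    exact binomial interval.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels, dtype=int)
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    n = len(y)
    npos, nneg = tp + fn, tn + fp
    out: dict[str, object] = {
        "threshold": threshold,
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }
    correct = tp + tn
    acc_lo, acc_hi = _clopper_pearson(correct, n, level)
    out["accuracy"] = {"value": correct / n, "ci": [acc_lo, acc_hi]}
    if npos:
        lo, hi = _clopper_pearson(tp, npos, level)
        out["sensitivity"] = {"value": tp / npos, "ci": [lo, hi]}
    if nneg:
        lo, hi = _clopper_pearson(tn, nneg, level)
        out["specificity"] = {"value": tn / nneg, "ci": [lo, hi]}
    return out


#: Task name -> (sample matrix, stage bracket restriction or None)
TASKS: dict[str, tuple[str, str | None]] = {
    "plasma-all": ("plasma", None),
    "plasma-early": ("plasma", "T1-2"),
    "plasma-late": ("plasma", "T3-4"),
    "urine-all": ("urine", None),
}


def _stage_bracket(stage: object) -> str | None:
    if not isinstance(stage, str) or not stage:
        return None
    return "T1-2" if stage in ("T1", "T2") else "T3-4" if stage in ("T3", "T4") else None


def impute_bmi(cohort: pd.DataFrame) -> pd.Series:
    """Replace missing BMI by the median within each group (N / T)."""
    bmi = cohort["bmi"].astype(float).copy()
    for grp, sub in cohort.groupby("group"):
        med = sub["bmi"].median()
        idx = sub.index[sub["bmi"].isna()]
        bmi.loc[idx] = med
    return bmi


def _evaluate(scores: np.ndarray, probs: np.ndarray, y: np.ndarray, spec: ModelSpec) -> dict:
    auc, lo, hi = delong_ci(scores, y)
    roc = roc_points(scores, y)
    report = {
        "auc": {"value": auc, "ci": [lo, hi]},
        "roc": {
            "fpr": [float(v) for v in roc["fpr"]],
            "tpr": [float(v) for v in roc["tpr"]],
        },
        "n": int(len(y)),
    }
    report.update(confusion_with_cis(probs, y, threshold=spec.threshold))
    return report


def run_task(
    relative: pd.DataFrame,
    cohort: pd.DataFrame,
    task: str,
    spec: ModelSpec,
) -> dict:
    """Train and evaluate one classification task; returns the full report.

    ``relative`` holds relative lipid concentrations (samples x lipids,
    post-quantitation); ``cohort`` carries group/stage/gender/bmi columns
    indexed by sample id.  The report is JSON-serializable and fully
    determined by the seed and configuration.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    _, bracket = TASKS[task]
    cohort = cohort.loc[cohort.index.intersection(relative.index)].copy()
    if bracket is not None:
        brackets = cohort["stage"].map(_stage_bracket)
        keep = (cohort["group"] == "N") | (brackets == bracket)
        cohort = cohort.loc[keep]
    if cohort.empty or cohort["group"].nunique() < 2:
        raise ValueError(f"task {task!r} selects an empty or single-class subset")

    lipid_cols = list(relative.columns)
    features = relative.loc[cohort.index].copy()
    features["bmi"] = impute_bmi(cohort)
    features["gender"] = (cohort["gender"].astype(str) == "M").astype(float)
    labels = (cohort["group"] == "T").astype(int)

    rng = np.random.default_rng(spec.seed)
    train_ids, test_ids, train_up = split_upsample(labels, spec, rng=rng)
    transformed, fit = preprocess(features, fit_on=train_ids, lipid_columns=lipid_cols)
    X_train = transformed.loc[train_up]
    y_train = labels.loc[train_up].to_numpy()
    model = fit_ridge_logistic(X_train, y_train, spec)

    report: dict[str, object] = {
        "task": task,
        "seed": int(spec.seed),
        "lambda": model.lam,
        "converged": bool(model.converged),
        "coefficients": {
            name: float(c) for name, c in zip(model.feature_names, model.coef)
        },
        "intercept": model.intercept,
        "dropped_features": fit.dropped,
        "n_train": len(train_ids),
        "n_train_upsampled": len(train_up),
        "n_test": len(test_ids),
        "cv_auc": {
            "lambda": [float(v) for v in model.cv_auc["lambda"]],
            "auc": [None if np.isnan(v) else float(v) for v in model.cv_auc["cv_auc"]],
        },
    }
    for part, ids in (("train", train_ids), ("test", test_ids)):
        Xp = transformed.loc[ids].to_numpy(dtype=float)
        yp = labels.loc[ids].to_numpy()
        scores = model.decision(Xp)
        probs = expit(scores)
        report[part] = _evaluate(scores, probs, yp, spec)
    return report
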