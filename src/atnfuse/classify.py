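"""Transfer classification of diagnosis and genetic-risk labels from loadings.

L1-penalized (lasso) logistic classifiers with inner cross-validated penalty
selection are fit on training-split features and evaluated out of sample,
producing the full metric battery (AUROC, AUPRC, accuracy, balanced
accuracy, sensitivity, specificity, precision, F1) with stratified
nonparametric bootstrap percentile confidence intervals.  Multiclass
diagnosis is handled as one-vs-one pairwise tasks whose metrics are
macro-averaged.  Comparator feature sets (demographics, per-modality
PCA/ICA, concatenated PCs, target-correlated top-10 PC combo) benchmark the
fused loadings against single-modality and naive fusion baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = ("auroc", "auprc", "accuracy", "balanced_accuracy",
                "sensitivity", "specificity", "precision", "f1")

#: pairwise diagnosis tasks macro-averaged in reports
DIAGNOSIS_TASKS = (("CN", "MCI_SCD"), ("CN", "mild"), ("MCI_SCD", "mild"))

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-4, 0.5, 20))


# ----------------------------------------------------------------------
# metrics

def evaluate_binary(scores: np.ndarray, labels: np.ndarray,
                    prob_threshold: float = 0.5) -> dict[str, float]:
    """Full binary metric set from continuous scores and 0/1 labels.

    AUROC is the probability a random positive outscores a random negative
    (ties counted half); AUPRC is the step-integrated precision-recall area.
    Thresholded metrics cut the scores at ``prob_threshold`` (intended for
    probability outputs).  Raises on single-class labels rather than
    returning silent defaults.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite scores")
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class; metrics undefined")
    pred = (s > prob_threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
    return {
        "auroc": float(roc_auc_score(y, s)),
        "auprc": float(average_precision_score(y, s)),
        "accuracy": (tp + tn) / y.size,
        "balanced_accuracy": 0.5 * (sens + spec),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "f1": f1,
    }


def macro_average(reports: list[dict[str, float]]) -> dict[str, float]:
    """Arithmetic mean of each metric across per-task reports."""
    if not reports:
        raise ValueError("no task reports to average")
    keys = set(reports[0])
    for r in reports[1:]:
        if set(r) != keys:
            raise ValueError("inconsistent metric keys across tasks")
    return {k: float(np.mean([r[k] for r in reports])) for k in keys}


def bootstrap_ci(metric, scores: np.ndarray, labels: np.ndarray, B: int = 2000,
                 seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Stratified nonparametric bootstrap percentile interval for a metric.

    ``metric`` is a callable (scores, labels) -> float, evaluated on B
    resamples drawn within each class (so class counts are preserved and no
    resample is degenerate).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if B < 100:
        raise ValueError("need B >= 100 bootstrap resamples")
    metric(s, y)  # must be defined on the original data
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    vals = np.empty(B)
    for b in range(B):
        idx = np.concatenate([rng.choice(pos, size=pos.size, replace=True),
                              rng.choice(neg, size=neg.size, replace=True)])
        vals[b] = metric(s[idx], y[idx])
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ----------------------------------------------------------------------
# lasso logistic

@dataclass
class LassoLogisticModel:
    """L1-logistic classifier with inner-CV penalty selection."""

    coef: np.ndarray
    intercept: float
    selected: np.ndarray        # indices of nonzero coefficients
    lambda_: float
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return Xs @ self.coef + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))


def fit_lasso_logistic(features: np.ndarray, labels: np.ndarray,
                       lambda_grid=DEFAULT_LAMBDA_GRID, inner_folds: int = 5,
                       seed: int = 0) -> LassoLogisticModel:
    """Fit an L1-penalized logistic classifier.

    The penalty is chosen to minimize stratified ``inner_folds``-fold
    cross-validated deviance over ``lambda_grid`` (penalty lambda on the
    mean log-loss scale, i.e. C = 1/(n lambda)); features are z-scored on
    the fitting data.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("single-class input")
    lams = np.asarray(sorted(lambda_grid), dtype=float)
    if lams.size == 0:
        raise ValueError("empty lambda grid")
    n = len(y)
    mu, sd = X.mean(0), X.std(0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    Xs = (X - mu) / sd
    min_class = np.bincount(y).min()
    folds = max(2, min(inner_folds, min_class))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    deviance = np.zeros(lams.size)
    for itr, ite in cv.split(Xs, y):
        for j, lam in enumerate(lams):
            clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                     C=1.0 / (itr.size * lam), max_iter=2000,
                                     random_state=seed)
            clf.fit(Xs[itr], y[itr])
            p = clf.predict_proba(Xs[ite])[:, 1]
            deviance[j] += log_loss(y[ite], p, labels=[0, 1]) * ite.size
    lam = float(lams[int(np.argmin(deviance))])  # minimum mean deviance rule
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=1.0 / (n * lam),
                             max_iter=2000, random_state=seed)
    clf.fit(Xs, y)
    coef = clf.coef_.ravel().astype(float)
    # refit the intercept unpenalized at fixed weights (the lasso convention:
    # only the weights carry the L1 penalty), so the full-shrinkage limit
    # returns exactly the base-rate log-odds
    intercept = _mle_intercept(Xs @ coef, y)
    return LassoLogisticModel(coef=coef, intercept=intercept,
                              selected=np.flatnonzero(np.abs(coef) > 1e-12),
                              lambda_=lam, feature_means=mu, feature_sds=sd)


def _mle_intercept(eta: np.ndarray, y: np.ndarray) -> float:
    """Newton solve of the 1-D logistic MLE for the intercept at fixed scores."""
    b = 0.0
    for _ in range(50):
        p = 1.0 / (1.0 + np.exp(-(eta + b)))
        grad = float((p - y).sum())
        hess = float((p * (1 - p)).sum())
        if hess < 1e-12:
            break
        step = grad / hess
        b -= step
        if abs(step) < 1e-12:
            break
    return float(b)


# ----------------------------------------------------------------------
# comparator feature sets

@dataclass
class FeatureSet:
    """A named subjects-by-d feature matrix with derivation provenance."""

    name: str
    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"non-finite entries in feature set {self.name!r}")


def build_comparators(dataset, split, n_components: int = 10, seed: int = 0,
                      include_ica: bool = True) -> list[FeatureSet]:
    """Comparator feature sets mirroring single-modality and naive fusion baselines.

    All decompositions are fit on the training split only and applied to
    every subject: demographics (age, sex), per-modality principal
    components, per-modality independent components (whitened fixed-point
    rotation), concatenated-modality PCs, and the ten pooled per-modality
    PCs most correlated with the training target ("top 10 PCs combo").
    """
    tr = split.train
    y_tr = dataset.target[tr]
    sets: list[FeatureSet] = []
    sex = (dataset.pheno["sex"].to_numpy() == "F").astype(float)
    demo = np.column_stack([dataset.pheno["age"].to_numpy(dtype=float), sex])
    sets.append(FeatureSet("demographics", demo, {"columns": ["age", "sex_female"]}))

    Xs_all, pc_scores, pc_names = [], [], []
    for code, x in zip(dataset.modalities, dataset.X):
        mu, sd = x[tr].mean(0), x[tr].std(0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        xs = (x - mu) / sd
        Xs_all.append(xs)
        nc = min(n_components, np.linalg.matrix_rank(xs[tr]), tr.size - 1)
        pca = PCA(n_components=nc, svd_solver="full").fit(xs[tr])
        scores = pca.transform(xs)
        sets.append(FeatureSet(f"{code}_pcs", scores,
                               {"method": "pca", "n_components": nc, "modality": code}))
        pc_scores.append(scores)
        pc_names += [f"{code}_pc{j}" for j in range(nc)]
        if include_ica:
            ica = FastICA(n_components=nc, random_state=seed, whiten="unit-variance",
                          max_iter=1000, tol=1e-3)
            sets.append(FeatureSet(f"{code}_ics", ica.fit(xs[tr]).transform(xs),
                                   {"method": "fastica", "n_components": nc,
                                    "modality": code, "seed": seed}))
    concat = np.hstack(Xs_all)
    nc = min(n_components, tr.size - 1)
    pca_all = PCA(n_components=nc, svd_solver="randomized", random_state=seed).fit(concat[tr])
    sets.append(FeatureSet("concat_pcs", pca_all.transform(concat),
                           {"method": "pca_concatenated", "n_components": nc}))

    pooled = np.hstack(pc_scores)
    r = np.zeros(pooled.shape[1])
    for j in range(pooled.shape[1]):
        col = pooled[tr, j]
        if col.std() > 1e-12 and y_tr.std() > 1e-12:
            r[j] = np.corrcoef(col, y_tr)[0, 1]
    top = np.argsort(-np.abs(r))[:10]
    sets.append(FeatureSet("top10_pcs_combo", pooled[:, top],
                           {"method": "target-correlated pooled PCs",
                            "columns": [pc_names[j] for j in top],
                            "train_correlations": r[top].tolist()}))
    return sets


# ----------------------------------------------------------------------
# full transfer study

@dataclass
class TaskResult:
    """Per-task outcome: held-out and cross-validated metrics with CIs."""

    task: str
    status: str                      # "ok" or "skipped: <reason>"
    test_metrics: dict = field(default_factory=dict)
    test_ci: dict = field(default_factory=dict)
    cv_metrics: dict = field(default_factory=dict)
    cv_ci: dict = field(default_factory=dict)
    selected: list = field(default_factory=list)
    lambda_: float = float("nan")
    n_train: int = 0
    n_test: int = 0


@dataclass
class ClassificationReport:
    """Per-feature-set, per-task results plus macro-averages over diagnosis pairs."""

    results: dict[str, dict[str, TaskResult]]  # feature set -> task -> result
    macro: dict[str, dict[str, float]]         # feature set -> macro metric set

    def to_dict(self) -> dict:
        out = {"macro": self.macro, "tasks": {}}
        for fs, tasks in self.results.items():
            out["tasks"][fs] = {}
            for name, t in tasks.items():
                out["tasks"][fs][name] = {
                    "status": t.status, "test_metrics": t.test_metrics,
                    "test_ci": t.test_ci, "cv_metrics": t.cv_metrics,
                    "cv_ci": t.cv_ci, "selected": [int(i) for i in t.selected],
                    "lambda": t.lambda_, "n_train": t.n_train, "n_test": t.n_test,
                }
        return out

    def summary(self) -> str:
        lines = ["Transfer classification report", "=" * 64,
                 f"{'feature set':24s} {'macro AUROC':>12s} {'carrier AUROC':>14s}"]
        for fs in self.results:
            mac = self.macro.get(fs, {})
            carrier = self.results[fs].get("carrier")
            cstr = (f"{carrier.test_metrics['auroc']:.3f}"
                    if carrier and carrier.status == "ok" else "-")
            mstr = f"{mac['auroc']:.3f}" if "auroc" in mac else "-"
            lines.append(f"{fs:24s} {mstr:>12s} {cstr:>14s}")
        return "\n".join(lines)


def _binary_task_labels(dataset, task) -> tuple[np.ndarray, np.ndarray] | None:
    """(mask of usable subjects, 0/1 labels) for a named task."""
    if task == "carrier":
        y = dataset.pheno["carrier"].to_numpy(dtype=int)
        return np.ones(len(y), dtype=bool), y
    neg, pos = task
    diag = dataset.pheno["diagnosis"].to_numpy()
    mask = (diag == neg) | (diag == pos)
    return mask, (diag == pos).astype(int)


def run_transfer_study(dataset, feature_sets: list[FeatureSet], split,
                       tasks=None, boot_B: int = 500, seed: int = 0,
                       lambda_grid=DEFAULT_LAMBDA_GRID, cv_folds: int = 5) -> ClassificationReport:
    """Fit lasso classifiers per feature set and task; evaluate train-CV and test.

    Tasks default to the three pairwise diagnosis comparisons plus carrier
    status.  Each task fits on the training split, reports pooled
    out-of-fold cross-validated training metrics and held-out test
    AUROC/AUPRC, all with stratified bootstrap CIs.  Tasks with an empty
    class in either split are reported as skipped, never dropped silently.
    """
    if tasks is None:
        tasks = list(DIAGNOSIS_TASKS) + ["carrier"]
    rng = np.random.default_rng(seed)
    results: dict[str, dict[str, TaskResult]] = {}
    macro: dict[str, dict[str, float]] = {}
    for fs in feature_sets:
        results[fs.name] = {}
        diag_reports = []
        for task in tasks:
            name = task if isinstance(task, str) else f"{task[0]}_vs_{task[1]}"
            mask, y = _binary_task_labels(dataset, task)
            tr = np.intersect1d(split.train, np.flatnonzero(mask))
            te = np.intersect1d(split.test, np.flatnonzero(mask))
            tres = TaskResult(task=name, status="ok", n_train=tr.size, n_test=te.size)
            if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
                tres.status = "skipped: a split has an empty class"
                results[fs.name][name] = tres
                continue
            task_seed = int(rng.integers(2**31))
            model = fit_lasso_logistic(fs.matrix[tr], y[tr], lambda_grid=lambda_grid,
                                       seed=task_seed)
            tres.selected = list(model.selected)
            tres.lambda_ = model.lambda_
            # held-out test metrics
            p_te = model.predict_proba(fs.matrix[te])
            tres.test_metrics = evaluate_binary(p_te, y[te])
            for metric in ("auroc", "auprc"):
                fn = (lambda s, l: roc_auc_score(l, s)) if metric == "auroc" \
                    else (lambda s, l: average_precision_score(l, s))
                tres.test_ci[metric] = bootstrap_ci(fn, p_te, y[te], B=boot_B,
                                                    seed=task_seed)
            # cross-validated training metrics from pooled out-of-fold scores
            folds = max(2, min(cv_folds, np.bincount(y[tr]).min()))
            cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=task_seed)
            oof = np.empty(tr.size)
            for itr, ite in cv.split(fs.matrix[tr], y[tr]):
                m = fit_lasso_logistic(fs.matrix[tr][itr], y[tr][itr],
                                       lambda_grid=lambda_grid, seed=task_seed)
                oof[ite] = m.predict_proba(fs.matrix[tr][ite])
            tres.cv_metrics = evaluate_binary(oof, y[tr])
            for metric in METRIC_NAMES:
                fn = _metric_fn(metric)
                tres.cv_ci[metric] = bootstrap_ci(fn, oof, y[tr], B=boot_B,
                                                  seed=task_seed)
            results[fs.name][name] = tres
            if name != "carrier":
                diag_reports.append(tres.test_metrics | {
                    k: v for k, v in tres.cv_metrics.items() if k not in ("auroc", "auprc")})
        ok = [r for r in diag_reports if r]
        if ok:
            macro[fs.name] = macro_average(ok)
    return ClassificationReport(results=results, macro=macro)


def _metric_fn(name: str):
    if name == "auroc":
        return lambda s, l: roc_auc_score(l, s)
    if name == "auprc":
        return lambda s, l: average_precision_score(l, s)
    return lambda s, l: evaluate_binary(s, l)[name]
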