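"""Cross-validated evaluation: fold planning, the metric suite, the
hyperparameter-grid harness and ablation orchestration.

Evaluation follows a k-fold (default 9) cross-validation repeated over
several independent runs (default 15).  Folds are class-stratified and mix
trials across subjects; every run draws a fresh fold assignment and fresh
model initialisation from seeds derived with ``numpy.random.SeedSequence``
so the whole plan is reproducible from one integer.

Metric suite per fold: accuracy, macro/micro F1, macro/micro precision and
one-vs-rest macro/micro ROC-AUC from the softmax scores.  For single-label
multiclass predictions micro-F1 = micro-precision = accuracy (an exact
identity — every false positive is another class's false negative).  The
reported SD is the standard deviation of fold-level accuracies pooled
across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import accuracy_score, f1_score, precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import label_binarize

__all__ = [
    "FoldPlan",
    "make_folds",
    "compute_metrics",
    "run_cv",
    "EvalReport",
    "hyperparameter_grid",
    "ADJ_FILTER_GRID",
    "ADJ_KERNEL_GRID",
    "PLV_GRID",
]

METRIC_COLUMNS = [
    "accuracy", "f1_macro", "f1_micro", "precision_macro", "precision_micro",
    "roc_auc_macro", "roc_auc_micro",
]

#: Hyperparameter grids mirroring the published tuning tables: four filter
#: counts at fixed kernel for the structural model, four kernel widths at
#: 64 filters, and filter-pair x kernel-size combinations for the
#: functional model.
ADJ_FILTER_GRID = tuple({"filters": f} for f in (32, 64, 128, 256))
ADJ_KERNEL_GRID = tuple({"filters": 64, "kernel_width": w} for w in (22, 45, 65, 85))
PLV_GRID = tuple(
    {"filters": pair, "kernel": k}
    for pair in ((8, 16), (32, 64), (128, 256), (256, 512))
    for k in ((2, 2), (3, 3))
)


@dataclass(frozen=True)
class FoldPlan:
    """Per-run assignment of every trial to one of k folds."""

    k: int
    runs: int
    assignments: np.ndarray  # (runs, n_trials) fold index per trial
    seed: int

    @property
    def n_trials(self) -> int:
        return self.assignments.shape[1]

    def fold_indices(self, run: int, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one run/fold."""
        mask = self.assignments[run] == fold
        idx = np.arange(self.n_trials)
        return idx[~mask], idx[mask]


def _derived_seeds(seed: int, n: int) -> np.ndarray:
    # positive 31-bit ints for sklearn random_state compatibility
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % (2**31 - 1)


def make_folds(labels, k: int = 9, runs: int = 15, seed: int = 0,
               vary_folds: bool = True) -> FoldPlan:
    """Stratified k-way partitions, one fresh permutation per run.

    ``labels`` may be a label array or any object with a ``labels``
    attribute (e.g. a TrialSet).  Folds partition all trials (pairwise
    disjoint, union complete) and are class-stratified to within one trial
    per class per fold.  The same seed reproduces the identical plan;
    ``vary_folds=False`` reuses the first run's partition for every run so
    that only model initialisation varies across runs.
    """
    labels = np.asarray(getattr(labels, "labels", labels))
    n = labels.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds trial count {n}")
    run_seeds = _derived_seeds(seed, runs)
    assignments = np.empty((runs, n), dtype=np.int64)
    for r in range(runs):
        rs = int(run_seeds[r if vary_folds else 0])
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
            assignments[r, test_idx] = fold
    return FoldPlan(k=k, runs=runs, assignments=assignments, seed=seed)


def compute_metrics(y_true, y_pred, y_scores=None, labels=None) -> dict[str, float]:
    """The per-fold metric record.

    ROC-AUC (one-vs-rest; macro = unweighted class mean, micro = pooled)
    needs ``y_scores`` with rows summing to 1; it is NaN (with a warning)
    when undefined, e.g. a single-class fold.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    rec = {
        "accuracy": accuracy_score(y_true, y_pred),
        "f1_macro": f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0),
        "f1_micro": f1_score(y_true, y_pred, labels=labels, average="micro", zero_division=0),
        "precision_macro": precision_score(y_true, y_pred, labels=labels, average="macro",
                                           zero_division=0),
        "precision_micro": precision_score(y_true, y_pred, labels=labels, average="micro",
                                           zero_division=0),
        "roc_auc_macro": np.nan,
        "roc_auc_micro": np.nan,
    }
    if y_scores is not None:
        y_scores = np.asarray(y_scores)
        present = np.unique(y_true)
        if len(present) < 2:
            warnings.warn("ROC-AUC undefined: fold contains a single class", stacklevel=2)
        else:
            onehot = label_binarize(y_true, classes=labels)
            if onehot.shape[1] == 1:  # binary edge case
                onehot = np.hstack([1 - onehot, onehot])
            try:
                rec["roc_auc_macro"] = roc_auc_score(onehot, y_scores, average="macro")
                rec["roc_auc_micro"] = roc_auc_score(onehot, y_scores, average="micro")
            except ValueError as err:  # e.g. class missing from fold
                warnings.warn(f"ROC-AUC undefined: {err}", stacklevel=2)
    return rec


@dataclass
class EvalReport:
    """Per-fold, per-run metrics plus their aggregates."""

    records: pd.DataFrame  # columns: run, fold, n_test, + METRIC_COLUMNS
    model_name: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def mean(self) -> pd.Series:
        return self.records[METRIC_COLUMNS].mean()

    @property
    def accuracy(self) -> float:
        return float(self.records["accuracy"].mean())

    @property
    def accuracy_sd(self) -> float:
        """SD of fold-level accuracies pooled across runs."""
        return float(self.records["accuracy"].std(ddof=1))

    def summary(self) -> pd.DataFrame:
        agg = self.records[METRIC_COLUMNS].agg(["mean", "std"])
        return agg

    def to_row(self) -> dict:
        row = {"model": self.model_name}
        row.update({k: float(v) for k, v in self.mean.items()})
        row["accuracy_sd"] = self.accuracy_sd
        return row


def run_cv(X, y, estimator, plan: FoldPlan, *, model_name: str | None = None,
           verbose: bool = False) -> EvalReport:
    """Train and evaluate an estimator over every run x fold of a plan.

    A fresh clone of ``estimator`` is fitted per fold; if it exposes a
    ``seed`` parameter, a per-fold seed derived from the plan seed is set
    so weight initialisation re-randomises across runs.  Degenerate folds
    (missing a class in train or test) are evaluated with a warning and
    NaN where a metric is undefined.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    labels = np.unique(y)
    fold_seeds = _derived_seeds(plan.seed + 1, plan.runs * plan.k)
    rows = []
    for run in range(plan.runs):
        for fold in range(plan.k):
            train_idx, test_idx = plan.fold_indices(run, fold)
            if len(np.unique(y[train_idx])) < len(labels):
                warnings.warn(f"run {run} fold {fold}: training fold is missing a class",
                              stacklevel=2)
            model = clone(estimator)
            if "seed" in model.get_params():
                model.set_params(seed=int(fold_seeds[run * plan.k + fold]))
            model.fit(X[train_idx], y[train_idx])
            y_pred = model.predict(X[test_idx])
            scores = model.predict_proba(X[test_idx]) if hasattr(model, "predict_proba") else None
            rec = compute_metrics(y[test_idx], y_pred, scores, labels=labels)
            rec.update(run=run, fold=fold, n_test=len(test_idx))
            rows.append(rec)
            if verbose:
                print(f"run {run} fold {fold}: acc={rec['accuracy']:.3f}")
    records = pd.DataFrame(rows)
    name = model_name or type(estimator).__name__
    return EvalReport(records=records, model_name=name)


def hyperparameter_grid(estimator, grid, X, y, plan: FoldPlan,
                        verbose: bool = False) -> pd.DataFrame:
    """One cross-validated row per configuration; best row flagged.

    ``grid`` is an iterable of parameter dicts applied with ``set_params``.
    A configuration that fails to build (e.g. kernel larger than input) is
    reported as a failed row and the sweep continues.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    for params in grid:
        row = {str(k): str(v) for k, v in params.items()}
        try:
            model = clone(estimator).set_params(**params)
            report = run_cv(X, y, model, plan, verbose=verbose)
            row.update(accuracy=report.accuracy, accuracy_sd=report.accuracy_sd,
                       f1_macro=float(report.mean["f1_macro"]),
                       f1_micro=float(report.mean["f1_micro"]), failed=False)
        except (ValueError, RuntimeError) as err:
            row.update(accuracy=np.nan, accuracy_sd=np.nan, f1_macro=np.nan,
                       f1_micro=np.nan, failed=True, error=str(err))
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["accuracy"].notna()
    table["best"] = False
    if ok.any():
        table.loc[table.loc[ok, "accuracy"].idxmax(), "best"] = True
    return table
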