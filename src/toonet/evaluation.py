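"""Repeated k-fold cross-validation with in-fold gene selection, and the
confusion-matrix metrics reported for it.

The protocol, per repeat: split the samples into k disjoint folds; for each
fold, rank genes and build the top-N-per-class panel using ONLY the k-1
training folds, train the classifier on those folds restricted to that
panel, and predict the held-out fold.  Merging the k held-out predictions
scores every sample exactly once per repeat; metrics are then averaged over
repeats.  Selecting features inside each fold keeps the held-out samples
invisible to the panel choice (no selection leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .classifier import (LogisticConfig, MLPConfig, predict, train_logistic,
                         train_mlp)
from .feature_selection import (GenePanel, build_panel, rank_genes_per_class,
                                subset_to_panel)
from .io import ExpressionMatrix, LabelTable, canonical_class, class_order


@dataclass
class CVConfig:
    k: int = 10
    repeats: int = 10
    n_per_class: int = 10
    seed: int = 0
    stratified: bool = True
    model_kind: str = "mlp"          # "mlp" | "logistic"
    mlp: MLPConfig = field(default_factory=MLPConfig)
    logistic: LogisticConfig = field(default_factory=LogisticConfig)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.model_kind not in ("mlp", "logistic"):
            raise ValueError(f"unknown model kind {self.model_kind!r}")


@dataclass
class ConfusionMatrix:
    """Reference classes in rows, predicted classes in columns."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.classes)
        if self.counts.shape != (C, C):
            raise ValueError("confusion matrix shape does not match classes")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(true_labels, predicted_labels, classes: list[str]) -> ConfusionMatrix:
    """Count (reference, predicted) pairs into a C x C grid."""
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(classes)}
    unknown = sorted({l for l in true_labels + predicted_labels if l not in index})
    if unknown:
        raise ValueError(f"labels outside the class set: {unknown}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass
class MetricsTable:
    """Per-class sensitivity TP/(TP+FN) and precision TP/(TP+FP), with
    unweighted macro averages and overall accuracy (trace/total)."""

    per_class: pd.DataFrame          # index class; columns sensitivity, precision
    macro_sensitivity: float
    macro_precision: float
    overall_accuracy: float

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        df = self.per_class.copy()
        avg = pd.DataFrame(
            {"sensitivity": [self.macro_sensitivity],
             "precision": [self.macro_precision]},
            index=["Average"])
        df = pd.concat([df, avg])
        return df * 100.0 if percent else df


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsTable:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    row = counts.sum(axis=1)   # reference counts
    col = counts.sum(axis=0)   # prediction counts
    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = np.where(row > 0, tp / row, 0.0)
        precision = np.where(col > 0, tp / col, 0.0)
    if (col == 0).any():
        never = [cm.classes[i] for i in np.nonzero(col == 0)[0]]
        warnings.warn(f"classes never predicted, precision set to 0: {never}",
                      stacklevel=2)
    per_class = pd.DataFrame(
        {"sensitivity": sensitivity, "precision": precision}, index=cm.classes)
    return MetricsTable(
        per_class=per_class,
        macro_sensitivity=float(sensitivity.mean()),
        macro_precision=float(precision.mean()),
        overall_accuracy=float(tp.sum() / counts.sum()),
    )


def macro_average(values) -> float:
    """Unweighted mean of per-class metric values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no per-class values to average")
    return float(values.mean())


def kfold_partition(sample_ids, labels, k: int, seed: int = 0,
                    stratified: bool = True) -> list[list[str]]:
    """Split sample ids into k disjoint, exhaustive folds.

    Fold sizes differ by at most one (per class stratum when stratified).
    The split is a pure function of (ids, labels, k, seed).
    """
    sample_ids = list(sample_ids)
    if k > len(sample_ids):
        raise ValueError(f"k={k} exceeds sample count {len(sample_ids)}")
    y = np.asarray(list(labels))
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [[sample_ids[i] for i in test_idx]
            for _, test_idx in splitter.split(np.zeros(len(sample_ids)), y)]


@dataclass
class CVResult:
    classes: list[str]
    predictions: pd.DataFrame        # repeat, fold, sample_id, true_label, predicted_label
    panels: list[tuple[int, int, GenePanel]]     # (repeat, fold, panel)
    repeat_accuracies: np.ndarray
    confusion: ConfusionMatrix       # pooled over repeats
    metrics: MetricsTable            # from the pooled confusion

    @property
    def mean_accuracy(self) -> float:
        """Mean of repeat-level merged-prediction accuracies."""
        return float(np.mean(self.repeat_accuracies))

    @property
    def pooled_accuracy(self) -> float:
        """Accuracy pooled over every fold of every repeat."""
        return float(np.diag(self.confusion.counts).sum() / self.confusion.total)

    def stability(self) -> pd.DataFrame:
        return panel_stability([p for _, _, p in self.panels])


def _train_fn(cfg: CVConfig):
    if cfg.model_kind == "mlp":
        return lambda m, l, seed: train_mlp(
            m, l, MLPConfig(**{**cfg.mlp.__dict__, "seed": seed}))
    return lambda m, l, seed: train_logistic(
        m, l, LogisticConfig(**{**cfg.logistic.__dict__, "seed": seed}))


def cross_validate(matrix: ExpressionMatrix, labels: LabelTable,
                   cfg: CVConfig | None = None) -> CVResult:
    """Repeated k-fold CV with per-fold gene selection.

    Returns per-repeat accuracies, the pooled confusion matrix and metrics,
    every per-fold panel (for stability analysis), and the merged per-sample
    predictions.
    """
    cfg = CVConfig() if cfg is None else cfg
    if matrix.sample_ids != labels.sample_ids:
        labels = labels.for_samples(matrix.sample_ids)
    classes = class_order(labels)
    y_all = np.asarray(labels.class_labels)
    ids = matrix.sample_ids
    id_index = {s: i for i, s in enumerate(ids)}

    rng = np.random.default_rng(cfg.seed)
    train = _train_fn(cfg)

    rows = []
    panels: list[tuple[int, int, GenePanel]] = []
    repeat_accuracies = []
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    for rep in range(cfg.repeats):
        part_seed = int(rng.integers(2**31 - 1))
        model_seed = int(rng.integers(2**31 - 1))
        folds = kfold_partition(ids, y_all, cfg.k, seed=part_seed,
                                stratified=cfg.stratified)
        rep_true, rep_pred = [], []
        for fold_no, test_ids in enumerate(folds):
            test_set = set(test_ids)
            train_ids = [s for s in ids if s not in test_set]
            train_y = y_all[[id_index[s] for s in train_ids]]
            scarce = [c for c in classes if (train_y == c).sum() < 2]
            if scarce:
                raise ValueError(
                    f"classes with < 2 training samples in a fold: {scarce}; "
                    "use a smaller k or more samples per class")
            train_matrix = matrix.subset_samples(train_ids)
            train_labels = labels.for_samples(train_ids)
            # panel selection sees the training portion only
            ranked = rank_genes_per_class(train_matrix, train_labels, classes)
            panel = build_panel(ranked, cfg.n_per_class)
            panels.append((rep, fold_no, panel))
            model = train(subset_to_panel(train_matrix, panel), train_labels,
                          model_seed)
            test_matrix = subset_to_panel(matrix.subset_samples(test_ids), panel)
            pred = predict(model, test_matrix)
            for sid in test_ids:
                t, p = y_all[id_index[sid]], pred[sid]
                rows.append((rep, fold_no, sid, t, p))
                rep_true.append(t)
                rep_pred.append(p)
        cm = confusion(rep_true, rep_pred, classes)
        pooled += cm.counts
        repeat_accuracies.append(np.diag(cm.counts).sum() / cm.total)

    predictions = pd.DataFrame(
        rows, columns=["repeat", "fold", "sample_id", "true_label",
                       "predicted_label"])
    pooled_cm = ConfusionMatrix(classes=classes, counts=pooled)
    return CVResult(
        classes=classes,
        predictions=predictions,
        panels=panels,
        repeat_accuracies=np.asarray(repeat_accuracies, dtype=float),
        confusion=pooled_cm,
        metrics=metrics_from_confusion(pooled_cm),
    )


def sweep_feature_number(matrix: ExpressionMatrix, labels: LabelTable,
                         cfg: CVConfig, n_values) -> pd.DataFrame:
    """Accuracy-vs-panel-size curve: one CV run per per-class gene number.

    ``total_genes`` is the size of the de-duplicated whole-data panel at
    that n (at most C x n, fewer when classes share genes).
    """
    n_values = list(n_values)
    if not n_values:
        raise ValueError("n_values must be non-empty")
    classes = class_order(labels if matrix.sample_ids == labels.sample_ids
                          else labels.for_samples(matrix.sample_ids))
    ranked_full = rank_genes_per_class(matrix, labels, classes)
    rows = []
    for n in n_values:
        run_cfg = CVConfig(**{**cfg.__dict__, "n_per_class": int(n)})
        result = cross_validate(matrix, labels, run_cfg)
        rows.append({
            "n_per_class": int(n),
            "total_genes": len(build_panel(ranked_full, int(n))),
            "mean_accuracy": result.mean_accuracy,
        })
    return pd.DataFrame(rows)


def panel_stability(panels: list[GenePanel]) -> pd.DataFrame:
    """Per-gene count of panels containing it, sorted by count then id.

    Used to ask how often each whole-data panel gene reappears across the
    k x repeats in-fold panels (panel robustness)."""
    if not panels:
        raise ValueError("need at least one panel")
    counts: dict[str, int] = {}
    for p in panels:
        for g in p.gene_ids:
            counts[g] = counts.get(g, 0) + 1
    df = pd.DataFrame(sorted(counts.items()), columns=["gene_id", "count"])
    return (df.sort_values(["count", "gene_id"], ascending=[False, True],
                           kind="stable").reset_index(drop=True))


def prediction_table_accuracy(table: pd.DataFrame, predicted_col: str,
                              true_col: str = "true_label") -> float:
    """Fraction of rows where the predicted class equals the true class.

    Class spellings are harmonized first, so the merged-class synonyms
    (e.g. ``COADREAD`` vs ``COAD + READ``) compare equal.
    """
    if len(table) == 0:
        raise ValueError("empty prediction table")
    pred = table[predicted_col].map(canonical_class)
    true = table[true_col].map(canonical_class)
    return float((pred == true).mean())


def write_cv_outputs(result: CVResult, out_dir) -> None:
    """Export metrics, confusion matrix, stability and predictions as TSV."""
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_frame(percent=True).round(2).to_csv(
        out_dir / "metrics.tsv", sep="\t", index_label="class")
    result.confusion.to_frame().to_csv(
        out_dir / "confusion.tsv", sep="\t", index_label="reference")
    result.stability().to_csv(out_dir / "stability.tsv", sep="\t", index=False)
    result.predictions.to_csv(out_dir / "predictions.tsv", sep="\t", index=False)
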