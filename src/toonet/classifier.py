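"""Softmax classifiers over a gene panel.

Two models are supported: a single-hidden-layer neural network (panel size
-> 50 hidden units -> one softmax output per class, L2 penalty 1e-4) and a
multinomial logistic-regression baseline with inverse regularization
C = 10,000.  Both are scikit-learn estimators wrapped so that prediction
enforces the exact gene panel (identity and order) seen at training.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .io import ExpressionMatrix, LabelTable

_BUNDLE_FORMAT = 1


@dataclass
class MLPConfig:
    """Neural-network hyperparameters.

    Layer sizes and the L2 penalty follow the published setup; activation,
    optimizer and iteration budget are conventional defaults and fully
    configurable.
    """

    hidden_units: int = 50
    l2_penalty: float = 1e-4
    max_iter: int = 500
    seed: int = 0
    activation: str = "relu"
    solver: str = "adam"
    # inputs are unstandardized (proportions can be ~1e-4); the stock 1e-3
    # step underfits at that scale, so the default step is one order larger
    learning_rate_init: float = 0.01

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be non-negative")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class LogisticConfig:
    inverse_reg_C: float = 10_000.0
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inverse_reg_C <= 0:
            raise ValueError("inverse_reg_C must be positive")


@dataclass
class TrainedModel:
    model_kind: str                  # "mlp" | "logistic"
    class_order: list[str]
    estimator: object = field(repr=False)
    panel_genes: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)


def _check_trainable(matrix: ExpressionMatrix, labels: LabelTable) -> np.ndarray:
    if matrix.sample_ids != labels.sample_ids:
        labels = labels.for_samples(matrix.sample_ids)
    y = np.asarray(labels.class_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires at least 2 classes")
    return y


def train_mlp(matrix: ExpressionMatrix, labels: LabelTable,
              cfg: MLPConfig | None = None) -> TrainedModel:
    """Train the softmax neural network on a panel-subset matrix."""
    cfg = MLPConfig() if cfg is None else cfg
    y = _check_trainable(matrix, labels)
    kwargs = {}
    if cfg.solver in ("adam", "sgd"):
        kwargs["learning_rate_init"] = cfg.learning_rate_init
    est = MLPClassifier(
        hidden_layer_sizes=(cfg.hidden_units,),
        activation=cfg.activation,
        solver=cfg.solver,
        alpha=cfg.l2_penalty,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
        **kwargs,
    )
    est.fit(matrix.values, y)
    return TrainedModel(
        model_kind="mlp",
        class_order=[str(c) for c in est.classes_],
        estimator=est,
        panel_genes=matrix.gene_ids,
        config=asdict(cfg),
    )


def train_logistic(matrix: ExpressionMatrix, labels: LabelTable,
                   cfg: LogisticConfig | None = None) -> TrainedModel:
    """Train the multinomial logistic baseline."""
    cfg = LogisticConfig() if cfg is None else cfg
    y = _check_trainable(matrix, labels)
    est = LogisticRegression(
        C=cfg.inverse_reg_C,
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    est.fit(matrix.values, y)
    return TrainedModel(
        model_kind="logistic",
        class_order=[str(c) for c in est.classes_],
        estimator=est,
        panel_genes=matrix.gene_ids,
        config=asdict(cfg),
    )


def _check_genes(model: TrainedModel, matrix: ExpressionMatrix) -> None:
    if matrix.gene_ids != model.panel_genes:
        missing = sorted(set(model.panel_genes) - set(matrix.gene_ids))
        extra = sorted(set(matrix.gene_ids) - set(model.panel_genes))
        detail = []
        if missing:
            detail.append(f"missing: {missing[:10]}")
        if extra:
            detail.append(f"unexpected: {extra[:10]}")
        if not detail:
            detail.append("gene order differs from the training panel")
        raise ValueError("prediction matrix does not match the model panel; "
                         + "; ".join(detail))


def predict_proba(model: TrainedModel, matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-class probabilities (softmax output), one row per sample.

    Rows are non-negative and sum to 1; columns follow ``model.class_order``.
    """
    _check_genes(model, matrix)
    probs = model.estimator.predict_proba(matrix.values)
    return pd.DataFrame(probs, index=matrix.data.index, columns=model.class_order)


def predict(model: TrainedModel, matrix: ExpressionMatrix) -> pd.Series:
    """Argmax class per sample; exact probability ties resolve to the
    earlier class in ``model.class_order``."""
    probs = predict_proba(model, matrix)
    idx = np.argmax(probs.to_numpy(), axis=1)
    labels = [model.class_order[i] for i in idx]
    return pd.Series(labels, index=matrix.data.index, name="predicted_class")


def save_model(model: TrainedModel, path) -> None:
    """Persist a model as a directory bundle (weights + JSON metadata)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": _BUNDLE_FORMAT,
        "model_kind": model.model_kind,
        "class_order": model.class_order,
        "panel_genes": model.panel_genes,
        "config": model.config,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    with open(path / "estimator.pkl", "wb") as fh:
        pickle.dump(model.estimator, fh)


def load_model(path) -> TrainedModel:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    if meta.get("format") != _BUNDLE_FORMAT:
        raise ValueError(f"unsupported model bundle format: {meta.get('format')}")
    with open(path / "estimator.pkl", "rb") as fh:
        est = pickle.load(fh)
    return TrainedModel(
        model_kind=meta["model_kind"],
        class_order=meta["class_order"],
        estimator=est,
        panel_genes=meta["panel_genes"],
        config=meta.get("config", {}),
    )
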