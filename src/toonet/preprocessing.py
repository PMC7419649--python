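"""Expression normalization: per-sample-sum scaling and a log2 variant.

Two input representations feed the downstream pipeline:

* ``sample_sum`` — each sample's expression vector is divided by its total
  (library size) and multiplied by ``scale``, giving per-sample proportions
  (scale 1) or CPM-style values (scale 1e6).
* ``log2`` — zeros are replaced by (global positive minimum x factor), then
  every entry is log2-transformed.  Output values can be negative.

No further normalization is applied after gene-panel selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix


@dataclass
class PreprocessConfig:
    mode: str = "sample_sum"          # "sample_sum" | "log2" | "none"
    scale: float = 1.0                # row-sum target for sample_sum
    zero_replacement_factor: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("sample_sum", "log2", "none"):
            raise ValueError(f"unknown preprocessing mode {self.mode!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.zero_replacement_factor <= 0:
            raise ValueError("zero_replacement_factor must be positive")


def normalize_by_sample_sum(matrix: ExpressionMatrix, scale: float = 1.0) -> ExpressionMatrix:
    """Divide each sample row by its sum, then multiply by ``scale``.

    Output row sums equal ``scale`` (to float precision).  A sample with an
    all-zero row has no defined library size and is a hard error.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    values = matrix.values
    row_sums = values.sum(axis=1)
    zero_rows = np.nonzero(row_sums <= 0)[0]
    if zero_rows.size:
        bad = [matrix.sample_ids[i] for i in zero_rows]
        raise ValueError(f"all-zero sample rows cannot be normalized: {bad}")
    out = values / row_sums[:, None] * scale
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns)
    )


def log2_transform(matrix: ExpressionMatrix, factor: float = 0.1) -> ExpressionMatrix:
    """log2 with zero replacement.

    Let g be the minimum over the strictly positive entries of the whole
    matrix ("global minimum").  Every zero is replaced by g x ``factor``
    (guaranteeing it stays below all observed positive values for
    factor < 1), then log2 is applied elementwise.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    values = matrix.values
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive entry; log2 transform undefined")
    g = positive.min()
    out = np.where(values == 0, g * factor, values)
    out = np.log2(out)
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.data.index, columns=matrix.data.columns),
        require_non_negative=False,
    )


def apply_preprocessing(matrix: ExpressionMatrix, cfg: PreprocessConfig) -> ExpressionMatrix:
    """Dispatch on ``cfg.mode``; ``"none"`` passes the matrix through."""
    if cfg.mode == "sample_sum":
        return normalize_by_sample_sum(matrix, cfg.scale)
    if cfg.mode == "log2":
        return log2_transform(matrix, cfg.zero_replacement_factor)
    return matrix
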