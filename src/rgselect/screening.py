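"""Genome-scale candidate mining from an expression matrix.

Stably expressed, moderately abundant genes make good qPCR reference
candidates.  The screen keeps genes whose RPKM-like expression stays
inside a medium-abundance window at *every* condition and whose
coefficient of variation (CV = sd / mean, sample standard deviation)
across conditions is at most ``cv_max``.  Defaults: window [200, 2000]
(inclusive bounds) and CV <= 0.35.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ZeroMeanError
from .tables_io import ExpressionMatrix, RunConfig


def relative_expression(values) -> np.ndarray:
    """Expression vector divided by its arithmetic mean (output mean = 1)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("expression values must be >= 0")
    mean = v.mean()
    if mean == 0:
        raise ZeroMeanError("relative expression undefined for an all-zero vector")
    return v / mean


def coefficient_of_variation(values) -> float:
    """Sample (n-1) standard deviation over the mean; scale-free."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("CV needs at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ZeroMeanError("CV undefined for zero-mean values")
    return float(np.std(v, ddof=1) / mean)


def expression_window_filter(m: ExpressionMatrix, lo: float, hi: float) -> np.ndarray:
    """Per-gene flag: True iff every condition's value lies in [lo, hi]."""
    if not lo < hi:
        raise ValueError("window requires lo < hi")
    return np.all((m.values >= lo) & (m.values <= hi), axis=1)


@dataclass
class ScreeningResult:
    """Per-gene screen outcome; ``selected = in_window AND passes_cv``."""

    gene_ids: list[str]
    mean_expression: np.ndarray
    cv: np.ndarray
    in_window: np.ndarray
    passes_cv: np.ndarray
    selected: np.ndarray
    lo: float
    hi: float
    cv_max: float

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.gene_ids,
                "mean_expression": self.mean_expression,
                "cv": self.cv,
                "in_window": self.in_window,
                "passes_cv": self.passes_cv,
                "selected": self.selected,
            }
        )


def screen_candidates(
    m: ExpressionMatrix,
    cfg: RunConfig | None = None,
    *,
    lo: float | None = None,
    hi: float | None = None,
    cv_max: float | None = None,
) -> ScreeningResult:
    """Apply the expression-window and CV filters to every gene.

    Thresholds come from ``cfg`` (or the study defaults) unless
    overridden by keyword.  Genes with zero mean expression get CV = inf
    and fail the CV filter rather than raising: a silent row of zeros is
    routine in genome-scale tables.
    """
    cfg = cfg or RunConfig()
    lo = cfg.expr_min if lo is None else lo
    hi = cfg.expr_max if hi is None else hi
    cv_max = cfg.cv_max if cv_max is None else cv_max
    if m.values.shape[1] < 2:
        raise InsufficientDataError("screening needs >= 2 condition columns")

    means = m.values.mean(axis=1)
    sds = np.std(m.values, axis=1, ddof=1)
    cv = np.where(means > 0, sds / np.where(means > 0, means, 1.0), np.inf)
    in_window = expression_window_filter(m, lo, hi)
    passes_cv = cv <= cv_max
    selected = in_window & passes_cv
    return ScreeningResult(
        list(m.gene_ids), means, cv, in_window, passes_cv, selected, lo, hi, cv_max
    )
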