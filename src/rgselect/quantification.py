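"""Standard-curve fits, normalization factors, and relative quantification.

The amplification efficiency E of a primer pair comes from an ordinary
least-squares fit of Ct against log10 template amount over a serial
dilution: E = 10^(-1/slope) - 1, with E = 1 meaning perfect per-cycle
doubling.  Target-gene expression is then reported as 2^-ddCt fold
changes relative to a calibrator stage, normalized by the geometric-mean
normalization factor of one or more reference genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    MissingCtError,
    ZeroVarianceError,
)
from .stability import QuantityMatrix, _amp_vector, ct_to_quantity
from .tables_io import CtMatrix, Sample


@dataclass
class StandardCurve:
    """Dilution-series regression: Ct ~ log10 relative template amount."""

    dilution_log10: np.ndarray
    ct: np.ndarray
    slope: float
    intercept: float
    efficiency: float
    r_squared: float


def efficiency_from_slope(slope: float) -> float:
    """E = 10^(-1/slope) - 1; slope -3.3219 (= -1/log10 2) gives E = 1."""
    if slope == 0:
        raise DegenerateDesignError("zero slope: efficiency undefined")
    return float(10.0 ** (-1.0 / slope) - 1.0)


def fit_standard_curve(dilution_log10, ct) -> StandardCurve:
    """OLS line through a dilution series; needs >= 3 distinct dilutions."""
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dilution and Ct vectors must be equal-length 1-D")
    if x.size < 3:
        raise InsufficientDataError("standard curve needs >= 3 points")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all dilution values equal; cannot fit a slope")
    fit = stats.linregress(x, y)
    return StandardCurve(
        dilution_log10=x,
        ct=y,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=efficiency_from_slope(float(fit.slope)),
        r_squared=float(fit.rvalue) ** 2,
    )


def _gmean(v: np.ndarray, axis=None) -> np.ndarray:
    return np.exp(np.mean(np.log(v), axis=axis))


def normalization_factor(m: CtMatrix, rg_genes: Sequence[str], amp=2.0) -> np.ndarray:
    """Per-sample geometric mean of the reference genes' relative quantities.

    ``rg_genes`` has set semantics: listing a gene twice does not weight
    it twice, so NF is invariant to duplicates in the list.
    """
    missing = [g for g in rg_genes if g not in m.gene_ids]
    if missing:
        raise KeyError(f"reference genes not in matrix: {missing}")
    if not rg_genes:
        raise ValueError("need at least one reference gene")
    uniq = list(dict.fromkeys(rg_genes))
    sub = m.select_genes(uniq)
    if np.isnan(sub.ct).any():
        raise MissingCtError(f"missing Ct among reference genes {uniq}")
    qm = ct_to_quantity(sub, amp if not isinstance(amp, Mapping) else
                        {g: amp[g] for g in uniq})
    return _gmean(qm.q, axis=0)


@dataclass
class QuantificationResult:
    """Per-sample fold changes and per-stage summaries vs a calibrator."""

    sample_ids: list[str]
    stages: list[str]
    normalization_factor: np.ndarray
    fold_change: np.ndarray
    stage_order: list[str]
    stage_mean: dict[str, float]
    stage_sd: dict[str, float]
    calibrator_stage: str | None

    @property
    def stage_mean_series(self) -> np.ndarray:
        return np.array([self.stage_mean[s] for s in self.stage_order])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "stage": self.stages,
                "normalization_factor": self.normalization_factor,
                "fold_change": self.fold_change,
            }
        )


def relative_quantification(
    target_ct,
    nf,
    calibrator,
    amp: float = 2.0,
    samples: Sequence[Sample] | None = None,
) -> QuantificationResult:
    """2^-ddCt-style fold changes of a target against a normalization factor.

    ``calibrator`` is a boolean mask (or index list) over samples marking
    the calibrator set.  The normalized quantity u(s) = A^(-Ct_t(s)) / NF(s)
    is referenced to the geometric mean of u over calibrator samples, so
    the calibrator's geometric-mean fold change is 1 by construction.
    Stage summaries (arithmetic mean and sd of replicate fold changes)
    are attached when sample metadata is supplied.
    """
    ct = np.asarray(target_ct, dtype=float)
    nf = np.asarray(nf, dtype=float)
    if ct.shape != nf.shape or ct.ndim != 1:
        raise ValueError("target Ct and NF must be equal-length vectors")
    if np.isnan(ct).any():
        raise MissingCtError("missing Ct in target vector")
    if amp <= 1:
        raise ValueError("amplification factor must be > 1")
    calib = np.asarray(calibrator)
    if calib.dtype == bool:
        mask = calib
    else:
        mask = np.isin(np.arange(ct.size), calib.astype(int))
    if mask.size != ct.size or not mask.any():
        raise ValueError("calibrator set must be a non-empty subset of samples")

    # work on log2 scale to dodge underflow for large Ct
    log2_u = -ct * np.log2(amp) - np.log2(nf)
    fold = 2.0 ** (log2_u - log2_u[mask].mean())

    sample_ids = [s.sample_id for s in samples] if samples else [str(i) for i in range(ct.size)]
    stages = [s.stage for s in samples] if samples else [""] * ct.size
    stage_order: list[str] = []
    for s in stages:
        if s and s not in stage_order:
            stage_order.append(s)
    stage_mean = {
        st: float(np.mean(fold[[i for i, x in enumerate(stages) if x == st]]))
        for st in stage_order
    }
    stage_sd = {
        st: float(np.std(fold[[i for i, x in enumerate(stages) if x == st]], ddof=1))
        if stages.count(st) > 1
        else 0.0
        for st in stage_order
    }
    calib_stage = None
    if samples:
        calib_stages = {stages[i] for i in np.nonzero(mask)[0]}
        if len(calib_stages) == 1:
            calib_stage = calib_stages.pop()
    return QuantificationResult(
        sample_ids, stages, nf, fold, stage_order, stage_mean, stage_sd, calib_stage
    )


def quantify(
    m: CtMatrix,
    target_gene: str,
    rg_genes: Sequence[str],
    calibrator_stage: str,
    amp: float = 2.0,
) -> QuantificationResult:
    """Convenience wrapper: NF from ``rg_genes``, folds vs ``calibrator_stage``."""
    if target_gene not in m.gene_ids:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    if target_gene in rg_genes:
        raise ValueError("target gene cannot also be a reference gene")
    nf = normalization_factor(m, rg_genes, amp)
    mask = np.array([s.stage == calibrator_stage for s in m.samples])
    if not mask.any():
        raise ValueError(f"no samples at calibrator stage {calibrator_stage!r}")
    return relative_quantification(m.row(target_gene), nf, mask, amp, samples=m.samples)


def trait_correlation(stage_means, trait) -> float:
    """Pearson correlation between a fold-change series and a trait series."""
    x = np.asarray(stage_means, dtype=float)
    y = np.asarray(trait, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be equal-length vectors")
    if x.size < 3:
        raise InsufficientDataError("correlation needs >= 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ZeroVarianceError("correlation undefined for a constant series")
    return float(stats.pearsonr(x, y).statistic)
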