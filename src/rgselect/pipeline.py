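"""End-to-end orchestration: screen -> stability -> consensus -> quantify.

A run takes a Ct table (mandatory), an optional genome-scale expression
table for the candidate screen, and optionally a target gene plus a
trait series for the validation stage.  Every threshold lives in a
:class:`~rgselect.tables_io.RunConfig`; the returned
:class:`PipelineRun` snapshots the config, the input digests, every
stage's output, and a line-by-line log, so a run is reproducible
bit-for-bit from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import RgSelectError
from .quantification import QuantificationResult, quantify, trait_correlation
from .screening import ScreeningResult, screen_candidates
from .stability import (
    ConsensusSelection,
    MinimalRgCount,
    StabilityReport,
    consensus_select,
    evaluate_stability,
    minimal_rg_count,
)
from .tables_io import CtMatrix, ExpressionMatrix, RunConfig

logger = logging.getLogger("rgselect")


def _digest(arrays: Sequence[np.ndarray], *texts: str) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    for t in texts:
        h.update(t.encode())
    return h.hexdigest()[:16]


class StageError(RgSelectError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineRun:
    """Everything one pipeline execution produced."""

    config: RunConfig
    digests: dict[str, str]
    screening: ScreeningResult | None
    report: StabilityReport
    selection: ConsensusSelection
    minimal: MinimalRgCount
    rg_used: list[str]
    quantification: QuantificationResult | None
    trait_r: float | None
    log: list[str] = field(default_factory=list)

    @property
    def selected_genes(self) -> list[str]:
        return list(self.selection.selected)


def run_pipeline(
    cfg: RunConfig,
    ct: CtMatrix,
    expression: ExpressionMatrix | None = None,
    target_gene: str | None = None,
    trait: Sequence[float] | None = None,
    efficiencies: Mapping[str, float] | None = None,
) -> PipelineRun:
    """Execute all stages in order with the thresholds in ``cfg``.

    When ``target_gene`` names a row of ``ct``, that row is excluded from
    the stability panel and quantified against the best
    ``minimal_rg_count`` consensus reference genes; a ``trait`` series
    (one value per stage, in stage order) is then correlated with the
    per-stage fold changes.
    """
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    digests = {"ct": _digest([ct.ct], *ct.gene_ids)}
    if expression is not None:
        digests["expression"] = _digest([expression.values], *expression.gene_ids)
    say(f"config: {cfg.to_dict()}")
    say(f"input digests: {digests}")

    screening = None
    if expression is not None:
        try:
            screening = screen_candidates(expression, cfg)
        except RgSelectError as e:
            raise StageError(f"screening: {e}") from e
        say(
            f"screening: {screening.n_selected}/{len(screening.gene_ids)} genes pass "
            f"window [{cfg.expr_min}, {cfg.expr_max}] and CV <= {cfg.cv_max}"
        )
    else:
        say("screening: skipped (no expression table)")

    panel = ct
    if target_gene is not None and target_gene in ct.gene_ids:
        panel = ct.select_genes([g for g in ct.gene_ids if g != target_gene])
        say(f"stability: target gene {target_gene!r} excluded from the panel")
    try:
        report = evaluate_stability(
            panel, amp=cfg.amp_factor, collapse_tech=cfg.collapse_tech
        )
        k_top = min(cfg.k_top, len(report.gene_ids))
        selection = consensus_select(
            report,
            k_top=k_top,
            min_methods=cfg.min_methods,
            ct_mean_max=cfg.ct_mean_max,
            eff_min=cfg.eff_min,
            eff_max=cfg.eff_max,
            efficiencies=efficiencies,
        )
        minimal = minimal_rg_count(report.genorm, cfg.v_threshold)
    except RgSelectError as e:
        raise StageError(f"stability: {e}") from e
    say(
        f"stability: geNorm final pair {report.genorm.final_pair}; "
        f"consensus {len(selection.consensus)} genes, selected {len(selection.selected)} "
        f"after QC (dropped: {selection.dropped or 'none'})"
    )
    say(
        f"minimal RG count: {minimal.n} (V threshold {cfg.v_threshold}"
        + (", no V below threshold)" if minimal.warning else ")")
    )

    quantification = None
    trait_r = None
    rg_used: list[str] = []
    if target_gene is not None:
        if target_gene not in ct.gene_ids:
            raise StageError(f"quantification: target gene {target_gene!r} not in Ct table")
        pool = selection.selected or report.genorm.ranking
        ranked = [g for g in report.genorm.ranking if g in set(pool)]
        rg_used = ranked[: minimal.n]
        try:
            work = ct
            if cfg.collapse_tech:
                from .tables_io import collapse_technical_replicates

                work = collapse_technical_replicates(ct)
            quantification = quantify(
                work, target_gene, rg_used, cfg.calibrator_stage, cfg.amp_factor
            )
        except (RgSelectError, KeyError, ValueError) as e:
            raise StageError(f"quantification: {e}") from e
        say(
            f"quantification: target {target_gene!r} vs RGs {rg_used}, "
            f"calibrator {cfg.calibrator_stage!r}; stage means "
            + ", ".join(
                f"{s}={quantification.stage_mean[s]:.3g}" for s in quantification.stage_order
            )
        )
        if trait is not None:
            try:
                trait_r = trait_correlation(quantification.stage_mean_series, trait)
            except RgSelectError as e:
                raise StageError(f"trait correlation: {e}") from e
            say(f"trait correlation: r = {trait_r:.4f}")
    elif trait is not None:
        say("trait correlation: skipped (no target gene)")

    return PipelineRun(
        config=cfg,
        digests=digests,
        screening=screening,
        report=report,
        selection=selection,
        minimal=minimal,
        rg_used=rg_used,
        quantification=quantification,
        trait_r=trait_r,
        log=log,
    )
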