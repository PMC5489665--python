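"""Delimited-text tables and core data containers for the pipeline.

Three table shapes flow through the pipeline, all plain UTF-8 delimited
text (TSV by default, CSV accepted, "." decimal separator):

* gene x condition expression matrices (RPKM-like values) — the
  genome-scale screening substrate;
* long-format qPCR Ct tables with columns
  ``gene, sample, stage, bio_rep, tech_rep, ct`` — the stability and
  quantification substrate (a wide gene x sample dialect with metadata
  header rows is also accepted);
* the per-gene score report emitted after stability analysis.

Missing Ct is encoded as an empty field or ``NA`` — never 0, since 0 is a
legal (if absurd) cycle number.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    DuplicateGeneError,
    DuplicateSampleError,
    MissingTableError,
    NegativeExpressionError,
    NonNumericCellError,
    TableValidationError,
    UnknownColumnError,
)

logger = logging.getLogger("rgselect")

#: canonical long-format Ct columns
LONG_COLUMNS = ("gene", "sample", "stage", "bio_rep", "tech_rep", "ct")

#: default developmental-stage labels (user-defined strings are equally valid)
DEFAULT_STAGES = ("IM", "MG", "B", "MR")

#: Ct values outside this window trigger a warning (not an error)
CT_PLAUSIBLE_RANGE = (5.0, 45.0)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sample:
    """One qPCR well/sample: stage label plus replicate coordinates."""

    sample_id: str
    stage: str
    bio_rep: int
    tech_rep: int = 1

    @property
    def triple(self) -> tuple[str, int, int]:
        return (self.stage, self.bio_rep, self.tech_rep)


@dataclass
class ExpressionMatrix:
    """Genes x conditions matrix of non-negative expression values.

    ``values`` are RPKM-like units; conditions are developmental stages
    and/or tissue columns, in table order.
    """

    gene_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.condition_labels = [str(c) for c in self.condition_labels]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.condition_labels)):
            raise TableValidationError(
                f"values grid {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_labels)} conditions"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DuplicateGeneError(f"duplicate gene ids: {dupes}")
        if not np.all(np.isfinite(self.values)):
            raise TableValidationError("expression values must be finite")
        if np.any(self.values < 0):
            bad = self.gene_ids[int(np.argwhere(self.values < 0)[0][0])]
            raise NegativeExpressionError(f"negative expression value for gene {bad!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def select_columns(self, labels: Sequence[str]) -> "ExpressionMatrix":
        """Matrix restricted to the given condition columns (screen per data set)."""
        idx = [self.condition_labels.index(c) for c in labels]
        return ExpressionMatrix(
            list(self.gene_ids), [str(c) for c in labels], self.values[:, idx], self.source_tag
        )


@dataclass
class CtMatrix:
    """Genes x samples grid of qPCR Ct values (NaN marks missing)."""

    gene_ids: list[str]
    samples: list[Sample]
    ct: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.ct = np.asarray(self.ct, dtype=float)
        if self.ct.shape != (len(self.gene_ids), len(self.samples)):
            raise TableValidationError(
                f"ct grid {self.ct.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise DuplicateGeneError(f"duplicate gene ids: {dupes}")
        triples = [s.triple for s in self.samples]
        if len(set(triples)) != len(triples):
            dupes = sorted({t for t in triples if triples.count(t) > 1})
            raise DuplicateSampleError(
                f"duplicate (stage, bio_rep, tech_rep) triples: {dupes}"
            )
        finite = self.ct[~np.isnan(self.ct)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise TableValidationError("non-missing Ct values must be finite")
        lo, hi = CT_PLAUSIBLE_RANGE
        if finite.size and (finite.min() < lo or finite.max() > hi):
            warnings.warn(
                f"Ct values outside the plausible {lo}-{hi} cycle range",
                UserWarning,
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def stage_labels(self) -> list[str]:
        """Stage labels in order of first appearance."""
        seen: list[str] = []
        for s in self.samples:
            if s.stage not in seen:
                seen.append(s.stage)
        return seen

    @property
    def stages(self) -> np.ndarray:
        return np.array([s.stage for s in self.samples])

    def row(self, gene: str) -> np.ndarray:
        return self.ct[self.gene_ids.index(gene)]

    def select_genes(self, genes: Sequence[str]) -> "CtMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return CtMatrix([str(g) for g in genes], list(self.samples), self.ct[idx])

    def mean_ct(self) -> np.ndarray:
        """Per-gene mean over non-missing Ct values."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.ct, axis=1)


@dataclass
class RunConfig:
    """All thresholds for a pipeline run (defaults follow the study design)."""

    expr_min: float = 200.0
    expr_max: float = 2000.0
    cv_max: float = 0.35
    k_top: int = 12
    min_methods: int = 2
    ct_mean_max: float = 28.0
    eff_min: float = 0.9
    eff_max: float = 1.1
    v_threshold: float = 0.15
    amp_factor: float = 2.0
    collapse_tech: bool = True
    calibrator_stage: str = "IM"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.expr_min < self.expr_max:
            raise ConfigError("expr_min must be < expr_max")
        if not self.cv_max > 0:
            raise ConfigError("cv_max must be > 0")
        if not self.eff_min < self.eff_max:
            raise ConfigError("eff_min must be < eff_max")
        if not 0 < self.v_threshold < 1:
            raise ConfigError("v_threshold must lie in (0, 1)")
        if self.amp_factor <= 1:
            raise ConfigError("amp_factor must be > 1")
        if self.k_top < 1 or self.min_methods < 1:
            raise ConfigError("k_top and min_methods must be >= 1")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword overrides win over file values."""
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a key/value mapping")
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def _check_path(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise MissingTableError(f"input table not found: {p}")
    return p


def read_expression_table(
    path: str | Path, sep: str | None = None, source_tag: str = ""
) -> ExpressionMatrix:
    """Read a gene x condition expression table.

    First column holds gene ids, header row names the conditions.  The
    delimiter is sniffed when ``sep`` is None (TSV and CSV both work).
    """
    p = _check_path(path)
    df = pd.read_csv(p, sep=sep, engine="python" if sep is None else "c", dtype=str)
    if df.shape[1] < 2:
        raise TableValidationError(f"{p}: expected gene column plus >=1 condition column")
    genes = df.iloc[:, 0].astype(str).tolist()
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise DuplicateGeneError(f"{p}: duplicate gene rows {dupes}")
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise NonNumericCellError(
            f"{p}: non-numeric value {body.iat[r, c]!r} at gene {genes[r]!r}, "
            f"condition {body.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise TableValidationError(f"{p}: expression tables may not contain missing values")
    m = ExpressionMatrix(genes, list(body.columns), numeric.to_numpy(float), source_tag or str(p))
    logger.info("read expression table %s: %d genes x %d conditions", p, m.n_genes, len(m.condition_labels))
    return m


def write_expression_table(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.condition_labels)
    df.index.name = "gene"
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path, sep: str | None = None, layout: str = "long") -> CtMatrix:
    """Read a qPCR Ct table.

    ``layout="long"`` (canonical) expects columns gene, sample, stage,
    bio_rep, tech_rep, ct; empty/NA ct cells become missing entries.
    ``layout="wide"`` expects a gene x sample grid preceded by three
    metadata header rows (stage, bio_rep, tech_rep).
    """
    p = _check_path(path)
    if layout == "wide":
        return _read_ct_wide(p, sep)
    if layout != "long":
        raise ValueError(f"unknown layout {layout!r}")
    df = pd.read_csv(
        p, sep=sep, engine="python" if sep is None else "c", dtype=str,
        keep_default_na=False,
    )
    cols = list(df.columns)
    missing = [c for c in LONG_COLUMNS if c not in cols]
    extra = [c for c in cols if c not in LONG_COLUMNS]
    if missing or extra:
        raise UnknownColumnError(
            f"{p}: expected columns {list(LONG_COLUMNS)}; missing {missing}, unknown {extra}"
        )

    def parse_ct(v: str) -> float:
        v = v.strip()
        if v == "" or v.upper() in {"NA", "NAN"}:
            return np.nan
        try:
            return float(v)
        except ValueError:
            raise NonNumericCellError(f"{p}: non-numeric ct value {v!r}") from None

    genes: list[str] = []
    sample_meta: dict[str, Sample] = {}
    values: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        gene, sample_id = str(row.gene), str(row.sample)
        try:
            meta = Sample(sample_id, str(row.stage), int(row.bio_rep), int(row.tech_rep))
        except ValueError:
            raise NonNumericCellError(
                f"{p}: bio_rep/tech_rep must be integers (gene {gene!r}, sample {sample_id!r})"
            ) from None
        if gene not in genes:
            genes.append(gene)
        if sample_id in sample_meta:
            if sample_meta[sample_id] != meta:
                raise TableValidationError(
                    f"{p}: sample {sample_id!r} has inconsistent stage/replicate metadata"
                )
        else:
            sample_meta[sample_id] = meta
        key = (gene, sample_id)
        if key in values:
            raise DuplicateSampleError(f"{p}: duplicated (gene, sample) pair {key}")
        values[key] = parse_ct(str(row.ct))

    samples = list(sample_meta.values())
    grid = np.full((len(genes), len(samples)), np.nan)
    for (gene, sample_id), v in values.items():
        grid[genes.index(gene), [s.sample_id for s in samples].index(sample_id)] = v
    m = CtMatrix(genes, samples, grid)
    logger.info("read ct table %s: %d genes x %d samples", p, m.n_genes, m.n_samples)
    return m


def _read_ct_wide(p: Path, sep: str | None) -> CtMatrix:
    df = pd.read_csv(p, sep=sep, engine="python" if sep is None else "c",
                     dtype=str, keep_default_na=False, index_col=0)
    for meta_row in ("stage", "bio_rep", "tech_rep"):
        if meta_row not in df.index[:3]:
            raise UnknownColumnError(
                f"{p}: wide layout needs metadata rows stage/bio_rep/tech_rep before genes"
            )
    samples = [
        Sample(str(c), str(df.loc["stage", c]), int(df.loc["bio_rep", c]),
               int(df.loc["tech_rep", c]))
        for c in df.columns
    ]
    body = df.drop(index=["stage", "bio_rep", "tech_rep"])
    grid = body.replace({"": np.nan, "NA": np.nan}).apply(pd.to_numeric).to_numpy(float)
    return CtMatrix(list(body.index.astype(str)), samples, grid)


def write_ct_table(m: CtMatrix, path: str | Path, sep: str = "\t", layout: str = "long") -> None:
    """Write a Ct matrix (long canonical layout; wide on request)."""
    if layout == "wide":
        meta = pd.DataFrame(
            {
                s.sample_id: [s.stage, s.bio_rep, s.tech_rep]
                for s in m.samples
            },
            index=["stage", "bio_rep", "tech_rep"],
        )
        body = pd.DataFrame(m.ct, index=m.gene_ids, columns=[s.sample_id for s in m.samples])
        out = pd.concat([meta, body])
        out.index.name = "gene"
        out.to_csv(path, sep=sep, na_rep="")
        return
    rows = []
    for gi, gene in enumerate(m.gene_ids):
        for si, s in enumerate(m.samples):
            v = m.ct[gi, si]
            rows.append(
                (gene, s.sample_id, s.stage, s.bio_rep, s.tech_rep,
                 "" if np.isnan(v) else repr(float(v)))
            )
    pd.DataFrame(rows, columns=list(LONG_COLUMNS)).to_csv(path, sep=sep, index=False)


def collapse_technical_replicates(m: CtMatrix) -> CtMatrix:
    """Average technical replicates into one sample per (stage, bio_rep).

    The collapsed Ct is the arithmetic mean of non-missing technical
    replicates; an all-missing triple stays missing.  Idempotent.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for i, s in enumerate(m.samples):
        groups.setdefault((s.stage, s.bio_rep), []).append(i)
    new_samples = [
        Sample(f"{stage}.{bio}", stage, bio, 1) for (stage, bio) in groups
    ]
    grid = np.full((m.n_genes, len(groups)), np.nan)
    for j, idx in enumerate(groups.values()):
        block = m.ct[:, idx]
        counts = np.sum(~np.isnan(block), axis=1)
        sums = np.nansum(np.where(np.isnan(block), 0.0, block), axis=1)
        grid[:, j] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CtMatrix(list(m.gene_ids), new_samples, grid)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def write_report(report, out_dir: str | Path, selection=None, minimal=None,
                 sep: str = "\t") -> dict[str, Path]:
    """Write the stability report as text files.

    Emits ``scores.tsv`` (per-gene score/rank table), ``summary.txt``
    (human-readable ranked lists, consensus, V curve, minimal RG set) and
    ``summary.json`` (the same content machine-readable).  ``report`` is a
    :class:`~rgselect.stability.StabilityReport`; ``selection`` and
    ``minimal`` are the consensus and minimal-count results when computed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": out / "scores.tsv",
        "summary_txt": out / "summary.txt",
        "summary_json": out / "summary.json",
    }
    frame = report.to_frame()
    frame.to_csv(paths["scores"], sep=sep, index=False)

    summary: dict = {
        "n_genes": len(report.gene_ids),
        "genorm_ranking": list(report.genorm.ranking),
        "genorm_final_pair": list(report.genorm.final_pair),
        "v_curve": {
            f"V{n}/{n + 1}": float(v)
            for n, v in zip(report.genorm.v_ns, report.genorm.v_values)
        },
    }
    if selection is not None:
        summary["consensus_genes"] = list(selection.consensus)
        summary["selected_genes"] = list(selection.selected)
        summary["qc_dropped"] = dict(selection.dropped)
        summary["k_top"] = selection.k_top
        summary["min_methods"] = selection.min_methods
    if minimal is not None:
        summary["minimal_rg_count"] = minimal.n
        summary["v_threshold"] = minimal.threshold
        summary["v_curve_warning"] = minimal.warning

    with open(paths["summary_json"], "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)

    lines = [
        "Reference-gene stability summary",
        "================================",
        f"genes analyzed: {summary['n_genes']}",
        "",
        "geNorm ranking (best first): " + ", ".join(summary["genorm_ranking"]),
        "geNorm final pair: " + " / ".join(summary["genorm_final_pair"]),
        "pairwise variation curve:",
    ]
    lines += [f"  {k} = {v:.4f}" for k, v in summary["v_curve"].items()]
    if selection is not None:
        lines += [
            "",
            f"consensus (top-{selection.k_top} in >= {selection.min_methods} methods): "
            + (", ".join(selection.consensus) or "(none)"),
            "selected after QC: " + (", ".join(selection.selected) or "(none)"),
        ]
        for g, reason in selection.dropped.items():
            lines.append(f"  dropped {g}: {reason}")
    if minimal is not None:
        note = " (no V below threshold; using largest n evaluated)" if minimal.warning else ""
        lines.append("")
        lines.append(
            f"minimal reference-gene count: {minimal.n} "
            f"(V threshold {minimal.threshold}){note}"
        )
    with open(paths["summary_txt"], "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("wrote report to %s", out)
    return paths


def read_report_scores(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read back the per-gene score table written by :func:`write_report`."""
    return pd.read_csv(_check_path(path), sep=sep)
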