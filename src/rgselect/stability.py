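"""Expression-stability statistics for candidate reference genes.

Three complementary views of "stably expressed" over a Ct matrix:

* **geNorm** — a gene's average pairwise variation M (sample standard
  deviation of log2 expression ratios) with all other candidates, a
  stepwise-exclusion ranking, and the pairwise-variation curve
  V(n, n+1) between normalization factors built from the n and n+1 best
  genes.  V below 0.15 means n genes suffice for normalization.
* **NormFinder** — the model-based variance decomposition of Andersen
  et al. (2004): per-group intra-group variances (corrected for
  sample-centering covariance) combined with shrunken inter-group
  expression differences.  Lower stability value = more stable.
* **Whisker D-value** — the boxplot whisker span, i.e. the plain Ct
  range max - min per gene.  A crude but assumption-free screen.

All statistics use log base 2 and sample (n-1) standard deviations.
Consensus selection intersects the methods' top-k lists and applies
mean-Ct and amplification-efficiency quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AllMissingError,
    GroupSizeError,
    InsufficientDataError,
    InsufficientGenesError,
    MissingCtError,
)
from .tables_io import CtMatrix, Sample, collapse_technical_replicates

__all__ = [
    "QuantityMatrix",
    "GeNormResult",
    "NormFinderResult",
    "StabilityReport",
    "ConsensusSelection",
    "MinimalRgCount",
    "ct_to_quantity",
    "genorm_pairwise_variation",
    "genorm_m_values",
    "genorm_rank",
    "genorm_v_curve",
    "normfinder_stability",
    "whisker_d_value",
    "boxplot_summary",
    "evaluate_stability",
    "consensus_select",
    "minimal_rg_count",
]


# ---------------------------------------------------------------------------
# quantities
# ---------------------------------------------------------------------------


@dataclass
class QuantityMatrix:
    """Relative quantities derived from Ct, anchored so max q = 1 per gene."""

    gene_ids: list[str]
    samples: list[Sample]
    q: np.ndarray

    def row(self, gene: str) -> np.ndarray:
        return self.q[self.gene_ids.index(gene)]


def _amp_vector(amp, gene_ids: Sequence[str]) -> np.ndarray:
    """Per-gene amplification factors from a scalar or a gene -> A mapping."""
    if isinstance(amp, Mapping):
        try:
            a = np.array([float(amp[g]) for g in gene_ids])
        except KeyError as e:
            raise KeyError(f"no amplification factor for gene {e.args[0]!r}") from None
    else:
        a = np.full(len(gene_ids), float(amp))
    if np.any(a <= 1):
        raise ValueError("amplification factors must be > 1 (A = 1 + E)")
    return a


def ct_to_quantity(m: CtMatrix, amp=2.0) -> QuantityMatrix:
    """Transform Ct to relative quantities q = A^(Ct_min - Ct).

    ``amp`` is a global amplification factor (default 2, the
    efficiency-agnostic convention) or a per-gene mapping A = 1 + E.
    The per-gene minimum Ct anchors the most abundant sample at q = 1.
    Missing Ct values are an error: collapse replicates or drop genes first.
    """
    if np.isnan(m.ct).any():
        bad = [g for g, row in zip(m.gene_ids, m.ct) if np.isnan(row).any()]
        raise MissingCtError(
            f"missing Ct for genes {bad}; collapse technical replicates, impute, "
            "or drop these genes before the quantity transform"
        )
    a = _amp_vector(amp, m.gene_ids)[:, None]
    q = a ** (m.ct.min(axis=1, keepdims=True) - m.ct)
    return QuantityMatrix(list(m.gene_ids), list(m.samples), q)


def _as_q_array(q) -> np.ndarray:
    arr = q.q if isinstance(q, QuantityMatrix) else np.asarray(q, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a genes x samples quantity grid")
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("quantities must be positive and finite")
    return arr


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------


def genorm_pairwise_variation(qj, qk) -> float:
    """Sample sd over samples of log2(qj / qk); symmetric in (j, k)."""
    qj = np.asarray(qj, dtype=float)
    qk = np.asarray(qk, dtype=float)
    if qj.shape != qk.shape:
        raise ValueError("quantity vectors must have equal length")
    if qj.size < 2:
        raise InsufficientDataError("pairwise variation needs >= 2 samples")
    return float(np.std(np.log2(qj / qk), ddof=1))


def _pairwise_v_matrix(x: np.ndarray) -> np.ndarray:
    """Symmetric matrix of pairwise variations from log2 quantities ``x``."""
    n = x.shape[0]
    v = np.zeros((n, n))
    for j in range(n):
        v[j] = np.std(x - x[j], axis=1, ddof=1)
    return v


def genorm_m_values(q) -> np.ndarray:
    """Per-gene M: mean pairwise variation with every other gene.

    Accepts a :class:`QuantityMatrix` or a positive genes x samples grid.
    With exactly two genes, M equals their mutual pairwise variation.
    """
    arr = _as_q_array(q)
    n = arr.shape[0]
    if n < 2:
        raise InsufficientGenesError("geNorm M needs >= 2 genes")
    v = _pairwise_v_matrix(np.log2(arr))
    if n == 2:
        return np.array([v[0, 1], v[0, 1]])
    return v.sum(axis=1) / (n - 1)


@dataclass
class GeNormResult:
    """Stepwise geNorm outcome for one Ct/quantity matrix."""

    gene_ids: list[str]
    #: M at the step each gene was excluded (final pair: their mutual V)
    m_values: np.ndarray
    #: worst-first exclusion order (does not include the final pair)
    exclusion_order: list[str]
    final_pair: tuple[str, str]
    #: best-first ranking: final pair (lexicographic), then reversed exclusions
    ranking: list[str]
    #: V(n, n+1) for n = 2..N-1 along the ranking
    v_ns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    v_values: np.ndarray = field(default_factory=lambda: np.array([]))

    def m_of(self, gene: str) -> float:
        return float(self.m_values[self.gene_ids.index(gene)])


def genorm_rank(q: QuantityMatrix) -> GeNormResult:
    """Rank genes by stepwise exclusion of the least stable (highest M) gene.

    Ties on the worst M are broken by excluding the lexicographically
    greater gene id, so smaller ids rank better; the order is recorded in
    the result.  The final pair shares its mutual V as M value.
    """
    arr = _as_q_array(q)
    genes = list(q.gene_ids)
    n = len(genes)
    if n < 3:
        raise InsufficientGenesError("geNorm ranking needs >= 3 genes")
    v = _pairwise_v_matrix(np.log2(arr))

    active = list(range(n))
    m_at_exclusion = np.empty(n)
    exclusion: list[str] = []
    while len(active) > 2:
        sub = v[np.ix_(active, active)]
        m = sub.sum(axis=1) / (len(active) - 1)
        # worst M; ties -> lexicographically greatest gene id goes first
        worst_m = m.max()
        tied = [i for i, mi in zip(active, m) if mi == worst_m]
        worst = max(tied, key=lambda i: genes[i])
        m_at_exclusion[worst] = worst_m
        exclusion.append(genes[worst])
        active.remove(worst)

    a, b = sorted(active, key=lambda i: genes[i])
    mutual = v[a, b]
    m_at_exclusion[a] = m_at_exclusion[b] = mutual
    final_pair = (genes[a], genes[b])
    ranking = [genes[a], genes[b]] + list(reversed(exclusion))

    result = GeNormResult(genes, m_at_exclusion, exclusion, final_pair, ranking)
    order = [genes.index(g) for g in ranking]
    result.v_ns, result.v_values = _v_curve_from_log2(np.log2(arr), order)
    return result


def _v_curve_from_log2(x: np.ndarray, order: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    n = len(order)
    ns, vs = [], []
    for k in range(2, n):
        top_k = np.mean(x[list(order[:k])], axis=0)       # log2 of geometric-mean NF
        top_k1 = np.mean(x[list(order[: k + 1])], axis=0)
        ns.append(k)
        vs.append(float(np.std(top_k - top_k1, ddof=1)))
    return np.array(ns, dtype=int), np.array(vs)


def genorm_v_curve(q, ranking: Sequence[str] | Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise-variation curve V(n, n+1), n = 2..N-1, along a ranking.

    ``ranking`` lists genes best-first (gene ids for a
    :class:`QuantityMatrix`, or integer row indices for a raw grid).
    NF_n(s) is the geometric mean of the top-n genes' quantities at
    sample s; V(n, n+1) is the sample sd over samples of
    log2(NF_n / NF_{n+1}).
    """
    arr = _as_q_array(q)
    if arr.shape[0] < 3:
        raise InsufficientGenesError("V curve needs >= 3 ranked genes")
    if len(ranking) != arr.shape[0]:
        raise ValueError("ranking must cover every gene")
    if isinstance(q, QuantityMatrix) and ranking and isinstance(ranking[0], str):
        order = [q.gene_ids.index(g) for g in ranking]
    else:
        order = [int(i) for i in ranking]
    return _v_curve_from_log2(np.log2(arr), order)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------


@dataclass
class NormFinderResult:
    """Variance-decomposition outcome; lower stability = more stable."""

    gene_ids: list[str]
    group_labels: list[str]
    stability: np.ndarray
    #: shrunken inter-group expression differences (genes x groups)
    intergroup_difference: np.ndarray
    #: corrected intra-group variances, floored at 0 (genes x groups)
    intragroup_variance: np.ndarray

    def stability_of(self, gene: str) -> float:
        return float(self.stability[self.gene_ids.index(gene)])


def normfinder_stability(m: CtMatrix, groups=None) -> NormFinderResult:
    """Model-based stability values on log2 expression y = -Ct.

    ``groups`` maps samples to group labels (default: the stage label).
    The estimator: (1) center each sample across genes; (2) per
    gene/group take mean deviations d (group mean minus the gene's own
    across-group mean) and within-group sample variances;
    (3) correct variances for the covariance induced by centering across
    k genes and floor at 0; (4) shrink d toward 0 by its sampling
    variance relative to the moment-estimated inter-group variance;
    (5) stability = mean over groups of |d~| + sqrt(var / n_g).  With a
    single group the stability reduces to the corrected intra-group sd.
    """
    if np.isnan(m.ct).any():
        bad = [g for g, row in zip(m.gene_ids, m.ct) if np.isnan(row).any()]
        raise MissingCtError(f"missing Ct for genes {bad}; NormFinder needs a complete matrix")
    k = m.n_genes
    if k < 3:
        raise InsufficientGenesError("NormFinder needs >= 3 genes (centering correction)")

    if groups is None:
        labels = [s.stage for s in m.samples]
    elif isinstance(groups, Mapping):
        labels = [str(groups[s.sample_id]) for s in m.samples]
    else:
        labels = [str(g) for g in groups]
        if len(labels) != m.n_samples:
            raise ValueError("groups must cover every sample")
    group_order: list[str] = []
    for g in labels:
        if g not in group_order:
            group_order.append(g)
    n_groups = len(group_order)

    y = -m.ct  # log2 expression up to per-gene constants (A = 2)
    z = y - y.mean(axis=0, keepdims=True)  # center each sample across genes

    d = np.empty((k, n_groups))
    var = np.empty((k, n_groups))
    sizes = np.empty(n_groups)
    for j, g in enumerate(group_order):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        if len(idx) < 2:
            raise GroupSizeError(f"group {g!r} has {len(idx)} sample(s); need >= 2")
        sizes[j] = len(idx)
        block = z[:, idx]
        d[:, j] = block.mean(axis=1)
        s2 = block.var(axis=1, ddof=1)
        # centering across k genes deflates each variance and couples genes:
        # E[s2_ig] = sigma2_ig (1 - 2/k) + T_g / k^2 with T_g = sum_i sigma2_ig
        t_hat = s2.sum() * k / (k - 1)
        var[:, j] = np.maximum((s2 - t_hat / k**2) * k / (k - 2), 0.0)
    # deviations are relative to each gene's own level: row-center the
    # group means so a gene's baseline abundance carries no penalty
    d -= d.mean(axis=1, keepdims=True)

    sampling_var = var / sizes[None, :]
    if n_groups == 1:
        stability = np.sqrt(var[:, 0])
        d_shrunk = np.zeros_like(d)
    else:
        gamma2 = max(
            0.0,
            float(d.ravel() @ d.ravel()) / ((k - 1) * (n_groups - 1))
            - float(sampling_var.mean()),
        )
        denom = gamma2 + sampling_var
        with np.errstate(invalid="ignore"):
            shrink = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
        d_shrunk = d * shrink
        stability = (np.abs(d_shrunk) + np.sqrt(sampling_var)).mean(axis=1)

    return NormFinderResult(list(m.gene_ids), group_order, stability, d_shrunk, var)


# ---------------------------------------------------------------------------
# boxplot statistics
# ---------------------------------------------------------------------------


def whisker_d_value(cts) -> float:
    """Whisker span of the Ct boxplot: max - min over non-missing values."""
    v = np.asarray(cts, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise AllMissingError("whisker D undefined: all Ct values missing")
    if v.size < 2:
        raise InsufficientDataError("whisker D needs >= 2 non-missing Ct values")
    return float(v.max() - v.min())


def boxplot_summary(cts, method: str = "linear") -> tuple[float, float, float, float, float]:
    """Five-number summary (min, Q1, median, Q3, max) of a Ct vector.

    Quartiles interpolate linearly between order statistics by default
    (the spreadsheet-inclusive convention); any numpy percentile method
    name is accepted.  Only min/max feed the whisker D-value, so the
    quartile convention never affects gene selection.
    """
    v = np.asarray(cts, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise InsufficientDataError("boxplot summary needs >= 2 values")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method=method)
    return (float(v.min()), float(q1), float(med), float(q3), float(v.max()))


# ---------------------------------------------------------------------------
# report assembly, consensus, minimal set
# ---------------------------------------------------------------------------


def _ranks_with_tiebreak(scores: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Ranks 1..N, ascending score, ties broken by lexicographic gene id."""
    order = np.lexsort((np.array(gene_ids, dtype=object), scores))
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


@dataclass
class StabilityReport:
    """Per-gene scores and ranks from all three methods, plus QC columns."""

    gene_ids: list[str]
    whisker_d: np.ndarray
    genorm_m: np.ndarray
    normfinder: np.ndarray
    rank_whisker: np.ndarray
    rank_genorm: np.ndarray
    rank_normfinder: np.ndarray
    mean_ct: np.ndarray
    genorm: GeNormResult
    normfinder_result: NormFinderResult
    consensus_count: np.ndarray | None = None
    efficiency: np.ndarray | None = None
    qc_pass: np.ndarray | None = None
    selected: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "gene": self.gene_ids,
                "whisker_d": self.whisker_d,
                "rank_whisker": self.rank_whisker,
                "genorm_m": self.genorm_m,
                "rank_genorm": self.rank_genorm,
                "normfinder_stability": self.normfinder,
                "rank_normfinder": self.rank_normfinder,
                "mean_ct": self.mean_ct,
            }
        )
        if self.consensus_count is not None:
            df["consensus_count"] = self.consensus_count
        if self.efficiency is not None:
            df["efficiency"] = self.efficiency
        if self.qc_pass is not None:
            df["qc_pass"] = self.qc_pass
        if self.selected is not None:
            df["selected"] = self.selected
        return df


def evaluate_stability(
    m: CtMatrix,
    *,
    amp=2.0,
    collapse_tech: bool = True,
    groups=None,
) -> StabilityReport:
    """Run all three stability methods on a Ct matrix.

    Technical replicates are averaged first by default (the standard
    practice for a stages x bio x tech design); pass
    ``collapse_tech=False`` to score raw replicate wells.  ``groups``
    sets the NormFinder grouping (default: stage labels).
    """
    work = collapse_technical_replicates(m) if collapse_tech else m
    qm = ct_to_quantity(work, amp)
    gen = genorm_rank(qm)
    nf = normfinder_stability(work, groups)
    whisker = np.array([whisker_d_value(row) for row in work.ct])
    mean_ct = work.mean_ct()

    genorm_ranks = np.empty(work.n_genes, dtype=int)
    for r, g in enumerate(gen.ranking, start=1):
        genorm_ranks[work.gene_ids.index(g)] = r

    return StabilityReport(
        gene_ids=list(work.gene_ids),
        whisker_d=whisker,
        genorm_m=gen.m_values,
        normfinder=nf.stability,
        rank_whisker=_ranks_with_tiebreak(whisker, work.gene_ids),
        rank_genorm=genorm_ranks,
        rank_normfinder=_ranks_with_tiebreak(nf.stability, work.gene_ids),
        mean_ct=mean_ct,
        genorm=gen,
        normfinder_result=nf,
    )


@dataclass
class ConsensusSelection:
    """Genes surviving the multi-method intersection and QC filters."""

    selected: list[str]
    consensus: list[str]
    dropped: dict[str, str]
    k_top: int
    min_methods: int


def consensus_select(
    report: StabilityReport,
    *,
    k_top: int = 12,
    min_methods: int = 2,
    ct_mean_max: float = 28.0,
    eff_min: float = 0.9,
    eff_max: float = 1.1,
    efficiencies: Mapping[str, float] | None = None,
) -> ConsensusSelection:
    """Intersect the methods' top-k lists, then apply QC filters.

    A gene is a consensus candidate when it sits in the top ``k_top`` of
    at least ``min_methods`` of the three rankings.  QC then drops genes
    whose mean Ct exceeds ``ct_mean_max`` (weak expression inflates
    technical noise) or whose amplification efficiency falls outside
    [eff_min, eff_max]; genes without a known efficiency pass that check.
    The report's consensus/QC columns are filled in as a side effect and
    the selection is returned ordered by geNorm rank.
    """
    n = len(report.gene_ids)
    if k_top > n:
        raise InsufficientGenesError(f"k_top={k_top} exceeds the {n} genes scored")
    in_top = (
        (report.rank_whisker <= k_top).astype(int)
        + (report.rank_genorm <= k_top).astype(int)
        + (report.rank_normfinder <= k_top).astype(int)
    )
    consensus_mask = in_top >= min_methods

    eff = np.full(n, np.nan)
    if efficiencies:
        for i, g in enumerate(report.gene_ids):
            if g in efficiencies:
                eff[i] = float(efficiencies[g])

    qc_pass = np.ones(n, dtype=bool)
    dropped: dict[str, str] = {}
    for i, g in enumerate(report.gene_ids):
        if not consensus_mask[i]:
            continue
        if report.mean_ct[i] > ct_mean_max:
            qc_pass[i] = False
            dropped[g] = f"mean Ct {report.mean_ct[i]:.2f} > {ct_mean_max}"
        elif not np.isnan(eff[i]) and not (eff_min <= eff[i] <= eff_max):
            qc_pass[i] = False
            dropped[g] = f"efficiency {eff[i]:.2f} outside [{eff_min}, {eff_max}]"

    selected_mask = consensus_mask & qc_pass
    by_genorm = sorted(range(n), key=lambda i: report.rank_genorm[i])
    consensus = [report.gene_ids[i] for i in by_genorm if consensus_mask[i]]
    selected = [report.gene_ids[i] for i in by_genorm if selected_mask[i]]

    report.consensus_count = in_top
    report.efficiency = eff
    report.qc_pass = qc_pass
    report.selected = selected_mask
    return ConsensusSelection(selected, consensus, dropped, k_top, min_methods)


@dataclass
class MinimalRgCount:
    """Smallest number of reference genes with V(n, n+1) under threshold."""

    n: int
    threshold: float
    warning: bool  # True when no V dipped below the threshold

    def __int__(self) -> int:
        return self.n


def minimal_rg_count(v_curve, threshold: float = 0.15) -> MinimalRgCount:
    """Read the minimal reference-gene count off a V curve.

    ``v_curve`` is a :class:`GeNormResult` or a ``(ns, values)`` pair.
    Returns the smallest n with V(n, n+1) < threshold; if no entry drops
    below the threshold, the largest n evaluated is returned with a
    warning flag.
    """
    if isinstance(v_curve, GeNormResult):
        ns, vs = v_curve.v_ns, v_curve.v_values
    else:
        ns, vs = v_curve
        ns = np.asarray(ns, dtype=int)
        vs = np.asarray(vs, dtype=float)
    if len(ns) == 0:
        raise InsufficientDataError("empty V curve")
    below = np.nonzero(vs < threshold)[0]
    if below.size:
        return MinimalRgCount(int(ns[below[0]]), threshold, False)
    return MinimalRgCount(int(ns[-1]), threshold, True)
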