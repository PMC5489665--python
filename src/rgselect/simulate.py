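"""Synthetic expression, Ct, dilution, and trait data with known truth.

Every generator is a deterministic function of its parameters and a
seed, and plants an explicit ground truth (which genes are stable, what
drift each unstable gene carries, what the true amplification efficiency
is) so that each pipeline stage can be tested by recovery rather than by
golden files.

The error model follows qPCR practice: Gaussian noise on the Ct (log)
scale, split into a biological component shared by a gene's technical
replicates and an independent technical component; expression values are
log-normal around each gene's baseline.  The default Ct design mirrors a
fruit-development study: 35 genes over four stages (IM, MG, B, MR) with
three biological and three technical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .tables_io import DEFAULT_STAGES, CtMatrix, ExpressionMatrix, Sample

#: drift shapes available to unstable genes
SHAPES = ("ramp_up", "ramp_down", "bump")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated data set."""

    stable_genes: list[str]
    seed: int
    replicate_noise_sd: float = 0.0
    technical_noise_sd: float = 0.0
    #: per-gene baseline (Ct cycles, or RPKM for expression tables)
    baseline: dict[str, float] = field(default_factory=dict)
    #: per-gene drift profile across stages (cycles / log2 units); stable genes: zeros
    stage_effect: dict[str, np.ndarray] = field(default_factory=dict)
    #: per-gene peak-to-peak drift amplitude (0 for stable genes)
    amplitude: dict[str, float] = field(default_factory=dict)
    #: per-gene drift shape name ("none" for stable genes)
    shape: dict[str, str] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def is_stable(self, gene: str) -> bool:
        return gene in set(self.stable_genes)


def _stage_effect(rng: np.random.Generator, n_stages: int, amplitude: float) -> tuple[np.ndarray, str]:
    """One random drift profile with the given peak-to-peak amplitude.

    Ramps take a random path (sorted uniform way-points), and every
    profile gets gene-specific per-stage wiggle before being rescaled to
    the exact peak-to-peak amplitude.  Developmental drift in real
    panels is gene-specific; without the wiggle, drifting genes of
    similar amplitude would form a near-proportional family that looks
    co-regulated — i.e. spuriously stable — to any ratio-based
    stability criterion.
    """
    shape = SHAPES[rng.integers(len(SHAPES))]
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if shape in ("ramp_up", "ramp_down"):
        inner = np.sort(rng.uniform(0.0, 1.0, max(n_stages - 2, 0)))
        eff = amplitude * np.concatenate([[0.0], inner, [1.0]])[:n_stages]
        if shape == "ramp_down":
            eff = eff[::-1].copy()
    else:  # single-stage bump
        eff = np.zeros(n_stages)
        bump_at = int(rng.integers(n_stages))
        eff[bump_at] = amplitude
        shape = f"bump_{bump_at}"
    if n_stages > 1:
        eff = eff + rng.normal(0.0, 0.5 * amplitude, n_stages)
        eff *= amplitude / np.ptp(eff)
        eff -= eff.min()  # re-anchor: rescaling can inflate the common offset
    return sign * eff, shape


# ---------------------------------------------------------------------------
# expression matrices (RNA-seq screening substrate)
# ---------------------------------------------------------------------------


def generate_expression_matrix(
    n_genes: int = 2000,
    n_stages: int = 7,
    frac_stable: float = 0.5,
    window: tuple[float, float] = (200.0, 2000.0),
    frac_in_window: float = 0.5,
    cv_target: float = 0.2,
    unstable_log2_amplitude: tuple[float, float] = (1.5, 3.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Stage-structured RPKM-like matrix with planted low-CV genes.

    Stable genes get multiplicative log-normal noise with sigma chosen so
    the expected CV equals ``cv_target`` (sigma = sqrt(ln(1 + cv^2)));
    unstable genes additionally drift across stages by a log2 profile of
    peak-to-peak amplitude drawn from ``unstable_log2_amplitude``, which
    pushes their CV well past the screening threshold.  Baselines are
    log-uniform inside the abundance window for a ``frac_in_window``
    share of genes and outside it (both below and above) for the rest.
    """
    if not 0 <= frac_stable <= 1:
        raise ValueError("frac_stable must lie in [0, 1]")
    if cv_target <= 0:
        raise ValueError("cv_target must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = window
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_stable = int(round(frac_stable * n_genes))
    stable = set(rng.choice(n_genes, size=n_stable, replace=False).tolist())

    in_window = rng.random(n_genes) < frac_in_window
    baselines = np.empty(n_genes)
    inside = 10 ** rng.uniform(np.log10(lo * 1.15), np.log10(hi / 1.15), n_genes)
    below = 10 ** rng.uniform(np.log10(5.0), np.log10(lo / 1.5), n_genes)
    above = 10 ** rng.uniform(np.log10(hi * 1.5), np.log10(hi * 12), n_genes)
    outside = np.where(rng.random(n_genes) < 0.5, below, above)
    baselines = np.where(in_window, inside, outside)

    sigma = np.sqrt(np.log1p(cv_target**2))
    truth = SyntheticTruth(
        stable_genes=[genes[i] for i in sorted(stable)],
        seed=seed,
        extra={"cv_target": cv_target, "window": window, "in_window_baseline": {}},
    )
    values = np.empty((n_genes, n_stages))
    for i, g in enumerate(genes):
        noise = rng.normal(0.0, sigma, n_stages)
        if i in stable:
            eff = np.zeros(n_stages)
            amp_i, shape = 0.0, "none"
        else:
            amp_i = rng.uniform(*unstable_log2_amplitude)
            eff, shape = _stage_effect(rng, n_stages, amp_i)
        # lognormal noise is mean-corrected so E[value] = baseline * 2^effect
        values[i] = baselines[i] * 2.0**eff * np.exp(noise - sigma**2 / 2)
        truth.baseline[g] = float(baselines[i])
        truth.stage_effect[g] = eff
        truth.amplitude[g] = float(amp_i)
        truth.shape[g] = shape
        truth.extra["in_window_baseline"][g] = bool(in_window[i])

    labels = [f"S{j + 1}" for j in range(n_stages)]
    return ExpressionMatrix(genes, labels, values, source_tag=f"synthetic(seed={seed})"), truth


# ---------------------------------------------------------------------------
# Ct matrices (qPCR substrate)
# ---------------------------------------------------------------------------


def generate_ct_matrix(
    n_genes: int = 35,
    stages: Sequence[str] = DEFAULT_STAGES,
    n_bio: int = 3,
    n_tech: int = 3,
    frac_stable: float = 0.3,
    baseline_range: tuple[float, float] = (19.0, 29.0),
    amplitude_range: tuple[float, float] = (1.5, 3.0),
    bio_noise_sd: float = 0.15,
    tech_noise_sd: float = 0.10,
    seed: int = 0,
) -> tuple[CtMatrix, SyntheticTruth]:
    """Ct grid with planted stable and stage-drifting genes.

    Ct(g, stage, b, t) = baseline_g + effect_g(stage) + bio(g, stage, b)
    + tech(g, stage, b, t).  Stable genes have effect identically zero;
    unstable genes drift by a random ramp or single-stage bump whose
    peak-to-peak amplitude is drawn from ``amplitude_range`` (cycles).
    """
    if n_bio < 1 or n_tech < 1 or not stages:
        raise ValueError("design must be non-empty")
    rng = np.random.default_rng(seed)
    stages = [str(s) for s in stages]
    genes = [f"RG{i + 1:03d}" for i in range(n_genes)]
    n_stable = int(round(frac_stable * n_genes))
    stable = set(rng.choice(n_genes, size=n_stable, replace=False).tolist())
    baselines = rng.uniform(*baseline_range, n_genes)

    samples = [
        Sample(f"{st}.b{b + 1}.t{t + 1}", st, b + 1, t + 1)
        for st in stages
        for b in range(n_bio)
        for t in range(n_tech)
    ]
    truth = SyntheticTruth(
        stable_genes=[genes[i] for i in sorted(stable)],
        seed=seed,
        replicate_noise_sd=bio_noise_sd,
        technical_noise_sd=tech_noise_sd,
    )
    ct = np.empty((n_genes, len(samples)))
    n_stages = len(stages)
    for i, g in enumerate(genes):
        if i in stable:
            eff, shape, amp_i = np.zeros(n_stages), "none", 0.0
        else:
            amp_i = rng.uniform(*amplitude_range)
            eff, shape = _stage_effect(rng, n_stages, amp_i)
        bio = rng.normal(0.0, bio_noise_sd, (n_stages, n_bio))
        tech = rng.normal(0.0, tech_noise_sd, (n_stages, n_bio, n_tech))
        grid = baselines[i] + eff[:, None, None] + bio[:, :, None] + tech
        ct[i] = grid.ravel()
        truth.baseline[g] = float(baselines[i])
        truth.stage_effect[g] = eff
        truth.amplitude[g] = float(abs(amp_i))
        truth.shape[g] = shape
    return CtMatrix(genes, samples, ct), truth


def generate_target_profile(
    profile: Mapping[str, float],
    rg_genes: Sequence[str] = ("RGa", "RGb"),
    target_gene: str = "TARGET",
    n_bio: int = 3,
    target_baseline: float = 26.0,
    rg_baseline: float = 22.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CtMatrix, SyntheticTruth]:
    """Ct rows encoding a known log2 fold-change profile against flat RGs.

    ``profile`` maps each stage to the target's log2 fold change relative
    to the profile's first stage (the natural calibrator).  With zero
    noise, quantifying the target against the flat reference genes
    recovers 2^profile exactly.
    """
    stages = list(profile)
    if not stages:
        raise ValueError("profile must cover at least one stage")
    rng = np.random.default_rng(seed)
    genes = [target_gene, *rg_genes]
    samples = [
        Sample(f"{st}.b{b + 1}", st, b + 1, 1) for st in stages for b in range(n_bio)
    ]
    ct = np.empty((len(genes), len(samples)))
    for j, s in enumerate(samples):
        ct[0, j] = target_baseline - float(profile[s.stage]) + rng.normal(0.0, noise_sd)
        for i in range(1, len(genes)):
            ct[i, j] = rg_baseline + rng.normal(0.0, noise_sd)
    truth = SyntheticTruth(
        stable_genes=list(rg_genes),
        seed=seed,
        replicate_noise_sd=noise_sd,
        stage_effect={target_gene: np.array([-profile[s] for s in stages])},
        extra={"log2_profile": dict(profile), "stages": stages},
    )
    return CtMatrix(genes, samples, ct), truth


def generate_dilution_series(
    true_efficiency: float = 1.0,
    n_points: int = 5,
    fold_step: float = 10.0,
    intercept: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Serial-dilution standard curve with a chosen true efficiency.

    Dilution i holds 1/fold_step^i of the template, so
    dilution_log10 = -i * log10(fold_step) and
    Ct = intercept - dilution_log10 / log10(1 + E) + noise.
    """
    if true_efficiency <= 0:
        raise ValueError("true_efficiency must be > 0")
    if n_points < 3:
        raise ValueError("need >= 3 dilution points")
    rng = np.random.default_rng(seed)
    dilution_log10 = -np.log10(fold_step) * np.arange(n_points)
    ct = (
        intercept
        - dilution_log10 / np.log10(1.0 + true_efficiency)
        + rng.normal(0.0, noise_sd, n_points)
    )
    return dilution_log10, ct


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def generate_bundle(
    seed: int = 0,
    n_expression_genes: int = 500,
    n_ct_genes: int = 20,
    frac_stable: float = 0.5,
    bio_noise_sd: float = 0.05,
    profile: Mapping[str, float] | None = None,
    trait: Sequence[float] = (1.2, 9.6, 11.8, 7.5),
) -> dict:
    """One consistent synthetic study: expression + Ct + target + dilutions.

    The defaults make a clean end-to-end fixture: half the Ct genes are
    stable with small replicate noise, so the top-2 normalization factor
    is tight (V(2, 3) far below 0.15) and the planted stable set should
    dominate every ranking.  ``profile`` defaults to a sharp
    mature-green peak (log2 folds 0/5/4/2 over IM, MG, B, MR), and the
    trait series rises to a breaker-stage maximum like a
    capsaicin-accumulation curve.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    expr, expr_truth = generate_expression_matrix(
        n_genes=n_expression_genes, seed=seeds[0]
    )
    ct, ct_truth = generate_ct_matrix(
        n_genes=n_ct_genes,
        frac_stable=frac_stable,
        # keep baselines inside the mean-Ct quality window so the bundle
        # exercises ranking rather than the abundance guideline
        baseline_range=(20.0, 27.0),
        bio_noise_sd=bio_noise_sd,
        tech_noise_sd=bio_noise_sd,
        seed=seeds[1],
    )
    profile = dict(profile) if profile else {"IM": 0.0, "MG": 5.0, "B": 4.0, "MR": 2.0}
    target, target_truth = generate_target_profile(
        profile, noise_sd=bio_noise_sd, seed=seeds[2]
    )
    # a target-gene row on the main Ct grid, so the pipeline can quantify it
    # against reference genes chosen from the same matrix
    rng_t = np.random.default_rng(seeds[3])
    target_row = np.array(
        [26.0 - profile[s.stage] + rng_t.normal(0.0, bio_noise_sd) for s in ct.samples]
    )
    ct_with_target = CtMatrix(
        [*ct.gene_ids, "TARGET"], list(ct.samples), np.vstack([ct.ct, target_row])
    )
    dilution = generate_dilution_series(true_efficiency=1.0, noise_sd=0.05, seed=seeds[4])
    return {
        "expression": expr,
        "expression_truth": expr_truth,
        "ct": ct,
        "ct_truth": ct_truth,
        "ct_with_target": ct_with_target,
        "target_gene": "TARGET",
        "profile": profile,
        "target": target,
        "target_truth": target_truth,
        "dilution": dilution,
        "trait": np.asarray(trait, dtype=float),
        "seed": seed,
    }
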