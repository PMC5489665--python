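# Methods

## The problem

qPCR expresses a target gene's abundance relative to internal reference
genes (RGs). A gene qualifies as an RG only if its expression is stable
across the conditions being compared — here, samples from a
developmental series (four fruit-ripening stages with biological and
technical replicates). `rgselect` implements the full
discovery-and-validation chain: a transcriptome-wide screen proposes
candidates, three independent stability statistics rank them on qPCR Ct
data, a consensus-plus-QC step picks the qualified set, the geNorm
V-curve fixes how many RGs a normalization factor needs, and a ΔΔCt
stage validates the choice against a target gene and an external trait.

## Screening

Candidates are genes whose RPKM-like expression lies inside a
medium-abundance window at **every** condition column and whose
coefficient of variation across columns is at most a threshold.

* Window: [200, 2000], bounds inclusive. Very low expression makes Ct
  values noisy and late; very high expression is often condition-driven.
* CV = sd/mean with the sample (n−1) standard deviation; threshold 0.35,
  compared inclusively (cv ≤ cv_max). CV is scale-free, so screening on
  raw values and on mean-normalized relative expression is identical —
  a property the tests enforce.
* Genes with zero mean get CV = ∞ and simply fail, rather than raising:
  all-zero rows are routine in genome-scale tables.
* When a table mixes accessions or tissues, select the relevant columns
  first (`ExpressionMatrix.select_columns`); the screen treats every
  column it is given as a condition that must pass.

## Quantity transform

Stability statistics operate on relative quantities
q = A^(Ct_min − Ct), anchored per gene so the most abundant sample has
q = 1. The amplification factor A defaults to 2 (the
efficiency-agnostic convention); per-gene A = 1 + E from standard curves
is supported but not the default — measured efficiencies vary widely
across primer pairs (fractions of 0.7 to 1.7 are realistic), and feeding
those into the transform distorts ranks with primer properties rather
than expression behaviour. Technical replicates are averaged into one
value per (stage, biological replicate) before scoring, matching
standard practice; a flag exposes raw-replicate scoring. Missing Ct is
an error for geNorm/NormFinder (both assume complete matrices); the
whisker statistic ignores missing entries.

## geNorm

The pairwise variation between genes j and k is the sample sd over
samples of log₂(qⱼ/qₖ); a gene's M-value is its mean pairwise variation
with all other candidates. Ranking proceeds by stepwise exclusion of the
gene with the highest M, recomputing after each removal, down to a final
pair that shares its mutual variation as M. Ties on the worst M are
broken by excluding the lexicographically greater gene id (pure
determinism; any tie-break is equally defensible). Log base 2 and
(n−1) standard deviations throughout.

The pairwise-variation curve uses normalization factors
NFₙ(s) = geometric mean of the top-n genes' quantities at sample s:
V(n, n+1) = sd over samples of log₂(NFₙ/NFₙ₊₁), for n = 2..N−1. The
minimal RG count is the smallest n with V below 0.15; when no entry
crosses, the largest evaluated n is returned with an explicit warning
flag rather than a silent answer.

Implementation note: the pairwise-variation matrix is computed as the
sd of differences of log₂ quantities (one vectorized pass per gene) and
reused across all exclusion steps, so 200-gene panels rank in
milliseconds; a brute-force double-loop recomputation agrees to 1e−12.

## NormFinder

On log-scale expression y = −Ct (log₂ quantity up to per-gene constants
when A = 2), with samples partitioned into groups (default: the stage
label):

1. center each sample across genes (removes sample-specific loading);
2. per gene and group, compute the group mean of the centered values
   and the within-group sample variance;
3. correct the variances for the covariance induced by centering across
   k genes — E[s²ᵢₘ] = σ²ᵢₘ(1 − 2/k) + Tₘ/k², inverted via
   σ̂²ᵢₘ = (s²ᵢₘ − Ŝₘ/(k(k−1)))·k/(k−2) — and floor at 0;
4. row-center the group means so each gene's deviations dᵢₘ are
   relative to its own level, and moment-estimate the inter-group
   variance γ² = max(0, Σd²/((k−1)(G−1)) − mean(σ̂²ᵢₘ/nₘ));
5. shrink each dᵢₘ by γ²/(γ² + σ̂²ᵢₘ/nₘ) and report
   stability = meanₘ(|d̃ᵢₘ| + √(σ̂²ᵢₘ/nₘ)).

With a single group the statistic reduces to the corrected intra-group
standard deviation. The centering correction needs k ≥ 3 genes; every
group needs ≥ 2 samples. Global per-sample shifts are removed exactly by
step 1, a property the invariance tests assert at 1e−12.

## Whisker D-value

The boxplot whisker span — simply max − min of a gene's Ct values. It
is translation-invariant, monotone under new observations, and free of
modelling assumptions, which makes it a useful third vote even though it
ignores replicate structure. The five-number boxplot summary uses linear
interpolation between order statistics (the spreadsheet-inclusive
convention, configurable); only min/max enter the D-value, so the
quartile convention never affects selection.

## Consensus and QC

Each method contributes its top-k list (k = 12 by default, mirroring a
35-candidate panel); genes present in at least `min_methods` (default 2)
lists are consensus candidates. QC then removes genes whose mean Ct
exceeds 28 cycles (weakly expressed templates amplify noise; the common
guideline window is 15–30 and the default sits deliberately below its
ceiling) or whose standard-curve efficiency falls outside [0.9, 1.1].
Genes without a known efficiency pass that check — efficiency is
primer-pair metadata that may not exist for every candidate. The QC
rule is applied uniformly to every gene with data; published selections
assembled by hand are sometimes more lenient, which is exactly the kind
of inconsistency a mechanical rule surfaces.

## Quantification

Standard curves are ordinary least squares of Ct on log₁₀ relative
template amount over a serial dilution (≥ 3 distinct points);
E = 10^(−1/slope) − 1 and R² is the squared correlation. The
normalization factor is the per-sample geometric mean of the chosen RGs'
quantities; the RG list has set semantics (duplicates are ignored).
Fold changes come from u(s) = A^(−Ct_target(s))/NF(s) referenced to the
geometric mean of u over calibrator samples — computed on the log scale
to avoid underflow at realistic Ct values. With A = 2 and a single RG
this reproduces the textbook 2^−ΔΔCt formula exactly (a tested
identity). Stage summaries are arithmetic means and sds of replicate
fold changes, matching common reporting; because the calibrator is
aggregated geometrically, the calibrator stage's *arithmetic* mean fold
equals 1 exactly only when its replicates agree, and exceeds 1 slightly
under noise (AM ≥ GM). Trait validation is the Pearson correlation
between per-stage mean fold changes and an external trait series
(n ≥ 3, both series non-constant).

## Synthetic data

The generators emulate the study design the pipeline targets and give
every test a planted ground truth.

* **Ct panels** (default 35 genes): four stages (IM, MG, B, MR) × 3
  biological × 3 technical replicates; baselines uniform over 19–29
  cycles (the range observed for real candidate panels); Gaussian noise
  on the Ct scale — the standard qPCR error model — split into a
  biological component (sd 0.15 cycles) shared by a well's technical
  replicates and an independent technical component (sd 0.10 cycles).
* **Drift**: unstable genes carry a stage-effect profile with
  peak-to-peak amplitude drawn from 1.5–3 cycles. The base shape is a
  monotone ramp (random way-points) or a single-stage bump with random
  sign, plus gene-specific per-stage wiggle (sd = half the amplitude,
  then rescaled to the exact amplitude and re-anchored at zero).
  The wiggle is essential, not cosmetic: a family of clean ramps of
  similar amplitude is mutually near-proportional, i.e. planted
  co-regulation, and a coalition of such genes out-coheres a small
  stable set under any ratio-based criterion. With gene-specific drift
  directions, all three methods recover ≥ 10 of 20 planted stable genes
  in their top-12 in 100/100 simulated 200-gene panels.
* **Expression matrices** (default 2000 genes × 7 stages): log-normal
  noise around each baseline with sigma = √ln(1 + CV²) so stable genes
  hit a target CV (default 0.2); unstable genes add a log₂ drift profile
  of amplitude 1.5–3, pushing CV far past 0.35; baselines fall inside
  the abundance window for half the genes and below/above it otherwise.
* **Dilution series**: Ct = intercept − d/log₁₀(1 + E) + noise for a
  chosen true efficiency; **target profiles** encode a chosen log₂
  fold-change trajectory against flat reference genes, so zero-noise
  data invert exactly through the quantification stage.
* Every generator is a pure function of (parameters, seed).

What the generators do **not** emulate — and hence what passing tests do
not show about real data: co-regulated gene modules (real developmental
programs move many genes along shared axes, and ratio-based rankings
like geNorm's are known to favour such modules over truly stable genes),
amplification failures and missing wells, plate/batch effects,
heavy-tailed or Ct-dependent noise, and any particular organism's
expression distribution beyond the stated moments. The multi-method
consensus with QC exists precisely because no single statistic is robust
to all of these.

## Problem sizes and numerical choices

The default test and acceptance runs use 200-gene × 12-sample panels for
recovery (100 seeds), 2000-gene screens, 20-gene bundles for end-to-end
checks, and 5-point dilution series — sizes chosen so the full suite
completes in seconds while keeping every statistic in its intended
regime. Oracle comparisons assert 1e−12 (geNorm, same arithmetic
reordered) and 1e−10 (NormFinder, loop-coded moments oracle).
Variance estimates are floored at zero before square roots; shrinkage
factors with zero denominators are defined as zero; ranks break ties by
gene id so every ranking is a deterministic permutation.

## Known limitations

* geNorm's M rewards agreement with the candidate majority; in panels
  dominated by a co-regulated drifting module it will rank that module
  highly. The synthetic generator deliberately avoids this regime; real
  analyses should lean on the consensus, not any single method.
* NormFinder's decomposition assumes roughly balanced groups with ≥ 2
  (ideally ≥ 3) samples each and ≥ 3 genes; with k = 3 the variance
  correction factor k/(k−2) is large and estimates are crude.
* The whisker D-value is an extreme-value statistic: one outlier well
  dominates it. It is kept because it needs no assumptions and the
  consensus dilutes its fragility.
* Efficiency QC treats unknown efficiencies as passing; supply a full
  efficiency table when primer data exist.
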