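# Methods

## Setting and models

The package targets factorial testcross programmes: `n_p` inbred
pollinator lines, organised in breeding pools, each crossed to `n_t`
male-sterile testers, giving `n_p × n_t` hybrids. Hybrid predictor
profiles are never measured; they are extrapolated from parental omics
layers by the mid-parent rule (below), and hybrid phenotypes come from
multi-environment field trials.

**Trial model and heritability.** Plot values follow

    Y = G + T + L + T×L + L×G + e

with genotype G fixed (for BLUEs) or random (for variance components),
and trial T, location L and the interactions random with identity
covariance on their grouping factors. Broad-sense heritability uses the
replicate-corrected form

    H² = σ²_G / (σ²_G + σ²_e / n₀)

with `n₀` the number of plant replicates per genotype (default 4).

**Multi-kernel mixed model.** With hybrid BLUEs (or means) `y`,

    y = 1μ + Σₖ gₖ + e,   gₖ ~ N(0, Kₖ σ²ₖ),   e ~ N(0, I σ²_e),

where the kernels `Kₖ` are chosen per predictor set: additive (VanRaden)
relationships per omics layer for gBLUP; plus dominance (Su) and
epistatic (Hadamard square of the additive matrix, rescaled to unit mean
diagonal) kernels from the SNP layer; or Gaussian kernels
`K = exp(−h·d̃²)` for RKHS regression, where `d̃²` are squared Euclidean
distances between hybrid profiles divided by their off-diagonal mean.
That scaling makes a single bandwidth grid
{0.01, 0.05, 0.1, 0.25, 0.5, 1, 2, 5} usable for layers of any
dimensionality; `h` is chosen by maximizing the single-kernel restricted
likelihood over the grid, ties (within 1e-6 log-likelihood units)
breaking toward the smallest `h`, i.e. the smoothest kernel.

**In silico hybrids.** Every hybrid feature value is the arithmetic mean
of its two parents' values, in every layer. For homozygous 0/2-coded
parents this gives dosages 0/1/2 with heterozygosity exactly at parental
disagreements; for transcripts and metabolites it is the standard
additive extrapolation. Heterosis is reported as
MPH = 100·(F1 − MP)/MP with MP the parent mean, and
BPH = 100·(F1 − BP)/BP with BP the better parent (maximum by default; a
direction flag selects the minimum for lower-is-better traits).

## REML

`fit_reml` maximizes the restricted log-likelihood

    lR = −½ [ (n−p)·log 2π + log|V| + log|X′V⁻¹X| + y′Py ],
    V = Σₖ σ²ₖ Kₖ + σ²_e I,

by average-information (AI) updates with step halving; whenever an AI
proposal leaves the parameter space or fails to improve lR, an EM-REML
step (Harville form) is taken instead, so accepted steps are monotone in
lR. Components are pinned to a floor of 1e-8·var(y) rather than exactly
zero, keeping V invertible; a component sitting at the floor with a
negative score is excluded from the AI update (active-set rule).
Convergence requires two consecutive iterations with
|Δ lR| < 1e-6 — the extra Newton step squares the parameter error once
the likelihood has flattened, which matters when fits are compared
against an independent oracle at 1e-4. If neither the halved AI step nor
EM can improve lR by more than the tolerance, the current point is
accepted as a (possibly boundary) optimum at the numerical precision
limit; this occurs for noiseless responses whose covariance is exactly
low-rank. Trace identities (tr(PK) = Σ P∘K) keep each iteration at a
single O(n³) factorization regardless of the number of kernels.

Predictions for masked hybrids use the train-only fit and the
cross-kernel formula

    ŷ_val = μ + Σₖ σ²ₖ Kₖ[val,train] V⁻¹ (y_train − μ),

which for BLUP is equivalent to missing-value augmentation and is easier
to verify (it reproduces ridge-regression marker predictions exactly
when the kernel is WW′/c from the same markers).

The trial model has only grouping-factor random terms, so its restricted
likelihood is evaluated through the low-rank identity
`(I + ZDZ′)⁻¹ = I − Z(D⁻¹ + Z′Z)⁻¹Z′` on the total number of factor
levels, with the residual variance profiled out and the log variance
ratios optimized by L-BFGS-B; this keeps a fit with thousands of plots
and ~300 genotypes under a second. Random terms whose factor has fewer
than two levels are dropped automatically.

## Preprocessing

- **TPM**: per individual, `rate_f = count_f / length_f`, rescaled so each
  row sums to 1e6. Expression filter keeps features with across-sample
  median TPM ≥ 5 (inclusive).
- **Blank filter**: keeps metabolites whose mean sample intensity is
  strictly greater than `ratio` (default 2) times the mean blank
  intensity; the mean is used as the central statistic. Zero-blank
  features with nonzero signal are kept.
- **Weight/day normalization**: intensities are divided by sample weight,
  then each measuring-day batch is median-centred per feature onto the
  grand median.
- **Outliers**: one pass; values outside median ± 4·SD become missing,
  with the classical (ddof = 1) SD computed before removal.
- **Box–Cox**: per-feature λ chosen by maximum likelihood over the grid
  −2(0.05)2; non-positive inputs are shifted with a logged offset.
- **Predictor scaling**: per-column min–max to [0, 2] for genotypes and
  [0, 1] for transcripts/metabolites — the ranges the kernels consume.
  (Centring would produce negatives, so a literal "centre and
  standardise to 0..2" is not implementable; min–max to the stated range
  is this package's resolution.) Constant columns map to the interval
  midpoint and are flagged.

## Synthetic data generator

The generator is first-class, tested code; its defaults define the study
conditions at desk scale: 300 pollinators in 3 pools, 2 testers
(600 hybrids), 2,000 SNPs, 1,000 transcripts, 150 metabolites, 2 trials ×
3 locations × 4 plant replicates. The full-scale layout (475 pollinators,
13k SNPs, 19k transcripts, 154 metabolites, 950 hybrids) is reachable by
configuration.

- **Pools**: Balding–Nichols — pool frequency ~ Beta around a shared
  ancestral frequency with differentiation `fst` (default 0.15), so
  E[(pᵢ−pⱼ)²] = 2·fst·p₀(1−p₀]; testers form their own pool. Parents are
  fully homozygous; panel-monomorphic SNPs are repaired by flipping one
  random individual.
- **Layer coupling**: transcript = baseline + cis-SNP effect + pool
  effect + noise on a nonnegative TPM-like scale; metabolite = sparse
  combination of three transcripts + noise. T therefore carries G
  information plus independent regulatory variance, and M is downstream
  of T. The true covariance between omics layers in a real breeding
  population is unknown; the coupling strengths are exposed parameters
  (`cis_effect_sd`, `pool_effect_sd`, noise SDs), not estimates of real
  tissue covariances.
- **Traits**: explicit per-SNP additive and dominance effects (200 causal
  SNPs each) and 100 additive×additive pairs on centred dosages. Each
  component is centred and rescaled so its realized variance fraction
  equals the configured target exactly (total genetic SD 1); the
  plant-level residual SD is then calibrated as
  σ²_e = σ²_G·n₀·(1−h²)/h², so the realized replicate-corrected H²
  equals the target by construction — an empirical calibration that is
  robust to any architecture choice. Trial/location/interaction effects
  default to SDs 0.3/0.5/0.2/0.1 in genetic-SD units, and a baseline of
  30 trait units keeps heterosis percentages well defined.
- **Determinism**: all randomness flows from one seed through named
  child streams (parents / endophenotypes / trait), so runs are
  bit-reproducible.

What the generator does *not* emulate: linkage maps and realistic LD
decay, selection and drift history, genotyping error, non-additive
inheritance of expression, and measured between-layer covariances of any
real crop population. Tests passing on this generator therefore
establish the correctness and internal consistency of the methods, not
field-level accuracy values.

## Cross-validation design

Each cycle masks ⌈0.25·n_p⌉ pollinators; *all* hybrids of a masked
pollinator form the validation set, so no pollinator contributes to both
sides (for 475 × 2 that is 119 pollinators → 238 validation hybrids).
All predictor sets see the same splits within a cycle, making the
ANOVA/Tukey comparisons within-cycle contrasts and reducing Monte-Carlo
noise. Hybrids with missing phenotypes stay in the kernels but are
excluded from fitting and from the accuracy computation; cycles whose fit
fails are recorded and skipped. The Gaussian bandwidth is estimated once
per trait on the full data, not per cycle (refitting inside each cycle
is supported by calling `estimate_bandwidth` on the training block, at
~8× the cost).

## Numerical choices and verification scale

- Kernels are symmetrized and, if an eigenvalue falls below −1e-8,
  repaired with logged diagonal jitter.
- REML fits are verified against an independent spectral
  (error-contrast eigendecomposition) profiled-likelihood oracle; the
  variance ratio is compared on the bounded scale σ²_g/(σ²_g+σ²_e),
  because the raw ratio diverges when the residual sits at its floor.
- Simulation studies run at 150 pollinators × 2 testers (300 hybrids)
  with 800 SNPs, 50–200 CV cycles and 20 seeds — sizes at which every
  check completes in seconds to a couple of minutes while leaving the
  Monte-Carlo error well inside the asserted tolerances. The heritability
  recovery study omits the location×genotype term from the estimation
  model; its simulated variance (0.01 in genetic-SD units) is two orders
  of magnitude below the plant-level residual and does not move H² at the
  ±0.1 scale checked.

## Known limitations

- The trial model supports crossed trial/location grouping factors with
  identity covariances only — no spatial field models, no heterogeneous
  GxE covariances.
- RKHS uses a single Gaussian kernel per layer (no kernel averaging over
  bandwidth grids).
- The pipeline treats one trait at a time; multi-trait models are out of
  scope.
- `compare_predictor_sets` drops cycles with any missing accuracy before
  the ANOVA (listwise), reporting the retained cycle count.
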