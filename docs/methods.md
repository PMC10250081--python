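# Methods

## Model

The method operates on a composite network over an ordered feature set of
`n_g` genes followed by `n_m` metabolites. The general network S0 is the
2×2 block matrix `[[Sg0, Sgm0], [Sgm0ᵀ, Sm0]]` with nonnegative undirected
weights; on the raw confidence scale (STRING/STITCH scoring) weights lie in
[0, 999] and the within-omics blocks are symmetric with zero diagonals
(interaction networks carry no self-edges). The disease similarity matrix E
has the same block structure, built from absolute Pearson correlations of
feature columns in a samples × features omics table; cases and controls are
pooled, since E is meant to capture the co-variation structure of the
diseased cohort as a whole (a Spearman switch exists but Pearson is the
default everywhere). E's diagonal is forced to zero so the walk cannot
self-loop.

Two scalars rebalance the blocks: the g–g blocks of S0 and E are multiplied
by λg and the m–m blocks by λm, leaving the g–m blocks fixed. Defaults
λg = 0.05 and λm = 20 correspond to a network with roughly two orders of
magnitude more genes than metabolites; a rule of thumb supported by the
benchmark is that stronger imbalance calls for smaller λg and larger λm.
Setting λg = λm = 1 is exactly the unweighted multi-omics extension of
DiSNEP and is exposed as the `disnep` variant; the `multinep-s0` variant
reweights only S0 (`reweight_similarity=False`); `general` skips
enhancement entirely and diffuses on the denoised, column-normalized S0.

### Enhancement

With Ẽ the column-normalized reweighted similarity matrix, the enhancement
recursion is

    S_{t+1} = α Ẽ S_t + (1 − α) S0̃,    S_0 = S0̃,   α = 0.75,

stopped when the entrywise L1 norm of the update drops below `tol = 1e-6`.
S0̃ enters the recursion raw (not normalized): only Ẽ needs to be
stochastic for convergence. Because column sums of Ẽ are ≤ 1 and α < 1,
the update is a contraction with factor α in the entrywise L1 norm, so the
residual after t steps is bounded by α^{t−1}·‖S_1 − S_0‖₁ and convergence
within the iteration cap is certifiable; hitting the cap raises an error
carrying the last residual rather than returning silently. The fixed point
has the closed form S* = (1 − α)(I − α Ẽ)⁻¹ S0̃, implemented independently
(`rwr_solve`, a dense linear solve) and used as the test oracle and as an
optional fast path for small problems; the iterative solver is the default.

The converged matrix is symmetrized ((S + Sᵀ)/2), its block diagonals
zeroed, denoised per block, and column-normalized. Denoising keeps the top
`ceil(keep × E_b)` of each block's `E_b` *nonzero* edges by weight
(defaults 5% g–g, 30% m–m, 15% g–m). The fraction is taken over nonzero
edges, not all pairs — most pairs have weight zero, so ranking all pairs
would make the percentages meaningless. For the symmetric blocks an edge is
an unordered pair (cut on the upper triangle, mirrored). Ties at the cut
break deterministically by (weight descending, row index, column index).
A block with no nonzero edges passes through with a logged notice.

The final column normalization breaks block symmetry, so the enhanced
network SE is represented as a full transition matrix (`EnhancedNetwork`)
rather than as symmetric blocks. Columns of isolated features are left
all-zero (sub-stochastic) instead of being replaced by uniform columns:
fabricating transitions out of disconnected features would invent
interactions, and the diffusion below remains a contraction regardless.

### Prioritization

Two-sided p-values come from Welch two-sample t-tests (case/control
designs) or paired t-tests (matched designs); features with zero
within-group variance get p = 1 with a warning. Scores are
v0 = Φ⁻¹(1 − p/2), computed as −Φ⁻¹(p/2) which is exact by symmetry and
stable for p near zero; p = 0 is clamped to 1e-300 (score ≈ 37) with a
warning since such features dominate the initial scores. The diffusion

    v_{t+1} = β SE v_t + (1 − β) v0,    β = 0.75,

uses the same stopping rule, contraction argument and direct-solve oracle
as the enhancement step. Features are ranked descending by the converged v
on one combined gene+metabolite list (per-type ranks are also emitted);
ties break deterministically by (score, genes before metabolites,
identifier). Features present in the network but missing from a supplied
p-value table receive p = 1.

## Evaluation metrics

Top-k recovery counts true signal genes and metabolites among the k
best-ranked combined features (defaults k ∈ {100, 200, 500}).

The interaction ratio score (IRS) of a feature in one block is its total
edge weight there divided by the mean total over all features on that side
of the block, so mean IRS is exactly 1 per block and the score is invariant
to rescaling a block. Totals are row sums ("inflow"): identical to column
sums on the symmetric general networks, and still meaningful on enhanced
networks where column normalization distorts the column sub-sums. The
denominator averages over *all* features of the side, including isolated
ones. An all-zero block yields NaN for every feature, with a warning —
there is no average connectivity to compare against.

`irs_comparison` partitions the true signals each method recovers in its
top k into an intersection cell and per-method unique cells, and reports
each cell's mean IRS in each supplied network's blocks; empty cells carry
NaN (an absence, not a zero score).

## Synthetic data generator

The generator reproduces the statistical structure of a case/control
multi-omics study at configurable scale; the reference configuration is
5000 genes (175 signal), 60 metabolites (12 signal), 100 cases and 100
controls.

**Omics profiles** are multivariate normal with Σij = ρij·σi·σj. Controls
sit at baseline means everywhere (genes 6.0 on a log2-like expression
scale, metabolites 0.0); cases elevate only the signal means (genes 6.15,
metabolites 0.15). SDs are 2.0 (genes) and 2.5 (metabolites), so the
per-feature effect sizes (0.075 and 0.06 SD) are essentially undetectable
by individual t-tests at n = 100+100 — recovery must come from the
correlation structure and the network. Correlations are block-constant:
ρ = 0.25 / 0.20 / 0.225 for signal–signal / noise–noise / signal–noise
gene pairs, 0.30 / 0.15 / 0.225 for metabolite pairs, and a configurable
quadruple for gene–metabolite pairs (signal–signal, signal-gene–noise-met,
noise-gene–signal-met, noise–noise), e.g. (0.2, 0.105, 0.105, 0.01).

A block-constant correlation matrix at arbitrary block sizes is not
automatically positive semidefinite. The matrix is repaired by clipping
eigenvalues at 1e-8, rebuilding and rescaling to unit diagonal; if the
repair moves any entry by more than 0.05 the configuration is rejected as
infeasible. The strongest gene–metabolite quadruple of interest,
(0.5, 0.225, 0.225, 0.01), *is* infeasible under this rule — at the
reference scale the repair would move entries by 0.149, and by 0.102 at
desk scale — so the benchmark's high-correlation scenario uses the highest
feasible quadruple (0.35, 0.18, 0.18, 0.01) instead. Sampling draws
standard normals in a fixed order (samples row-major, features canonical,
cases first) and applies an eigen factor of the repaired correlation
matrix, so a seed fully determines the cohort.

**Networks** draw Bernoulli edges per block with heavy-tailed integer
confidence weights in [1, 999] (999·U⁴, many weak edges, few strong).
Default densities are those implied by a real STRING+STITCH composite
network over a prostate-cancer cohort's features: 3.3% (g–g), 23% (m–m),
2.3% (g–m). A single enrichment knob (default 3) multiplies the edge
probability for signal–signal pairs in all three blocks, mirroring the
above-average connectivity of curated disease genes; at 1 the signal
labels are exchangeable and signal IRS has expectation 1. When real edge
lists are available, `subsample_network` takes induced sub-networks
instead.

**The study runner** derives per-replicate generators from the master seed
via the counter scheme `SeedSequence([master_seed, replicate])`, so
replicates are independent and individually re-runnable. Each replicate
draws a fresh truth, network and cohort, computes Welch p-values and the
pooled similarity matrix once, and runs all methods on the same inputs.

### What the generator does and does not capture

It reproduces the imbalance, sparsity regime, weak-effect/correlated-signal
structure and signal-connectivity enrichment of real cohorts. It does not
reproduce scale-free degree distributions, hub genes, pathway-level modular
structure, non-Gaussian abundance distributions, missingness, or batch
effects. Passing benchmarks here show the pipeline exploits connectivity
and correlation structure as designed — not that the specific λ defaults
are optimal for any particular real cohort.

### Desk-scale behavior of the benchmark

The bundled acceptance checks run the benchmark at 500 genes (20 signal) /
30 metabolites (6 signal) with 20 replicates — small enough for seconds-
scale runs. One caveat of this scale: the balance between the λg-scaled
g–g mass and the g–m mass of a gene's column depends on the gene:metabolite
ratio (17:1 here vs ~85:1 at the reference scale), so λm = 20 over-corrects
and places essentially all 30 metabolites in the top-100 window. Combined
and gene-level comparisons between methods are unaffected, but metabolite
recovery for the reweighted method sits at its ceiling (6/6), so effects
that should *reduce* its metabolite recovery (e.g. gene–metabolite
correlations exceeding metabolite–metabolite ones) are not visible at this
scale.

The null-calibration check uses equal signal fractions in both feature
types (10% of genes and 10% of metabolites). This matters: metabolites are
systematically better connected than genes (denser m–m block), so the
top-k window is metabolite-rich even under the null, and the pooled
hypergeometric expectation k·K/N is only valid when the signal fraction is
the same in both types.

## Numerical choices

- All matrices are dense numpy arrays; the supported scales (up to a few
  thousand features) need no sparse path, and BLAS-backed dense products
  keep the solvers fast and bit-reproducible.
- Residual norms are entrywise L1 (sum of absolute differences) for both
  the matrix and vector recursions, used consistently.
- `column_normalize` leaves all-zero columns at zero; nonzero column sums
  are 1 within 1e-12.
- Correlation matrices clip |r| into [0, 1] against rounding excursions;
  exactly constant columns (detected by zero range, robust to demeaning
  rounding) get zero similarity and a warning.
- Ranking, denoising and the study runner are fully deterministic given
  seeds; all tie-breaks are documented lexicographic rules.

## Known limitations

- Identifier mapping across databases is out of scope; inputs must be
  pre-mapped, and `harmonize` reports intersection statistics to diagnose
  mapping problems.
- Only two omics layers are supported; the block composition generalizes
  but no multi-layer interface is exposed.
- The enhanced network is diffusion-ready but no longer symmetric;
  consumers needing an undirected network should use the pre-normalization
  blocks.
- Multiple-testing correction is deliberately absent: the method consumes
  raw p-values, and any FDR step belongs upstream.
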