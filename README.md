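# multinep

Simultaneous prioritization of disease-associated **genes and metabolites**
on an imbalanced multi-omics network.

## The problem

Network propagation is a standard way to re-rank candidate disease features:
features with weak individual association signals but strong interactions
with high-scoring features get promoted. A *multi-omics* network couples a
gene–gene (g–g) interaction network, a metabolite–metabolite (m–m) network
and a gene–metabolite (g–m) network into one graph, so that g–m cross-talk
can help prioritize both feature types at once. The catch is imbalance: a
cohort typically carries ~18 000 genes but only ~200 annotated metabolites,
so g–g edges drown out g–m edges when ranking genes, and g–m edges drown out
m–m edges when ranking metabolites.

This package implements the MultiNEP approach: rebalance the sub-networks
with two weights before propagation,

```
S0~ = [ λg·Sg0   Sgm0  ]          E~ = [ λg·Eg   Egm ]
      [ Sgm0ᵀ   λm·Sm0 ]              [ Egmᵀ   λm·Em ]
```

with λg < 1 shrinking the g–g block and λm > 1 amplifying the m–m block
relative to the untouched g–m block (defaults λg = 0.05, λm = 20). The
pipeline then has three steps:

1. **Reweight** the general network S0 (STRING/STITCH-style confidence
   scores in [0, 999]) and the disease similarity matrix E (absolute
   pairwise correlations of the cohort's omics profiles).
2. **Enhance** — random walk with restart
   `S_{t+1} = α·E~·S_t + (1−α)·S0~` (α = 0.75, entrywise-L1 stopping rule at
   1e-6) driven by the column-normalized E~, followed by symmetrization,
   per-block denoising (keep the top 5% of g–g, 30% of m–m, 15% of g–m
   edges) and column normalization, giving a disease-specific transition
   network SE.
3. **Prioritize** — map per-feature two-sided p-values (e.g. case/control
   t-tests) to scores `v0 = Φ⁻¹(1 − p/2)`, diffuse them with
   `v_{t+1} = β·SE·v_t + (1−β)·v0` (β = 0.75), and rank all features by the
   converged scores on one combined list.

Setting λg = λm = 1 recovers the unweighted enhancement baseline (DiSNEP
extended to a multi-omics network); skipping enhancement entirely gives the
General Network baseline; reweighting only S0 gives the MultiNEP-S0 variant.
All four are built in (`variant=` in `prioritize`).

The package also ships the full synthetic benchmark: a generator for
imbalanced multi-omics networks with signal-enriched connectivity, a
multivariate-normal cohort simulator with block-constant correlations, a
replicated study runner, and the evaluation metrics (top-k true-signal
recovery and the interaction ratio score, IRS — a feature's total edge
weight in a block divided by the block's per-feature average).

## Worked example

Run a small replicated benchmark (5 replicates, 500 genes of which 20 are
true signals, 30 metabolites of which 6 are true signals) comparing the
reweighted method against both baselines:

```python
from multinep import SimulationConfig, run_study, summarize_study

cfg = SimulationConfig(n_genes=500, n_signal_genes=20,
                       n_metabolites=30, n_signal_metabolites=6,
                       rho_gm=(0.2, 0.105, 0.105, 0.01))
table = run_study(cfg, weight_grid=[(0.05, 20.0)], n_reps=5, seed=7, ks=[100])
print(summarize_study(table))
```

```
  method  lambda_g  lambda_m   k  true_signal_genes_mean  true_signal_metabolites_mean  combined_mean  combined_se
  disnep      1.00       1.0 100                     4.8                           4.0            8.8     0.860233
 general       NaN       NaN 100                     3.4                           4.6            8.0     1.183216
multinep      0.05      20.0 100                     4.6                           6.0           10.6     0.979796
```

Each row is the mean over replicates of how many true signal features land
in the top 100 of the combined ranking. With individual effect sizes this
small (0.075 SD for genes, 0.06 SD for metabolites at n = 100+100, so
t-tests alone are nearly powerless), recovery is driven by the correlation
structure and network connectivity of the signals — and the reweighted run
(`multinep`) recovers more true signals (10.6) than unweighted enhancement
(`disnep`, 8.8) or no enhancement (`general`, 8.0), chiefly by rescuing
metabolites.

The same pipeline is scriptable from the shell:

```bash
multinep simulate --seed 3 --n-genes 500 --n-metabolites 30 --out-prefix sim
multinep prioritize --network sim.network.tsv --omics sim.omics.tsv \
    --label-col group --lambda-g 0.05 --lambda-m 20 --out ranked.tsv
multinep evaluate --results ranked.tsv --truth sim.truth.tsv --out report.tsv
```

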