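"""Synthetic multi-omics networks and disease omics profiles.

The generator reproduces the statistical structure of a case/control
multi-omics study on an imbalanced network: many genes, few metabolites, a
small set of "signal" features whose case means are slightly elevated and
whose mutual correlations are stronger than the background.  Individually
the mean shifts are far too small for a t-test to detect at n = 100 per
arm (effect sizes below 0.1 SD); recovering the signals therefore depends
on the correlation structure and on their above-average connectivity in
the network -- exactly the regime network propagation is meant for.

Omics profiles are multivariate normal with a block-constant correlation
matrix: one correlation for signal-signal gene pairs, one for noise-noise,
one for signal-noise, the analogous three for metabolites, and a quadruple
for the four kinds of gene-metabolite pairs.  Block-constant correlation
matrices of arbitrary size are not automatically positive semidefinite, so
the matrix is repaired by eigenvalue clipping and rescaled to unit
diagonal before sampling; if the repair moves any correlation by more than
0.05 the configuration is rejected as infeasible.

The network generator is the download-free stand-in for subsampling real
protein-protein and chemical-interaction databases: per-block Bernoulli
edges with heavy-tailed confidence weights in [1, 999], and an enrichment
knob that multiplies the edge probability among signal features so that
signals have elevated connectivity (interaction ratio scores above 1), as
disease genes do in curated networks.  When real edge lists are available,
:func:`subsample_network` reproduces the subsampling route instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .network import FeatureSet, MultiOmicsNetwork, WeightConfig
from .prioritization import AssociationScores, prioritize, test_scores
from .similarity import OmicsDataset, build_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "NetworkTopology",
    "GroundTruth",
    "make_truth",
    "build_correlation",
    "simulate_omics",
    "simulate_network",
    "subsample_network",
    "run_study",
    "summarize_study",
]

#: repairing the correlation matrix to PSD must not move any entry more
#: than this (in correlation units), else the config is infeasible
MAX_REPAIR_SHIFT = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults describe the reference scenario: 5000 genes (175 signal) and
    60 metabolites (12 signal) profiled in 100 cases and 100 controls.
    Gene expressions sit around 6 (log2-like scale, SD 2) with signal
    means raised to 6.15; metabolite abundances around 0 (SD 2.5) with
    signal means at 0.15.  ``rho_gm`` orders the gene-metabolite
    correlations as (signal-signal, signal gene-noise metabolite,
    noise gene-signal metabolite, noise-noise).
    """

    n_genes: int = 5000
    n_signal_genes: int = 175
    n_metabolites: int = 60
    n_signal_metabolites: int = 12
    n_cases: int = 100
    n_controls: int = 100
    mu_signal_gene: float = 6.15
    mu_noise_gene: float = 6.0
    mu_signal_met: float = 0.15
    mu_noise_met: float = 0.0
    sigma_gene: float = 2.0
    sigma_met: float = 2.5
    rho_gg: tuple[float, float, float] = (0.25, 0.20, 0.225)  # (ss, nn, sn)
    rho_mm: tuple[float, float, float] = (0.30, 0.15, 0.225)  # (ss, nn, sn)
    rho_gm: tuple[float, float, float, float] = (0.05, 0.03, 0.03, 0.01)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_signal_genes <= self.n_genes:
            raise ValueError("need 0 < n_signal_genes <= n_genes")
        if not 0 < self.n_signal_metabolites <= self.n_metabolites:
            raise ValueError("need 0 < n_signal_metabolites <= n_metabolites")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if self.sigma_gene <= 0 or self.sigma_met <= 0:
            raise ValueError("standard deviations must be positive")
        for rho in (*self.rho_gg, *self.rho_mm, *self.rho_gm):
            if not 0 <= rho < 1:
                raise ValueError(f"correlations must lie in [0, 1), got {rho}")


@dataclass(frozen=True)
class NetworkTopology:
    """Edge densities and signal enrichment of the synthetic network.

    Densities default to those of a STRING+STITCH composite network over
    a prostate-cancer cohort's features (~18k genes, ~200 metabolites):
    3.3% of gene pairs, 23% of metabolite pairs and 2.3% of
    gene-metabolite pairs carry an edge.  ``signal_enrichment``
    multiplies the edge probability for pairs where both endpoints are
    signal features (in all three blocks), giving signals the elevated
    connectivity observed for curated disease genes; 1 means no
    enrichment.
    """

    density_gg: float = 0.033
    density_mm: float = 0.23
    density_gm: float = 0.023
    signal_enrichment: float = 3.0

    def __post_init__(self) -> None:
        for name in ("density_gg", "density_mm", "density_gm"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.signal_enrichment < 1:
            raise ValueError("signal_enrichment must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Identifiers of the true signal features."""

    signal_genes: frozenset[str]
    signal_metabolites: frozenset[str]

    def __init__(self, signal_genes: Iterable[str], signal_metabolites: Iterable[str]):
        object.__setattr__(self, "signal_genes", frozenset(signal_genes))
        object.__setattr__(self, "signal_metabolites", frozenset(signal_metabolites))

    def is_signal(self, feature_id: str) -> bool:
        return feature_id in self.signal_genes or feature_id in self.signal_metabolites


def default_features(n_genes: int, n_metabolites: int) -> FeatureSet:
    """Canonical synthetic identifiers G0001.., M001.. ."""
    gw = max(4, len(str(n_genes)))
    mw = max(3, len(str(n_metabolites)))
    return FeatureSet(
        genes=[f"G{i:0{gw}d}" for i in range(1, n_genes + 1)],
        metabolites=[f"M{i:0{mw}d}" for i in range(1, n_metabolites + 1)],
    )


def make_truth(
    cfg: SimulationConfig, features: FeatureSet, rng: np.random.Generator
) -> GroundTruth:
    """Randomly designate signal genes and metabolites."""
    sg = rng.choice(features.n_genes, size=cfg.n_signal_genes, replace=False)
    sm = rng.choice(features.n_metabolites, size=cfg.n_signal_metabolites, replace=False)
    return GroundTruth(
        signal_genes=(features.genes[i] for i in sg),
        signal_metabolites=(features.metabolites[i] for i in sm),
    )


def _signal_mask(features: FeatureSet, truth: GroundTruth) -> np.ndarray:
    return np.array([truth.is_signal(f) for f in features.all_ids], dtype=bool)


def build_correlation(
    cfg: SimulationConfig, features: FeatureSet, truth: GroundTruth
) -> np.ndarray:
    """Block-constant correlation matrix, repaired to PSD.

    The raw matrix assigns each feature pair the correlation of its block
    (signal/noise x gene/metabolite combination).  Eigenvalues are clipped
    at 1e-8, the matrix rebuilt and rescaled to unit diagonal; a repair
    that moves any entry by more than 0.05 raises, since the requested
    correlation structure is then not achievable.
    """
    n = features.n_features
    ng = features.n_genes
    sig = _signal_mask(features, truth)
    gene = np.zeros(n, dtype=bool)
    gene[:ng] = True

    R = np.empty((n, n))
    sg, ng_mask = sig & gene, ~sig & gene
    sm, nm_mask = sig & ~gene, ~sig & ~gene
    rho_ss, rho_nn, rho_sn = cfg.rho_gg
    R[np.ix_(sg, sg)] = rho_ss
    R[np.ix_(ng_mask, ng_mask)] = rho_nn
    R[np.ix_(sg, ng_mask)] = rho_sn
    R[np.ix_(ng_mask, sg)] = rho_sn
    rho_ss, rho_nn, rho_sn = cfg.rho_mm
    R[np.ix_(sm, sm)] = rho_ss
    R[np.ix_(nm_mask, nm_mask)] = rho_nn
    R[np.ix_(sm, nm_mask)] = rho_sn
    R[np.ix_(nm_mask, sm)] = rho_sn
    r_ss, r_sn, r_ns, r_nn = cfg.rho_gm
    for gmask, mmask, rho in (
        (sg, sm, r_ss),
        (sg, nm_mask, r_sn),
        (ng_mask, sm, r_ns),
        (ng_mask, nm_mask, r_nn),
    ):
        R[np.ix_(gmask, mmask)] = rho
        R[np.ix_(mmask, gmask)] = rho
    np.fill_diagonal(R, 1.0)

    w, V = np.linalg.eigh(R)
    if w.min() >= 1e-8:
        return R
    w_clipped = np.clip(w, 1e-8, None)
    R_fix = (V * w_clipped) @ V.T
    d = np.sqrt(np.diag(R_fix))
    R_fix = R_fix / np.outer(d, d)
    R_fix = (R_fix + R_fix.T) / 2.0
    np.fill_diagonal(R_fix, 1.0)
    shift = float(np.abs(R_fix - R).max())
    if shift > MAX_REPAIR_SHIFT:
        raise ValueError(
            f"PSD repair moved a correlation by {shift:.3f} > {MAX_REPAIR_SHIFT}; "
            "the requested correlation structure is infeasible"
        )
    logger.debug("correlation matrix repaired to PSD (max shift %.2e)", shift)
    return R_fix


def simulate_omics(
    cfg: SimulationConfig,
    truth: Optional[GroundTruth] = None,
    features: Optional[FeatureSet] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[OmicsDataset, GroundTruth]:
    """Draw case/control omics profiles from N(mu, Sigma).

    Sigma_ij = rho_ij sigma_i sigma_j with block-constant rho; the same
    Sigma is used for both groups, and only the means differ: cases have
    the signal means at their elevated values, controls sit at the noise
    means everywhere.  Sampling order is fixed (cases first, features in
    canonical order, samples row-major), so results are reproducible from
    the seed regardless of configuration details.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if features is None:
        features = default_features(cfg.n_genes, cfg.n_metabolites)
    if truth is None:
        truth = make_truth(cfg, features, rng)

    n = features.n_features
    ng = features.n_genes
    sig = _signal_mask(features, truth)
    sigma = np.where(np.arange(n) < ng, cfg.sigma_gene, cfg.sigma_met)
    mu_control = np.where(np.arange(n) < ng, cfg.mu_noise_gene, cfg.mu_noise_met)
    mu_case = mu_control.copy()
    mu_case[sig & (np.arange(n) < ng)] = cfg.mu_signal_gene
    mu_case[sig & (np.arange(n) >= ng)] = cfg.mu_signal_met

    R = build_correlation(cfg, features, truth)
    w, V = np.linalg.eigh(R)
    factor = V * np.sqrt(np.clip(w, 0.0, None))  # factor @ factor.T == R

    Z = rng.standard_normal((cfg.n_cases + cfg.n_controls, n))
    X = (Z @ factor.T) * sigma
    X[: cfg.n_cases] += mu_case
    X[cfg.n_cases:] += mu_control

    group = np.r_[np.ones(cfg.n_cases, dtype=int), np.zeros(cfg.n_controls, dtype=int)]
    sample_ids = [f"case{i+1:03d}" for i in range(cfg.n_cases)] + [
        f"ctrl{i+1:03d}" for i in range(cfg.n_controls)
    ]
    data = OmicsDataset(
        sample_ids=sample_ids,
        features=features,
        values=X,
        design="two_group",
        group=group,
    )
    return data, truth


def _heavy_weights(rng: np.random.Generator, size: int) -> np.ndarray:
    """Heavy-tailed integer confidence weights in [1, 999]."""
    u = rng.random(size)
    return np.ceil(999 * u**4).clip(1, 999)


def _bernoulli_block(
    rng: np.random.Generator,
    shape: tuple[int, int],
    density: float,
    boost_rows: np.ndarray,
    boost_cols: np.ndarray,
    enrichment: float,
) -> np.ndarray:
    prob = np.full(shape, density)
    prob[np.ix_(boost_rows, boost_cols)] = min(1.0, density * enrichment)
    edges = rng.random(shape) < prob
    W = np.zeros(shape)
    W[edges] = _heavy_weights(rng, int(edges.sum()))
    return W


def simulate_network(
    n_genes: int,
    n_metabolites: int,
    truth: GroundTruth,
    topology: NetworkTopology = NetworkTopology(),
    seed: int = 0,
    features: Optional[FeatureSet] = None,
    rng: Optional[np.random.Generator] = None,
) -> MultiOmicsNetwork:
    """Random block network with signal-enriched connectivity.

    Each block draws Bernoulli edges at its density, multiplied by
    ``topology.signal_enrichment`` for pairs of signal features, with
    heavy-tailed confidence weights.  gg and mm are sampled on the upper
    triangle and mirrored.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    if features is None:
        features = default_features(n_genes, n_metabolites)
    if features.n_genes != n_genes or features.n_metabolites != n_metabolites:
        raise ValueError("features inconsistent with requested counts")
    sig_g = np.array([g in truth.signal_genes for g in features.genes])
    sig_m = np.array([m in truth.signal_metabolites for m in features.metabolites])
    if sig_g.sum() != len(truth.signal_genes) or sig_m.sum() != len(
        truth.signal_metabolites
    ):
        raise ValueError("ground truth contains identifiers outside the feature set")

    gg = _bernoulli_block(
        rng, (n_genes, n_genes), topology.density_gg,
        np.flatnonzero(sig_g), np.flatnonzero(sig_g), topology.signal_enrichment,
    )
    gg = np.triu(gg, k=1)
    gg = gg + gg.T
    mm = _bernoulli_block(
        rng, (n_metabolites, n_metabolites), topology.density_mm,
        np.flatnonzero(sig_m), np.flatnonzero(sig_m), topology.signal_enrichment,
    )
    mm = np.triu(mm, k=1)
    mm = mm + mm.T
    gm = _bernoulli_block(
        rng, (n_genes, n_metabolites), topology.density_gm,
        np.flatnonzero(sig_g), np.flatnonzero(sig_m), topology.signal_enrichment,
    )
    return MultiOmicsNetwork(
        features=features, gg=gg, mm=mm, gm=gm, weight_scale="raw_confidence"
    )


def subsample_network(
    net: MultiOmicsNetwork,
    keep_genes: Sequence[str],
    keep_metabolites: Sequence[str],
) -> MultiOmicsNetwork:
    """Induced sub-network on the given identifiers, weights preserved."""
    gene_pos = {g: i for i, g in enumerate(net.features.genes)}
    met_pos = {m: i for i, m in enumerate(net.features.metabolites)}
    unknown = [f for f in keep_genes if f not in gene_pos] + [
        f for f in keep_metabolites if f not in met_pos
    ]
    if unknown:
        raise KeyError(f"unknown identifiers: {unknown[:5]}")
    gidx = np.array([gene_pos[g] for g in keep_genes], dtype=int)
    midx = np.array([met_pos[m] for m in keep_metabolites], dtype=int)
    return MultiOmicsNetwork(
        features=FeatureSet(list(keep_genes), list(keep_metabolites)),
        gg=net.gg[np.ix_(gidx, gidx)],
        mm=net.mm[np.ix_(midx, midx)],
        gm=net.gm[np.ix_(gidx, midx)],
        weight_scale=net.weight_scale,
    )


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Per-replicate generator seeded by the counter scheme
    ``SeedSequence([master_seed, replicate])``."""
    return np.random.default_rng(np.random.SeedSequence([master_seed, replicate]))


def run_study(
    cfg: SimulationConfig,
    weight_grid: Sequence[tuple[float, float]],
    n_reps: int,
    seed: int,
    ks: Sequence[int] = (100, 200, 500),
    topology: NetworkTopology = NetworkTopology(),
    base_cfg: WeightConfig = WeightConfig(),
    include_s0_variant: bool = False,
    solver: str = "iterative",
) -> pd.DataFrame:
    """Replicate the simulation benchmark.

    Each replicate draws a fresh network and cohort, computes two-sample
    t-test p-values and the pooled similarity matrix, then prioritizes
    with the General Network baseline, the no-reweighting baseline
    (lambda_g = lambda_m = 1, labelled ``disnep``), and the reweighted
    method at every grid point; top-k true-signal counts are recorded for
    each.  Rows are tidy: one per (replicate, method, k).  Fully
    reproducible from ``seed`` via the per-replicate counter scheme.
    """
    from .evaluation import topk_counts

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not weight_grid:
        raise ValueError("weight_grid must contain at least one (lambda_g, lambda_m)")
    ks = [int(k) for k in ks]
    n_feat = cfg.n_genes + cfg.n_metabolites
    if any(k > n_feat for k in ks):
        raise ValueError(f"k exceeds the {n_feat} available features")

    rows = []
    for rep in range(n_reps):
        rng = replicate_rng(seed, rep)
        features = default_features(cfg.n_genes, cfg.n_metabolites)
        truth = make_truth(cfg, features, rng)
        net = simulate_network(
            cfg.n_genes, cfg.n_metabolites, truth, topology, features=features, rng=rng
        )
        data, _ = simulate_omics(cfg, truth=truth, features=features, rng=rng)
        pvals = test_scores(data)
        sim = build_similarity(data)

        runs: list[tuple[str, float, float, AssociationScores]] = []
        res = prioritize(net, sim=sim, pvalues=pvals, cfg=base_cfg,
                         variant="general", solver=solver)
        runs.append(("general", np.nan, np.nan, res))
        res = prioritize(net, sim=sim, pvalues=pvals, cfg=base_cfg,
                         variant="disnep", solver=solver)
        runs.append(("disnep", 1.0, 1.0, res))
        for lg, lm in weight_grid:
            mcfg = base_cfg.with_lambdas(lg, lm)
            res = prioritize(net, sim=sim, pvalues=pvals, cfg=mcfg,
                             variant="multinep", solver=solver)
            runs.append(("multinep", lg, lm, res))
            if include_s0_variant:
                res = prioritize(net, sim=sim, pvalues=pvals, cfg=mcfg,
                                 variant="multinep-s0", solver=solver)
                runs.append(("multinep-s0", lg, lm, res))

        for method, lg, lm, res in runs:
            counts = topk_counts(res, truth, ks)
            for _, row in counts.iterrows():
                rows.append(
                    {
                        "replicate": rep,
                        "method": method,
                        "lambda_g": lg,
                        "lambda_m": lm,
                        "k": int(row["k"]),
                        "true_signal_genes": int(row["true_signal_genes"]),
                        "true_signal_metabolites": int(row["true_signal_metabolites"]),
                        "combined": int(row["combined"]),
                    }
                )
    return pd.DataFrame(rows)


def summarize_study(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of the top-k counts per method and k."""
    group_cols = ["method", "lambda_g", "lambda_m", "k"]
    value_cols = ["true_signal_genes", "true_signal_metabolites", "combined"]
    g = table.groupby(group_cols, dropna=False)[value_cols]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem(ddof=1).add_suffix("_se")
    n = g.size().rename("n_reps")
    return pd.concat([mean, sem, n], axis=1).reset_index()
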