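"""Association scores and their diffusion on the enhanced network.

Per-feature two-sided p-values (from a two-sample or paired t-test, or
supplied directly) are mapped to nonnegative association scores

    v0 = Phi^{-1}(1 - p/2),

the half-normal quantile of the evidence -- 0 at p = 1, ~1.96 at p = 0.05.
The scores are then smoothed over the disease-specific transition network
SE by a second random walk with restart,

    v_{t+1} = beta SE v_t + (1 - beta) v0,

whose fixed point v = (1-beta)(I - beta SE)^{-1} v0 redistributes evidence
from each feature to the features it feeds in the network.  Features are
ranked by the diffused score over the combined gene+metabolite list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .enhancement import EnhancedNetwork, enhance, rwr_solve
from .network import (
    FeatureSet,
    MultiOmicsNetwork,
    WeightConfig,
    column_normalize,
    compose,
    denoise,
)
from .similarity import OmicsDataset, build_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationScores",
    "VARIANTS",
    "scores_from_pvalues",
    "test_scores",
    "diffuse",
    "prioritize",
]

#: p-values of exactly 0 are clamped here so scores stay finite (score ~37)
P_FLOOR = 1e-300

VARIANTS = ("multinep", "multinep-s0", "disnep", "general")


@dataclass(frozen=True)
class DiffusionResult:
    v: np.ndarray
    n_iter: int
    residual: float


@dataclass
class AssociationScores:
    """Prioritized per-feature scores.

    ``ranks`` are 1-based over the combined gene+metabolite list,
    descending by diffused score ``v``; ties are broken deterministically
    by (score desc, genes before metabolites, identifier).
    """

    features: FeatureSet
    pvalues: np.ndarray
    v0: np.ndarray
    v: np.ndarray
    ranks: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """One row per feature, sorted by rank."""
        ng = self.features.n_genes
        df = pd.DataFrame(
            {
                "feature": list(self.features.all_ids),
                "type": ["gene"] * ng + ["metabolite"] * self.features.n_metabolites,
                "pvalue": self.pvalues,
                "v0": self.v0,
                "v": self.v,
                "rank": self.ranks,
            }
        )
        df["type_rank"] = df.groupby("type")["rank"].rank(method="first").astype(int)
        return df.sort_values("rank").reset_index(drop=True)

    def top(self, k: int) -> tuple[str, ...]:
        """Identifiers of the k best-ranked features."""
        order = np.argsort(self.ranks)
        ids = self.features.all_ids
        return tuple(ids[i] for i in order[:k])


def scores_from_pvalues(p: np.ndarray) -> np.ndarray:
    """Map two-sided p-values to half-normal scores Phi^{-1}(1 - p/2)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n_zero = int(np.count_nonzero(p == 0))
    if n_zero:
        logger.warning(
            "scores_from_pvalues: %d zero p-value(s) clamped to %.0e; "
            "their scores (~37) will dominate the initial score vector",
            n_zero, P_FLOOR,
        )
        p = np.maximum(p, P_FLOOR)
    # Phi^{-1}(1 - p/2) computed as -Phi^{-1}(p/2): exact by symmetry and
    # numerically stable for tiny p, where 1 - p/2 rounds to 1
    return -ndtri(p / 2)


def test_scores(data: OmicsDataset, flavor: str = "welch") -> np.ndarray:
    """Two-sided per-feature p-values from the dataset's design.

    ``two_group`` designs use a two-sample t-test (Welch by default,
    ``flavor='student'`` for pooled variance); ``paired`` designs use a
    paired t-test on case/control pairs matched by pair identifier.
    Features with zero variance in every group yield p = 1 with a warning.
    """
    if flavor not in ("welch", "student"):
        raise ValueError("flavor must be 'welch' or 'student'")
    if data.design == "two_group":
        cases = data.values[data.group == 1]
        controls = data.values[data.group == 0]
        if len(cases) < 2 or len(controls) < 2:
            raise ValueError("each group needs at least 2 samples for a t-test")
        res = stats.ttest_ind(cases, controls, axis=0, equal_var=(flavor == "student"))
        p = np.asarray(res.pvalue, dtype=float)
    elif data.design == "paired":
        case_rows = {pid: i for i, pid in enumerate(data.pair_id[data.group == 1])}
        ctrl_rows = {pid: i for i, pid in enumerate(data.pair_id[data.group == 0])}
        shared = [pid for pid in case_rows if pid in ctrl_rows]
        if len(shared) < 2:
            raise ValueError("paired t-test needs at least 2 complete pairs")
        case_idx = np.flatnonzero(data.group == 1)[[case_rows[p_] for p_ in shared]]
        ctrl_idx = np.flatnonzero(data.group == 0)[[ctrl_rows[p_] for p_ in shared]]
        res = stats.ttest_rel(data.values[case_idx], data.values[ctrl_idx], axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError(f"design {data.design!r} does not define a test")
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.warning(
            "test_scores: %d feature(s) with zero within-group variance; p set to 1",
            int(degenerate.sum()),
        )
        p = np.where(degenerate, 1.0, p)
    return p


def diffuse(
    SE: Union[np.ndarray, EnhancedNetwork],
    v0: np.ndarray,
    beta: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
    solver: str = "iterative",
) -> DiffusionResult:
    """Iterate v_{t+1} = beta SE v_t + (1-beta) v0 to convergence.

    Stops when the L1 norm of the update drops below ``tol``; raises if
    ``max_iter`` is reached first.  ``solver='direct'`` returns the exact
    fixed point instead.
    """
    M = SE.full if isinstance(SE, EnhancedNetwork) else np.asarray(SE, dtype=float)
    v0 = np.asarray(v0, dtype=float)
    if not 0 <= beta < 1:
        raise ValueError(f"beta must lie in [0, 1), got {beta}")
    if M.shape[0] != M.shape[1] or M.shape[0] != v0.shape[0]:
        raise ValueError(f"dimension mismatch: SE is {M.shape}, v0 is {v0.shape}")
    if solver == "direct":
        return DiffusionResult(v=rwr_solve(M, v0, beta), n_iter=0, residual=0.0)
    if solver != "iterative":
        raise ValueError("solver must be 'iterative' or 'direct'")
    if beta == 0:
        return DiffusionResult(v=v0.copy(), n_iter=1, residual=0.0)
    v = v0.copy()
    restart = (1 - beta) * v0
    residual = np.inf
    for t in range(1, max_iter + 1):
        v_next = beta * (M @ v) + restart
        residual = float(np.abs(v_next - v).sum())
        v = v_next
        if residual < tol:
            return DiffusionResult(v=v, n_iter=t, residual=residual)
    raise RuntimeError(
        f"diffusion did not converge within {max_iter} iterations "
        f"(last residual {residual:.3e} >= tol {tol:.1e})"
    )


def rank_scores(features: FeatureSet, v: np.ndarray) -> np.ndarray:
    """1-based ranks, descending by score.

    Ties broken by feature type (genes before metabolites) then by
    identifier, so ranking is deterministic across runs and platforms.
    """
    ng = features.n_genes
    type_key = np.array([0] * ng + [1] * features.n_metabolites)
    ids = np.array(features.all_ids)
    order = np.lexsort((ids, type_key, -v))
    ranks = np.empty(len(v), dtype=int)
    ranks[order] = np.arange(1, len(v) + 1)
    return ranks


def general_network(net: MultiOmicsNetwork, cfg: WeightConfig) -> EnhancedNetwork:
    """Baseline transition network: denoised, normalized S0 -- no
    reweighting and no disease enhancement."""
    kept = denoise(net, cfg.keep_gg, cfg.keep_mm, cfg.keep_gm)
    return EnhancedNetwork(full=column_normalize(compose(kept)), features=net.features)


def prioritize(
    net: MultiOmicsNetwork,
    sim: Optional[MultiOmicsNetwork] = None,
    data: Optional[OmicsDataset] = None,
    pvalues: Optional[np.ndarray] = None,
    cfg: WeightConfig = WeightConfig(),
    variant: str = "multinep",
    solver: str = "iterative",
    test_flavor: str = "welch",
) -> AssociationScores:
    """Full pipeline: enhance the network, score features, diffuse, rank.

    Exactly one of ``pvalues`` (per-feature, canonical order) or ``data``
    must supply the association evidence; when only ``data`` is given the
    similarity matrix is also built from it.  ``variant`` selects the
    method: ``multinep`` (reweight both network and similarity),
    ``multinep-s0`` (reweight the network only), ``disnep`` (no
    reweighting: lambda_g = lambda_m = 1), or ``general`` (no enhancement:
    diffusion on the denoised, normalized general network).
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if pvalues is None:
        if data is None:
            raise ValueError("either pvalues or data must be provided")
        pvalues = test_scores(data, flavor=test_flavor)
    if sim is None and variant != "general":
        if data is None:
            raise ValueError(f"variant {variant!r} needs a similarity matrix or data")
        sim = build_similarity(data)

    if variant == "general":
        SE = general_network(net, cfg)
    else:
        if variant == "disnep":
            cfg = cfg.with_lambdas(1.0, 1.0)
        if variant == "multinep-s0":
            cfg = replace(cfg, reweight_similarity=False)
        SE = enhance(net, sim, cfg, solver=solver)

    v0 = scores_from_pvalues(pvalues)
    result = diffuse(SE, v0, cfg.beta, tol=cfg.tol, max_iter=cfg.max_iter, solver=solver)
    ranks = rank_scores(net.features, result.v)
    return AssociationScores(
        features=net.features,
        pvalues=np.asarray(pvalues, dtype=float),
        v0=v0,
        v=result.v,
        ranks=ranks,
    )
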