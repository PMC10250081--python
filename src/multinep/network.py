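"""Block-structured multi-omics networks and the operations used on them.

A multi-omics network couples two omics layers -- genes and metabolites --
through three classes of undirected weighted edges: gene-gene (g-g),
metabolite-metabolite (m-m) and gene-metabolite (g-m).  The network is kept
as three dense blocks over a fixed, ordered feature set (genes first, then
metabolites); the full adjacency is the 2x2 block composition

    S = [[gg, gm],
         [gm.T, mm]].

The operations here are the building blocks of the enhancement pipeline:
per-block reweighting (to rebalance the g-g block, which typically
outnumbers the m-m block by two orders of magnitude), symmetrization,
per-block top-fraction denoising, and column normalization to a (sub-)
stochastic transition matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "MultiOmicsNetwork",
    "WeightConfig",
    "reweight",
    "symmetrize",
    "denoise",
    "column_normalize",
    "compose",
    "decompose",
]

#: maximum edge weight on the STRING/STITCH confidence scale
RAW_CONFIDENCE_MAX = 999.0

WEIGHT_SCALES = ("raw_confidence", "normalized", "similarity")


@dataclass(frozen=True)
class FeatureSet:
    """Ordered gene and metabolite identifiers.

    The concatenation genes-then-metabolites is the canonical index order
    for every matrix and vector in the package.
    """

    genes: tuple[str, ...]
    metabolites: tuple[str, ...]

    def __init__(self, genes: Sequence[str], metabolites: Sequence[str]):
        object.__setattr__(self, "genes", tuple(genes))
        object.__setattr__(self, "metabolites", tuple(metabolites))
        if not self.genes or not self.metabolites:
            raise ValueError("both gene and metabolite lists must be non-empty")
        seen: set[str] = set()
        for name in self.genes + self.metabolites:
            if name in seen:
                raise ValueError(f"duplicate feature identifier: {name!r}")
            seen.add(name)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_features(self) -> int:
        return len(self.genes) + len(self.metabolites)

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.genes + self.metabolites

    def index_of(self, feature_id: str) -> int:
        """Position of ``feature_id`` in the canonical order."""
        try:
            return self.all_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature identifier: {feature_id!r}") from None

    def is_gene(self, feature_id: str) -> bool:
        return feature_id in set(self.genes)


def _check_block(name: str, M: np.ndarray, symmetric: bool) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError(f"{name} block must be 2-dimensional")
    if np.any(M < 0):
        raise ValueError(f"{name} block has negative weights")
    if symmetric:
        if M.shape[0] != M.shape[1]:
            raise ValueError(f"{name} block must be square")
        if not np.array_equal(M, M.T):
            raise ValueError(f"{name} block must be symmetric")
        if np.any(np.diag(M) != 0):
            raise ValueError(f"{name} block must have a zero diagonal")
    return M


@dataclass
class MultiOmicsNetwork:
    """Weighted, undirected multi-omics network in block form.

    Parameters
    ----------
    features
        Canonical gene + metabolite ordering.
    gg, mm, gm
        Nonnegative weight blocks.  ``gg`` and ``mm`` are symmetric with a
        zero diagonal; ``gm`` is genes x metabolites.
    weight_scale
        ``raw_confidence`` for STRING/STITCH-style scores in [0, 999],
        ``similarity`` for absolute correlations in [0, 1], or
        ``normalized`` for anything downstream of normalization.
    """

    features: FeatureSet
    gg: np.ndarray
    mm: np.ndarray
    gm: np.ndarray
    weight_scale: str = "raw_confidence"

    def __post_init__(self) -> None:
        if self.weight_scale not in WEIGHT_SCALES:
            raise ValueError(
                f"weight_scale must be one of {WEIGHT_SCALES}, got {self.weight_scale!r}"
            )
        self.gg = _check_block("gg", self.gg, symmetric=True)
        self.mm = _check_block("mm", self.mm, symmetric=True)
        self.gm = _check_block("gm", self.gm, symmetric=False)
        ng, nm = self.features.n_genes, self.features.n_metabolites
        if self.gg.shape != (ng, ng):
            raise ValueError(f"gg shape {self.gg.shape} != ({ng}, {ng})")
        if self.mm.shape != (nm, nm):
            raise ValueError(f"mm shape {self.mm.shape} != ({nm}, {nm})")
        if self.gm.shape != (ng, nm):
            raise ValueError(f"gm shape {self.gm.shape} != ({ng}, {nm})")
        if self.weight_scale == "raw_confidence":
            top = max(m.max(initial=0.0) for m in (self.gg, self.mm, self.gm))
            if top > RAW_CONFIDENCE_MAX:
                raise ValueError(
                    f"raw_confidence weights must be <= {RAW_CONFIDENCE_MAX:g}, "
                    f"found {top:g}"
                )
        if self.weight_scale == "similarity":
            top = max(m.max(initial=0.0) for m in (self.gg, self.mm, self.gm))
            if top > 1.0 + 1e-12:
                raise ValueError(f"similarity weights must be <= 1, found {top:g}")

    def compose(self) -> np.ndarray:
        """Full (genes+metabolites) square adjacency matrix."""
        return compose(self)

    def block(self, name: str) -> np.ndarray:
        if name not in ("gg", "mm", "gm"):
            raise ValueError("block must be one of 'gg', 'mm', 'gm'")
        return getattr(self, name)

    def edge_count(self, block: str) -> int:
        """Number of undirected edges (gg/mm) or pairs (gm) with weight > 0."""
        M = self.block(block)
        if block == "gm":
            return int(np.count_nonzero(M))
        return int(np.count_nonzero(np.triu(M, k=1)))


@dataclass(frozen=True)
class WeightConfig:
    """Pipeline parameters.

    ``lambda_g`` scales the g-g block down and ``lambda_m`` scales the m-m
    block up relative to the untouched g-m block; the defaults (0.05, 20)
    are tuned for a network with ~100x more genes than metabolites.
    ``alpha`` and ``beta`` are the restart mixing weights of the two
    random-walk recursions and must stay below 1 for contraction.  The
    ``keep_*`` fractions are the per-block top-edge retention rates of the
    denoising step.  ``reweight_similarity`` off gives the variant that
    reweights only the general network, not the similarity matrix.
    """

    lambda_g: float = 0.05
    lambda_m: float = 20.0
    alpha: float = 0.75
    beta: float = 0.75
    tol: float = 1e-6
    max_iter: int = 1000
    keep_gg: float = 0.05
    keep_mm: float = 0.30
    keep_gm: float = 0.15
    reweight_similarity: bool = True

    def __post_init__(self) -> None:
        if self.lambda_g <= 0 or self.lambda_m <= 0:
            raise ValueError("lambda_g and lambda_m must be positive")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1), got {v}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        for name in ("keep_gg", "keep_mm", "keep_gm"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    def with_lambdas(self, lambda_g: float, lambda_m: float) -> "WeightConfig":
        return replace(self, lambda_g=lambda_g, lambda_m=lambda_m)


def reweight(
    net: MultiOmicsNetwork, lambda_g: float, lambda_m: float
) -> MultiOmicsNetwork:
    """Scale the gg block by ``lambda_g`` and the mm block by ``lambda_m``.

    The gm block is left untouched, so the two scalars control the
    contributions of the within-omics blocks *relative* to the
    between-omics block.  ``lambda_g = lambda_m = 1`` is the identity.
    """
    if lambda_g <= 0 or lambda_m <= 0:
        raise ValueError("lambda_g and lambda_m must be positive")
    scale = net.weight_scale
    if scale == "raw_confidence" and (lambda_g > 1 or lambda_m > 1):
        # scaled weights may exceed 999; the result is no longer on the
        # raw confidence scale
        scale = "normalized"
    if scale == "similarity" and (lambda_g > 1 or lambda_m > 1):
        scale = "normalized"
    return MultiOmicsNetwork(
        features=net.features,
        gg=net.gg * lambda_g,
        mm=net.mm * lambda_m,
        gm=net.gm.copy(),
        weight_scale=scale,
    )


def symmetrize(M: np.ndarray) -> np.ndarray:
    """Return (M + M.T) / 2; rejects non-square input."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"symmetrize requires a square matrix, got shape {M.shape}")
    return (M + M.T) / 2.0


def _top_fraction_mask(
    weights: np.ndarray, rows: np.ndarray, cols: np.ndarray, keep: float
) -> np.ndarray:
    """Boolean mask selecting the top ``ceil(keep * n)`` of ``n`` edges.

    Ties at the cut are broken deterministically by (weight descending,
    row index ascending, column index ascending).
    """
    n = weights.size
    n_keep = math.ceil(keep * n)
    order = np.lexsort((cols, rows, -weights))
    mask = np.zeros(n, dtype=bool)
    mask[order[:n_keep]] = True
    return mask


def _denoise_symmetric(M: np.ndarray, keep: float, label: str) -> np.ndarray:
    iu = np.triu_indices_from(M, k=1)
    w = M[iu]
    nz = w > 0
    if not nz.any():
        logger.info("denoise: %s block has no nonzero edges; passed through", label)
        return M.copy()
    rows, cols = iu[0][nz], iu[1][nz]
    mask = _top_fraction_mask(w[nz], rows, cols, keep)
    out = np.zeros_like(M)
    out[rows[mask], cols[mask]] = w[nz][mask]
    return out + out.T


def _denoise_rect(M: np.ndarray, keep: float, label: str) -> np.ndarray:
    rows, cols = np.nonzero(M)
    if rows.size == 0:
        logger.info("denoise: %s block has no nonzero edges; passed through", label)
        return M.copy()
    w = M[rows, cols]
    mask = _top_fraction_mask(w, rows, cols, keep)
    out = np.zeros_like(M)
    out[rows[mask], cols[mask]] = w[mask]
    return out


def denoise(
    net: MultiOmicsNetwork,
    keep_gg: float,
    keep_mm: float,
    keep_gm: float,
) -> MultiOmicsNetwork:
    """Per-block sparsification keeping only the heaviest edges.

    Within each block independently, the top ``ceil(keep * E)`` of the
    block's ``E`` nonzero edges (by weight) are retained and all others set
    to zero.  For the symmetric gg/mm blocks an edge is an unordered pair:
    the cut operates on the upper triangle and is mirrored, so symmetry is
    preserved.  Blocks with no nonzero edges pass through with a notice.
    """
    for name, keep in (("keep_gg", keep_gg), ("keep_mm", keep_mm), ("keep_gm", keep_gm)):
        if not 0 < keep <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {keep}")
    return MultiOmicsNetwork(
        features=net.features,
        gg=_denoise_symmetric(net.gg, keep_gg, "gg"),
        mm=_denoise_symmetric(net.mm, keep_mm, "mm"),
        gm=_denoise_rect(net.gm, keep_gm, "gm"),
        weight_scale=net.weight_scale,
    )


def column_normalize(M: np.ndarray) -> np.ndarray:
    """Divide each column with positive sum by its sum.

    Columns that are entirely zero are left as zero, making the result
    column-sub-stochastic rather than fabricating uniform transitions out
    of isolated features; the downstream recursions remain contractions
    because their mixing weights are below 1 and column sums are <= 1.
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise ValueError("column_normalize requires nonnegative entries")
    sums = M.sum(axis=0)
    out = M.copy()
    pos = sums > 0
    out[:, pos] = out[:, pos] / sums[pos]
    return out


def compose(net: MultiOmicsNetwork) -> np.ndarray:
    """Assemble the full square matrix [[gg, gm], [gm.T, mm]]."""
    return np.block([[net.gg, net.gm], [net.gm.T, net.mm]])


def decompose(
    full: np.ndarray, features: FeatureSet, weight_scale: str = "raw_confidence"
) -> MultiOmicsNetwork:
    """Split a full genes+metabolites matrix back into blocks.

    Inverse of :func:`compose` for any matrix whose gg/mm diagonal blocks
    are symmetric with zero diagonals and whose off-diagonal blocks are
    transposes of each other.
    """
    full = np.asarray(full, dtype=float)
    n = features.n_features
    if full.shape != (n, n):
        raise ValueError(f"matrix shape {full.shape} does not match {n} features")
    ng = features.n_genes
    gm = full[:ng, ng:]
    if not np.array_equal(full[ng:, :ng], gm.T):
        raise ValueError("off-diagonal blocks are not transposes of each other")
    return MultiOmicsNetwork(
        features=features,
        gg=full[:ng, :ng],
        mm=full[ng:, ng:],
        gm=gm,
        weight_scale=weight_scale,
    )
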