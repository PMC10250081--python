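"""Network enhancement: random walk with restart on the similarity matrix.

The reweighted general network S0~ is pushed toward a disease-specific
network SE by the recursion

    S_{t+1} = alpha * E~ @ S_t + (1 - alpha) * S0~,      S_0 = S0~,

where E~ is the column-normalized (reweighted) disease similarity matrix.
For alpha < 1 and column sums of E~ at most 1 this is a contraction in the
entrywise L1 norm with factor alpha, so it converges geometrically to the
unique fixed point S* = (1 - alpha) (I - alpha E~)^{-1} S0~.  The iterative
solver is the default; an equivalent direct linear solve is available for
small problems and as an independent cross-check.

After convergence the enhanced matrix is symmetrized, denoised per block
(top 5% of g-g, 30% of m-m, 15% of g-m edges by default) and column
normalized to give the transition matrix SE used for score diffusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .network import (
    FeatureSet,
    MultiOmicsNetwork,
    WeightConfig,
    column_normalize,
    compose,
    denoise,
    reweight,
    symmetrize,
)

logger = logging.getLogger(__name__)

__all__ = ["RWRResult", "EnhancedNetwork", "rwr_matrix", "rwr_solve", "enhance"]


@dataclass(frozen=True)
class RWRResult:
    """Converged random-walk-with-restart state.

    ``residual`` is the entrywise L1 norm of the last update; ``n_iter`` is
    0 when the direct solver was used.
    """

    matrix: np.ndarray
    n_iter: int
    residual: float


def _check_rwr_args(E_norm: np.ndarray, X0: np.ndarray, alpha: float) -> None:
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must lie in [0, 1), got {alpha}")
    if E_norm.ndim != 2 or E_norm.shape[0] != E_norm.shape[1]:
        raise ValueError("E_norm must be square")
    if X0.shape[0] != E_norm.shape[0]:
        raise ValueError(
            f"dimension mismatch: E_norm is {E_norm.shape}, X0 is {X0.shape}"
        )
    col_sums = E_norm.sum(axis=0)
    if np.any(col_sums > 1 + 1e-9):
        raise ValueError(
            "E_norm column sums exceed 1; column-normalize it first "
            f"(max sum {col_sums.max():.6f})"
        )


def rwr_matrix(
    E_norm: np.ndarray,
    S0_tilde: np.ndarray,
    alpha: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> RWRResult:
    """Iterate S_{t+1} = alpha E~ S_t + (1-alpha) S0~ to convergence.

    Iteration stops when the entrywise L1 norm of the update falls below
    ``tol``.  Reaching ``max_iter`` first raises, carrying the last
    residual -- a silent non-converged return would poison everything
    downstream.
    """
    E_norm = np.asarray(E_norm, dtype=float)
    S = np.asarray(S0_tilde, dtype=float)
    _check_rwr_args(E_norm, S, alpha)
    if alpha == 0:
        return RWRResult(matrix=S.copy(), n_iter=1, residual=0.0)
    restart = (1 - alpha) * S
    residual = np.inf
    for t in range(1, max_iter + 1):
        S_next = alpha * (E_norm @ S) + restart
        residual = float(np.abs(S_next - S).sum())
        S = S_next
        if residual < tol:
            logger.debug("rwr_matrix converged in %d iterations (residual %.3e)", t, residual)
            return RWRResult(matrix=S, n_iter=t, residual=residual)
    raise RuntimeError(
        f"random walk did not converge within {max_iter} iterations "
        f"(last residual {residual:.3e} >= tol {tol:.1e})"
    )


def rwr_solve(E_norm: np.ndarray, X0: np.ndarray, alpha: float) -> np.ndarray:
    """Direct fixed point (1-alpha)(I - alpha E~)^{-1} X0.

    Exact closed form of the recursion's limit; intended for small
    problems and as an independent check on the iterative solver.
    """
    E_norm = np.asarray(E_norm, dtype=float)
    X0 = np.asarray(X0, dtype=float)
    _check_rwr_args(E_norm, X0, alpha)
    n = E_norm.shape[0]
    return (1 - alpha) * np.linalg.solve(np.eye(n) - alpha * E_norm, X0)


def enhance(
    net: MultiOmicsNetwork,
    sim: MultiOmicsNetwork,
    cfg: WeightConfig,
    solver: str = "iterative",
) -> MultiOmicsNetwork:
    """Build the disease-specific transition network SE.

    Pipeline: (1) reweight the general network with (lambda_g, lambda_m);
    (2) reweight the similarity matrix the same way (skipped when
    ``cfg.reweight_similarity`` is off, giving the reweight-S0-only
    variant); (3) column-normalize the composed similarity; (4) run the
    matrix random walk with restart; (5) symmetrize; (6) denoise each
    block; (7) column-normalize.  The result carries
    ``weight_scale='normalized'``.
    """
    if solver not in ("iterative", "direct"):
        raise ValueError("solver must be 'iterative' or 'direct'")
    if net.features.all_ids != sim.features.all_ids:
        raise ValueError("network and similarity matrix must share a feature set")

    S0t = compose(reweight(net, cfg.lambda_g, cfg.lambda_m))
    if cfg.reweight_similarity:
        sim = reweight(sim, cfg.lambda_g, cfg.lambda_m)
    E_norm = column_normalize(compose(sim))

    if solver == "direct":
        St = rwr_solve(E_norm, S0t, cfg.alpha)
    else:
        St = rwr_matrix(E_norm, S0t, cfg.alpha, tol=cfg.tol, max_iter=cfg.max_iter).matrix

    St_sym = symmetrize(St)
    ng = net.features.n_genes
    blocks = MultiOmicsNetwork(
        features=net.features,
        gg=_zero_diag(St_sym[:ng, :ng]),
        mm=_zero_diag(St_sym[ng:, ng:]),
        gm=St_sym[:ng, ng:],
        weight_scale="normalized",
    )
    kept = denoise(blocks, cfg.keep_gg, cfg.keep_mm, cfg.keep_gm)
    return EnhancedNetwork(full=column_normalize(compose(kept)), features=net.features)


def _zero_diag(M: np.ndarray) -> np.ndarray:
    out = M.copy()
    np.fill_diagonal(out, 0.0)
    return out


@dataclass(frozen=True)
class EnhancedNetwork:
    """Column-normalized enhanced network SE.

    Column normalization breaks the symmetry of the denoised matrix, so SE
    is kept as the full (genes+metabolites) transition matrix rather than
    as symmetric blocks.  Columns with at least one edge sum to 1; columns
    of isolated features are all zero.
    """

    full: np.ndarray
    features: FeatureSet

    def __post_init__(self) -> None:
        n = self.features.n_features
        if self.full.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.full.shape} does not match {n} features"
            )

    @property
    def gg(self) -> np.ndarray:
        ng = self.features.n_genes
        return self.full[:ng, :ng]

    @property
    def mm(self) -> np.ndarray:
        ng = self.features.n_genes
        return self.full[ng:, ng:]

    @property
    def gm(self) -> np.ndarray:
        ng = self.features.n_genes
        return self.full[:ng, ng:]

    def block(self, name: str) -> np.ndarray:
        if name not in ("gg", "mm", "gm"):
            raise ValueError("block must be one of 'gg', 'mm', 'gm'")
        return getattr(self, name)
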