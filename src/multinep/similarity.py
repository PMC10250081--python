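"""Disease similarity matrices from multi-omics profiles.

The enhancement step needs a disease-specific similarity matrix E with the
same block structure as the general network: absolute pairwise correlations
between feature columns of a samples x (genes+metabolites) expression/
abundance table, partitioned into gene-gene, metabolite-metabolite and
gene-metabolite blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .network import FeatureSet, MultiOmicsNetwork

logger = logging.getLogger(__name__)

__all__ = ["OmicsDataset", "build_similarity", "harmonize"]

DESIGNS = ("two_group", "paired", "none")


@dataclass
class OmicsDataset:
    """A samples x features omics table with an optional study design.

    ``values`` columns follow the canonical order of ``features`` (genes
    then metabolites).  For a ``two_group`` design ``group`` holds one
    binary label per sample (1 = case, 0 = control); for a ``paired``
    design ``pair_id`` additionally matches each case to its control.
    """

    sample_ids: tuple[str, ...]
    features: FeatureSet
    values: np.ndarray
    design: str = "none"
    group: Optional[np.ndarray] = None
    pair_id: Optional[np.ndarray] = None

    def __init__(
        self,
        sample_ids: Sequence[str],
        features: FeatureSet,
        values: np.ndarray,
        design: str = "none",
        group: Optional[Sequence[int]] = None,
        pair_id: Optional[Sequence] = None,
    ):
        self.sample_ids = tuple(str(s) for s in sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        self.features = features
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.sample_ids), features.n_features):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {features.n_features} features"
            )
        if design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}, got {design!r}")
        self.design = design
        self.group = None
        self.pair_id = None
        if design in ("two_group", "paired"):
            if group is None:
                raise ValueError(f"design {design!r} requires group labels")
            self.group = np.asarray(group, dtype=int)
            if self.group.shape != (len(self.sample_ids),):
                raise ValueError("group must hold one label per sample")
            if not set(np.unique(self.group)) <= {0, 1}:
                raise ValueError("group labels must be 0 (control) or 1 (case)")
        if design == "paired":
            if pair_id is None:
                raise ValueError("paired design requires pair identifiers")
            self.pair_id = np.asarray(pair_id)
            if self.pair_id.shape != (len(self.sample_ids),):
                raise ValueError("pair_id must hold one identifier per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def feature_column(self, feature_id: str) -> np.ndarray:
        return self.values[:, self.features.index_of(feature_id)]


def _abs_correlation(values: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        from scipy.stats import rankdata

        values = rankdata(values, axis=0)
    constant = values.max(axis=0) == values.min(axis=0)
    if constant.any():
        logger.warning(
            "build_similarity: %d constant feature column(s) excluded "
            "(zero similarity)", int(constant.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(values, rowvar=False)
    R = np.abs(R)
    R[~np.isfinite(R)] = 0.0
    R[constant, :] = 0.0
    R[:, constant] = 0.0
    np.fill_diagonal(R, 0.0)
    # |r| can exceed 1 by rounding; the similarity scale requires [0, 1]
    np.clip(R, 0.0, 1.0, out=R)
    return R


def build_similarity(data: OmicsDataset, method: str = "pearson") -> MultiOmicsNetwork:
    """Absolute pairwise feature correlations as a block similarity matrix.

    Entry (i, j) is |corr(column i, column j)| for i != j and 0 on the
    diagonal, so the diffusion driven by this matrix cannot self-loop.
    Cases and controls are pooled: the similarity is meant to capture the
    co-variation structure of the disease cohort as a whole.  Constant
    columns get zero similarity everywhere, with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if data.n_samples < 3:
        raise ValueError(
            f"at least 3 samples are required for correlations, got {data.n_samples}"
        )
    R = _abs_correlation(data.values, method)
    ng = data.features.n_genes
    return MultiOmicsNetwork(
        features=data.features,
        gg=(R[:ng, :ng] + R[:ng, :ng].T) / 2.0,
        mm=(R[ng:, ng:] + R[ng:, ng:].T) / 2.0,
        gm=R[:ng, ng:],
        weight_scale="similarity",
    )


def harmonize(
    net: MultiOmicsNetwork, data: OmicsDataset
) -> tuple[MultiOmicsNetwork, OmicsDataset]:
    """Restrict network and dataset to their shared feature identifiers.

    Both objects come back indexed by the intersection, in the network's
    canonical order.  An empty intersection for either omics type is an
    error carrying a sample of the unmatched identifiers, which usually
    signals an identifier-mapping problem upstream.
    """
    data_ids = set(data.features.all_ids)
    keep_genes = [g for g in net.features.genes if g in data_ids]
    keep_mets = [m for m in net.features.metabolites if m in data_ids]
    for kind, kept, net_ids in (
        ("gene", keep_genes, net.features.genes),
        ("metabolite", keep_mets, net.features.metabolites),
    ):
        if not kept:
            sample = ", ".join(list(net_ids)[:5])
            raise ValueError(
                f"no {kind} identifiers shared between network and dataset "
                f"(network has e.g. {sample})"
            )
    n_dropped_net = net.features.n_features - len(keep_genes) - len(keep_mets)
    n_dropped_data = data.features.n_features - len(keep_genes) - len(keep_mets)
    if n_dropped_net or n_dropped_data:
        logger.info(
            "harmonize: dropped %d network features and %d dataset features "
            "outside the intersection", n_dropped_net, n_dropped_data,
        )

    feats = FeatureSet(keep_genes, keep_mets)
    gidx = np.array([net.features.genes.index(g) for g in keep_genes], dtype=int)
    midx = np.array([net.features.metabolites.index(m) for m in keep_mets], dtype=int)
    sub_net = MultiOmicsNetwork(
        features=feats,
        gg=net.gg[np.ix_(gidx, gidx)],
        mm=net.mm[np.ix_(midx, midx)],
        gm=net.gm[np.ix_(gidx, midx)],
        weight_scale=net.weight_scale,
    )
    col_idx = np.array([data.features.index_of(f) for f in feats.all_ids], dtype=int)
    sub_data = OmicsDataset(
        sample_ids=data.sample_ids,
        features=feats,
        values=data.values[:, col_idx],
        design=data.design,
        group=data.group,
        pair_id=data.pair_id,
    )
    return sub_net, sub_data
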