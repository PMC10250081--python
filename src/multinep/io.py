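"""Readers and writers for edge lists, omics tables and result tables.

Edge lists follow the STRING/STITCH convention: whitespace- or
tab-separated rows of (node_a, node_b, weight), one file per block or a
single file with a fourth block-tag column (gg/mm/gm).  Duplicate
undirected edges keep the maximum weight, with a warning.  Omics tables
are delimited text with a header of feature identifiers and a sample-id
first column; feature typing comes from explicit gene/metabolite lists or
from an identifier prefix convention.

All readers reject malformed input with the offending location rather
than silently coercing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .network import FeatureSet, MultiOmicsNetwork
from .prioritization import AssociationScores
from .similarity import OmicsDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_edge_list",
    "read_network",
    "write_network",
    "read_omics_table",
    "write_results",
    "write_study",
    "write_report",
]

PathLike = Union[str, Path]


def read_edge_list(path: PathLike, tagged: bool = False) -> pd.DataFrame:
    """Parse one edge-list file into (node_a, node_b, weight[, block]).

    Rows must have 3 columns (4 when ``tagged``); an optional header line
    is skipped if its weight field is not numeric.  Malformed rows raise
    with their line number.
    """
    n_cols = 4 if tagged else 3
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                weight = float(parts[2])
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                ) from None
            if weight < 0:
                raise ValueError(f"{path}:{lineno}: negative weight {weight}")
            rec = {"node_a": parts[0], "node_b": parts[1], "weight": weight}
            if tagged:
                if parts[3] not in ("gg", "mm", "gm"):
                    raise ValueError(
                        f"{path}:{lineno}: block tag must be gg/mm/gm, got {parts[3]!r}"
                    )
                rec["block"] = parts[3]
            records.append(rec)
    return pd.DataFrame(
        records, columns=["node_a", "node_b", "weight"] + (["block"] if tagged else [])
    )


def _read_node_directives(path: PathLike) -> tuple[list[str], list[str]]:
    """Collect ``#node <type> <id>`` roster lines from an edge-list file."""
    genes, mets = [], []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#node\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 or parts[1] not in ("gene", "metabolite"):
                raise ValueError(f"{path}: malformed node directive {line!r}")
            (genes if parts[1] == "gene" else mets).append(parts[2])
    return genes, mets


def _dedupe(edges: pd.DataFrame, undirected: bool, label: str) -> pd.DataFrame:
    if edges.empty:
        return edges
    e = edges.copy()
    if undirected:
        pairs = e[["node_a", "node_b"]]
        e["node_a"] = pairs.min(axis=1)
        e["node_b"] = pairs.max(axis=1)
    n_before = len(e)
    e = e.groupby(["node_a", "node_b"], as_index=False, sort=False)["weight"].max()
    if len(e) < n_before:
        logger.warning(
            "read_network: %d duplicate %s edge(s) collapsed (max weight kept)",
            n_before - len(e), label,
        )
    return e


def read_network(
    gg: Optional[PathLike] = None,
    mm: Optional[PathLike] = None,
    gm: Optional[PathLike] = None,
    tagged: Optional[PathLike] = None,
    genes: Optional[Sequence[str]] = None,
    metabolites: Optional[Sequence[str]] = None,
    weight_scale: str = "raw_confidence",
) -> MultiOmicsNetwork:
    """Assemble a multi-omics network from edge-list files.

    Supply either the three per-block files (``gg``, ``mm``, ``gm``) or a
    single ``tagged`` file with a block column.  Node types are inferred
    from where an identifier appears (gg/mm membership and gm sides); an
    identifier claimed as both gene and metabolite is an error.  Explicit
    ``genes``/``metabolites`` lists override inference and may add
    isolated nodes.
    """
    if tagged is not None:
        if any(p is not None for p in (gg, mm, gm)):
            raise ValueError("give either a tagged file or per-block files, not both")
        all_edges = read_edge_list(tagged, tagged=True)
        parts = {
            b: all_edges[all_edges["block"] == b].drop(columns="block")
            for b in ("gg", "mm", "gm")
        }
    else:
        if gg is None and mm is None and gm is None:
            raise ValueError("no edge-list files given")
        empty = pd.DataFrame(columns=["node_a", "node_b", "weight"])
        parts = {
            "gg": read_edge_list(gg) if gg else empty,
            "mm": read_edge_list(mm) if mm else empty,
            "gm": read_edge_list(gm) if gm else empty,
        }
    e_gg = _dedupe(parts["gg"], undirected=True, label="gg")
    e_mm = _dedupe(parts["mm"], undirected=True, label="mm")
    e_gm = _dedupe(parts["gm"], undirected=False, label="gm")

    seen_genes = list(
        dict.fromkeys(
            list(e_gg["node_a"]) + list(e_gg["node_b"]) + list(e_gm["node_a"])
        )
    )
    seen_mets = list(
        dict.fromkeys(
            list(e_mm["node_a"]) + list(e_mm["node_b"]) + list(e_gm["node_b"])
        )
    )
    roster_genes, roster_mets = [], []
    paths = [tagged] if tagged is not None else [p for p in (gg, mm, gm) if p]
    for p in paths:
        rg, rm = _read_node_directives(p)
        roster_genes += [g for g in rg if g not in roster_genes]
        roster_mets += [m for m in rm if m not in roster_mets]
    if genes is not None:
        gene_list = list(genes)
    else:
        gene_list = roster_genes if roster_genes else seen_genes
    if metabolites is not None:
        met_list = list(metabolites)
    else:
        met_list = roster_mets if roster_mets else seen_mets
    conflict = sorted(set(gene_list) & set(met_list))
    if conflict:
        raise ValueError(
            f"{len(conflict)} identifier(s) appear as both gene and metabolite, "
            f"e.g. {conflict[:5]}"
        )
    for name, claimed, allowed in (
        ("gene", seen_genes, set(gene_list)),
        ("metabolite", seen_mets, set(met_list)),
    ):
        missing = [x for x in claimed if x not in allowed]
        if missing:
            raise ValueError(
                f"edge files mention {name}s absent from the explicit list: "
                f"{missing[:5]}"
            )

    feats = FeatureSet(gene_list, met_list)
    gpos = {g: i for i, g in enumerate(feats.genes)}
    mpos = {m: i for i, m in enumerate(feats.metabolites)}
    GG = np.zeros((feats.n_genes, feats.n_genes))
    for a, b, w in e_gg.itertuples(index=False):
        i, j = gpos[a], gpos[b]
        if i == j:
            raise ValueError(f"self-edge on gene {a!r}")
        GG[i, j] = GG[j, i] = w
    MM = np.zeros((feats.n_metabolites, feats.n_metabolites))
    for a, b, w in e_mm.itertuples(index=False):
        i, j = mpos[a], mpos[b]
        if i == j:
            raise ValueError(f"self-edge on metabolite {a!r}")
        MM[i, j] = MM[j, i] = w
    GM = np.zeros((feats.n_genes, feats.n_metabolites))
    for a, b, w in e_gm.itertuples(index=False):
        GM[gpos[a], mpos[b]] = w
    return MultiOmicsNetwork(
        features=feats, gg=GG, mm=MM, gm=GM, weight_scale=weight_scale
    )


def write_network(net, path: PathLike) -> None:
    """Write a network (block form or enhanced full form) as a tagged
    edge list: node_a, node_b, weight, block.

    Symmetric blocks are written once per unordered pair; the enhanced
    (asymmetric) form writes every nonzero directed entry.  The node
    roster is recorded in ``#node`` comment lines so isolated features and
    the canonical order survive a round trip.
    """
    feats = net.features
    rows = []
    from .enhancement import EnhancedNetwork

    if isinstance(net, EnhancedNetwork):
        blocks = [("gg", net.gg, False), ("mm", net.mm, False), ("gm", net.gm, False)]
    else:
        blocks = [("gg", net.gg, True), ("mm", net.mm, True), ("gm", net.gm, False)]
    for tag, M, symmetric in blocks:
        if tag == "gg":
            row_ids = col_ids = feats.genes
        elif tag == "mm":
            row_ids = col_ids = feats.metabolites
        else:
            row_ids, col_ids = feats.genes, feats.metabolites
        src = np.triu(M, k=1) if symmetric else M
        for i, j in zip(*np.nonzero(src)):
            rows.append((row_ids[i], col_ids[j], repr(float(src[i, j])), tag))
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\tblock\n")
        for g in feats.genes:
            fh.write(f"#node\tgene\t{g}\n")
        for m in feats.metabolites:
            fh.write(f"#node\tmetabolite\t{m}\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


def read_omics_table(
    path: PathLike,
    genes: Optional[Sequence[str]] = None,
    metabolites: Optional[Sequence[str]] = None,
    gene_prefix: str = "G",
    met_prefix: str = "M",
    label_col: Optional[str] = None,
    pair_col: Optional[str] = None,
    sep: str = "\t",
) -> OmicsDataset:
    """Read a samples x features table into an :class:`OmicsDataset`.

    The first column holds sample ids; remaining columns are features plus
    the optional design columns.  Features are classified by the explicit
    ``genes``/``metabolites`` lists when given, else by identifier prefix.
    ``label_col`` (binary, 1 = case) selects a two-group design;
    adding ``pair_col`` makes it paired.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated sample ids: {dupes[:5]}")
    group = pair_id = None
    design = "none"
    if label_col is not None:
        if label_col not in df.columns:
            raise ValueError(f"label column {label_col!r} not found in {path}")
        group = df[label_col].to_numpy()
        df = df.drop(columns=label_col)
        design = "two_group"
    if pair_col is not None:
        if label_col is None:
            raise ValueError("pair_col requires label_col")
        if pair_col not in df.columns:
            raise ValueError(f"pair column {pair_col!r} not found in {path}")
        pair_id = df[pair_col].to_numpy()
        df = df.drop(columns=pair_col)
        design = "paired"

    cols = list(df.columns)
    if genes is not None or metabolites is not None:
        gene_set = set(genes or [])
        met_set = set(metabolites or [])
        gene_cols = [c for c in cols if c in gene_set]
        met_cols = [c for c in cols if c in met_set]
        unknown = [c for c in cols if c not in gene_set and c not in met_set]
        if unknown:
            raise ValueError(
                f"columns not classified as gene or metabolite: {unknown[:5]}"
            )
    else:
        gene_cols = [c for c in cols if c.startswith(gene_prefix)]
        met_cols = [c for c in cols if c.startswith(met_prefix) and c not in gene_cols]
        unknown = [c for c in cols if c not in gene_cols and c not in met_cols]
        if unknown:
            raise ValueError(
                f"columns match neither prefix {gene_prefix!r} nor {met_prefix!r}: "
                f"{unknown[:5]}"
            )
    values = df[gene_cols + met_cols]
    bad = values.columns[~values.apply(
        lambda c: pd.api.types.is_numeric_dtype(c)
    )].tolist()
    if bad:
        raise ValueError(f"non-numeric feature column(s): {bad[:5]}")
    return OmicsDataset(
        sample_ids=[str(s) for s in df.index],
        features=FeatureSet(gene_cols, met_cols),
        values=values.to_numpy(dtype=float),
        design=design,
        group=group,
        pair_id=pair_id,
    )


def write_omics_table(data: OmicsDataset, path: PathLike, sep: str = "\t") -> None:
    """Inverse of :func:`read_omics_table` (design columns first)."""
    df = pd.DataFrame(
        data.values, index=list(data.sample_ids), columns=list(data.features.all_ids)
    )
    df.index.name = "sample"
    if data.group is not None:
        df.insert(0, "group", data.group)
    if data.pair_id is not None:
        df.insert(1, "pair", data.pair_id)
    df.to_csv(path, sep=sep)


def write_results(scores: AssociationScores, path: PathLike) -> None:
    """Ranked per-feature table: feature, type, p-value, v0, v, rank."""
    scores.to_frame().to_csv(path, sep="\t", index=False)


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_study(table: pd.DataFrame, path: PathLike) -> None:
    """Tidy study table (one row per replicate x method x k)."""
    table.to_csv(path, sep="\t", index=False)


def write_report(report: pd.DataFrame, path: PathLike) -> None:
    """Evaluation report (top-k table or IRS comparison)."""
    report.to_csv(path, sep="\t", index=False)


def read_pvalues(path: PathLike) -> pd.Series:
    """Two-column table (feature, pvalue) -> Series indexed by feature."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (feature, pvalue)")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    if ((s < 0) | (s > 1)).any():
        raise ValueError(f"{path}: p-values outside [0, 1]")
    return s
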