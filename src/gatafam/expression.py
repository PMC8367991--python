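"""Expression-matrix ingestion, hierarchical clustering of genes, and
co-expression coherence of gene clusters (PCs).

FPKM values are log2(x+1) transformed by default before clustering;
distances and linkage mirror R's ``hclust`` conventions (euclidean /
complete by default) via :mod:`scipy.cluster.hierarchy`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .phylo import GeneCluster

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    genes: list
    conditions: list
    values: np.ndarray  # genes x conditions, raw FPKM
    transform: str = "log2p1"
    n_missing_filled: int = 0

    def transformed(self) -> np.ndarray:
        if self.transform == "log2p1":
            return np.log2(self.values + 1.0)
        return self.values

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.conditions)


def load_fpkm(table_path: str, transform: str = "log2p1",
              family_ids: Optional[Sequence[str]] = None) -> ExpressionMatrix:
    """Read a delimited gene x condition FPKM table.

    First column holds gene IDs, header row condition labels.  Missing
    cells become 0 with a warning; duplicate gene IDs and negative values
    are errors.  Unknown IDs (relative to ``family_ids``) are kept with a
    warning.
    """
    df = pd.read_csv(table_path, sep=None, engine="python", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene id(s): {dups}")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        log.warning("filled %d missing cell(s) with 0", n_missing)
        df = df.fillna(0.0)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative FPKM value in table")
    if family_ids is not None:
        unknown = sorted(set(df.index) - set(family_ids))
        if unknown:
            log.warning("%d gene id(s) not in the family set kept: %s",
                        len(unknown), ", ".join(unknown[:5]))
    return ExpressionMatrix(
        genes=list(df.index),
        conditions=list(df.columns),
        values=values,
        transform=transform,
        n_missing_filled=n_missing,
    )


def cluster_genes(
    m: ExpressionMatrix, distance: str = "euclidean", linkage: str = "complete"
) -> np.ndarray:
    """Agglomerative dendrogram (scipy linkage matrix) over genes."""
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("complete", "average"):
        raise ValueError(f"unknown linkage {linkage!r}")
    if len(m.genes) < 2:
        raise ValueError("need at least 2 genes")
    X = m.transformed()
    if distance == "correlation":
        sd = X.std(axis=1)
        flat = np.flatnonzero(sd == 0)
        if flat.size:
            raise ValueError(
                f"zero-variance gene under correlation distance: {m.genes[flat[0]]!r}"
            )
    d = pdist(X, metric=distance)
    return hierarchy.linkage(d, method=linkage)


def flat_clusters(Z: np.ndarray, genes: Sequence[str], k: int) -> dict:
    """Cut the dendrogram into k flat clusters: gene -> cluster label."""
    if k < 1 or k > len(genes):
        raise ValueError(f"k={k} outside [1, {len(genes)}]")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(genes, (int(x) for x in labels)))


def pc_coherence(
    Z: np.ndarray,
    genes: Sequence[str],
    clusters: Sequence[GeneCluster],
    k: Optional[int] = None,
    gene_of_member: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Label each PC's co-expression coherence at a k-cluster cut.

    ``full`` — all expressed members share one flat cluster; ``partial`` —
    at least two members share one but not all; ``none`` — no two members
    co-cluster; ``not_assessable`` — fewer than two members expressed.
    ``k`` defaults to the number of PCs with expressed members.
    """
    gene_of_member = gene_of_member or {}
    present = set(genes)
    member_genes = {
        cl.pc_id: sorted(
            {gene_of_member.get(m, m) for m in cl.members} & present
        )
        for cl in clusters
    }
    if k is None:
        k = max(sum(1 for v in member_genes.values() if len(v) >= 2), 1)
    assign = flat_clusters(Z, genes, k)
    rows = []
    for cl in clusters:
        mem = member_genes[cl.pc_id]
        if len(mem) < 2:
            label = "not_assessable"
        else:
            tally: dict = {}
            for g in mem:
                tally[assign[g]] = tally.get(assign[g], 0) + 1
            biggest = max(tally.values())
            if biggest == len(mem) and len(tally) == 1:
                label = "full"
            elif biggest >= 2:
                label = "partial"
            else:
                label = "none"
        rows.append({"pc_id": cl.pc_id, "n_expressed": len(mem), "coherence": label})
    return pd.DataFrame(rows)
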