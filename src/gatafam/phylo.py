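"""Domain alignment, neighbor-joining trees, bootstrap support, subfamily
assignment and gene-cluster (orthogroup) extraction.

The domain alignment is anchor-based rather than optimized: the four
cysteines of the class-IV zinc finger are forced into common columns and
spacer/flank residues are padded with gaps, which is exact for this motif
family and keeps the alignment deterministic.  Trees are classic
Saitou-Nei neighbor joining on p-distances with documented tie-breaks,
held in :class:`skbio.TreeNode` so rooting, patristic distances and
newick serialization come from scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from skbio import TreeNode

from ._util import as_rng, round_half_up
from .domain_scan import DomainHit

GAP = "-"


# ---------------------------------------------------------------------------
# anchor alignment


@dataclass
class DomainAlignment:
    rows: dict  # member_id -> aligned string
    column_count: int
    anchor_columns: tuple  # four column indices of C1..C4

    @property
    def ids(self) -> list:
        return list(self.rows)

    def motif_region(self) -> tuple:
        """[start, end) columns of the C..C tetrad."""
        return (self.anchor_columns[0], self.anchor_columns[3] + 1)

    def matrix(self, ids: Optional[Sequence[str]] = None) -> np.ndarray:
        ids = list(ids) if ids is not None else self.ids
        return np.array([list(self.rows[i]) for i in ids])


def anchor_align(
    domains: Sequence[tuple],
    flank5: int = 7,
    flank3: int = 25,
) -> DomainAlignment:
    """Align complete domains by their cysteine anchors.

    ``domains`` is a sequence of ``(member_id, protein, DomainHit)``;
    partial (IV_p) hits are rejected.  Within each spacer, gaps are
    right-justified (inserted immediately before the next cysteine);
    flanks are taken from the source protein and end-gap padded.
    """
    if not domains:
        raise ValueError("empty domain set")
    for member_id, _, hit in domains:
        if not hit.complete:
            raise ValueError(f"partial (IV_p) domain for {member_id!r} cannot be anchor-aligned")
    s1max = max(h.spacers[0] for _, _, h in domains)
    s2max = max(h.spacers[1] for _, _, h in domains)
    s3 = domains[0][2].spacers[2]
    rows = {}
    for member_id, protein, hit in domains:
        c1, c2, c3, c4 = hit.c_positions
        s1, s2, _ = hit.spacers
        left = protein[max(0, c1 - flank5): c1]
        left = GAP * (flank5 - len(left)) + left
        right = protein[c4 + 1: c4 + 1 + flank3]
        right = right + GAP * (flank3 - len(right))
        row = (
            left
            + "C" + protein[c1 + 1: c2] + GAP * (s1max - s1)
            + "C" + protein[c2 + 1: c3] + GAP * (s2max - s2)
            + "C" + protein[c3 + 1: c4]
            + "C" + right
        )
        if member_id in rows:
            raise ValueError(f"duplicate member id {member_id!r}")
        rows[member_id] = row
    anchors = (
        flank5,
        flank5 + 1 + s1max,
        flank5 + 1 + s1max + 1 + s2max,
        flank5 + 1 + s1max + 1 + s2max + 1 + s3,
    )
    ncol = anchors[3] + 1 + flank3
    assert all(len(r) == ncol for r in rows.values())
    return DomainAlignment(rows=rows, column_count=ncol, anchor_columns=anchors)


def align_from_hits(
    proteins: Mapping[str, str], hits: Mapping[str, DomainHit], **kw
) -> DomainAlignment:
    return anchor_align([(m, proteins[m], h) for m, h in hits.items()], **kw)


# ---------------------------------------------------------------------------
# distances and neighbor joining


def _pdist_from_arrays(M: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Vectorized p-distance: mismatches / comparable (non-gap) columns."""
    both = valid[:, None, :] & valid[None, :, :]
    ncomp = both.sum(axis=2)
    if (ncomp + np.eye(len(M), dtype=int) == 0).any():
        raise ValueError("a pair of rows shares no comparable columns")
    mism = ((M[:, None, :] != M[None, :, :]) & both).sum(axis=2)
    with np.errstate(invalid="ignore"):
        d = np.where(ncomp > 0, mism / np.maximum(ncomp, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    return d


def pdistance_matrix(aln: DomainAlignment, ids: Optional[Sequence[str]] = None):
    """Pairwise p-distance with pairwise deletion of gapped columns."""
    ids = list(ids) if ids is not None else aln.ids
    if len(ids) < 3:
        raise ValueError("need at least 3 rows")
    M = aln.matrix(ids)
    return _pdist_from_arrays(M, M != GAP), ids


def nj_tree(d: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-matrix ties are broken by the smallest (row, column) index pair in
    the current working order; negative branch lengths are clamped to 0
    with the deficit transferred to the sister edge.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any() or (d < 0).any():
        raise ValueError("distance matrix must be non-negative and finite")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [TreeNode(name=str(i)) for i in ids]
    D = d.copy()
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (i, j)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min((int(a), int(b)) for a, b in cand if a < b)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length = float(li)
        nj_.length = float(lj)
        parent.extend([ni, nj_])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes = [nodes[k] for k in keep] + [parent]
        D = D2
    root = TreeNode()
    a, b = nodes
    a.length = float(max(D[0, 1], 0.0))
    b.length = 0.0
    root.extend([a, b])
    return root


# ---------------------------------------------------------------------------
# bootstrap


def _bipartitions(tree: TreeNode) -> set:
    """Non-trivial bipartitions as canonical frozensets of tip names."""
    tips = frozenset(t.name for t in tree.tips())
    ref = min(tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tips - side) < 2:
            continue
        parts.add(side if ref not in side else tips - side)
    return parts


def bootstrap_support(
    aln: DomainAlignment,
    replicates: int = 1000,
    seed: int = 0,
    ids: Optional[Sequence[str]] = None,
) -> TreeNode:
    """NJ tree with bootstrap support on internal nodes.

    Columns are resampled with replacement per replicate (seeded);
    support = percentage of replicate trees containing each bipartition
    of the reference tree, stored as ``node.support``.  Alignments with
    fewer than 4 rows return the tree with no supports.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids = list(ids) if ids is not None else aln.ids
    d, _ = pdistance_matrix(aln, ids)
    tree = nj_tree(d, ids)
    for node in tree.non_tips(include_self=True):
        node.support = None
    if len(ids) < 4:
        return tree
    rng = as_rng(seed)
    M = aln.matrix(ids)
    valid = M != GAP
    ncol = M.shape[1]
    counts: dict = {}
    for _ in range(replicates):
        cols = rng.integers(0, ncol, size=ncol)
        try:
            db = _pdist_from_arrays(M[:, cols], valid[:, cols])
        except ValueError:
            continue  # a pair lost all comparable columns in this resample
        for part in _bipartitions(nj_tree(db, ids)):
            counts[part] = counts.get(part, 0) + 1
    tipset = frozenset(ids)
    ref = min(tipset)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(tipset - side) < 2:
            continue
        key = side if ref not in side else tipset - side
        node.support = 100.0 * counts.get(key, 0) / replicates
    return tree


# ---------------------------------------------------------------------------
# subfamily assignment and gene clusters


def assign_subfamily(
    tree: TreeNode, anchors: Mapping[str, str], rtol: float = 1e-9
) -> dict:
    """Label each non-anchor tip with the subfamily of its nearest anchor.

    Distance is patristic (sum of branch lengths); exact ties between
    anchors of different subfamilies yield "unresolved".
    """
    if not anchors:
        raise ValueError("no anchors supplied")
    dm = tree.tip_tip_distances()
    names = list(dm.ids)
    anchor_names = [a for a in names if a in anchors]
    if not anchor_names:
        raise ValueError("no anchors present in the tree")
    out = {}
    for name in names:
        if name in anchors:
            continue
        dists = np.array([dm[name, a] for a in anchor_names])
        best = dists.min()
        close = [anchor_names[k] for k in np.flatnonzero(dists <= best * (1 + rtol) + 1e-300)]
        subs = {anchors[a] for a in close}
        out[name] = subs.pop() if len(subs) == 1 else "unresolved"
    return out


@dataclass
class GeneCluster:
    """A named clade of family members spanning multiple species (a PC)."""

    pc_id: str
    members: list
    species_counts: dict
    support: Optional[float]
    subfamily: str = ""


def detect_clusters(
    tree: TreeNode,
    species_map: Mapping[str, str],
    anchors: Iterable[str] = (),
    min_species: int = 5,
    min_support: float = 50.0,
    subfamilies: Optional[Mapping[str, str]] = None,
    subfamily_order: Sequence[str] = ("III", "II", "I", "IV"),
) -> tuple:
    """Extract maximal well-supported in-genus clades (gene clusters).

    A clade qualifies when all its tips are in-genus (non-anchor), it
    spans >= ``min_species`` distinct species, and its support (when
    computed) is >= ``min_support``.  Maximality: qualifying clades nested
    inside another qualifying clade are absorbed.  Clusters are numbered
    PC01.. by subfamily (``subfamily_order``) and, within a subfamily, by
    preorder position in the midpoint-rooted tree.  Returns
    ``(clusters, unclustered_ids)``.
    """
    anchors = set(anchors)
    rooted = tree.root_at_midpoint()
    for tip in rooted.tips():
        if tip.name not in species_map and tip.name not in anchors:
            raise ValueError(f"unlabelled leaf {tip.name!r}")
    found = []  # (preorder_index, node, tipnames)
    order = {id(n): k for k, n in enumerate(rooted.preorder(include_self=True))}
    claimed: set = set()

    def qualifies(node) -> bool:
        if node.is_root():
            return False  # the whole tree is never a cluster
        tipnames = [t.name for t in node.tips()]
        if any(t in anchors for t in tipnames):
            return False
        sp = {species_map[t] for t in tipnames}
        if len(sp) < min_species or len(tipnames) < 2:
            return False
        sup = getattr(node, "support", None)
        return sup is None or sup >= min_support

    def walk(node):
        if not node.children:
            return
        if qualifies(node):
            tipnames = [t.name for t in node.tips()]
            found.append((order[id(node)], node, tipnames))
            claimed.update(tipnames)
            return
        for ch in node.children:
            walk(ch)

    walk(rooted)

    def sub_key(tipnames):
        if not subfamilies:
            return (len(subfamily_order), "")
        labels = [subfamilies.get(t, "") for t in tipnames]
        maj = max(set(labels), key=labels.count)
        try:
            return (subfamily_order.index(maj), maj)
        except ValueError:
            return (len(subfamily_order), maj)

    found.sort(key=lambda rec: (sub_key(rec[2])[0], rec[0]))
    clusters = []
    for k, (_, node, tipnames) in enumerate(found, start=1):
        counts: dict = {}
        for t in tipnames:
            counts[species_map[t]] = counts.get(species_map[t], 0) + 1
        clusters.append(
            GeneCluster(
                pc_id=f"PC{k:02d}",
                members=sorted(tipnames),
                species_counts=counts,
                support=getattr(node, "support", None),
                subfamily=sub_key(tipnames)[1],
            )
        )
    unclustered = sorted(
        t.name for t in rooted.tips() if t.name not in claimed and t.name not in anchors
    )
    return clusters, unclustered


def tf_per_gene_ratio(
    clusters: Sequence[GeneCluster],
    gene_of_member: Mapping[str, str],
    species_map: Mapping[str, str],
    isoform_counts: Mapping[str, int],
):
    """Per-species x per-PC ratio of coding isoforms (TFs) per member gene.

    Tree members may be isoform-level; ``gene_of_member`` collapses them
    to genes.  Species absent from a PC get a missing value.
    """
    import pandas as pd

    records = {}
    for cl in clusters:
        by_species: dict = {}
        for m in cl.members:
            by_species.setdefault(species_map[m], set()).add(gene_of_member[m])
        row = {}
        for sp, genes in by_species.items():
            total = sum(isoform_counts[g] for g in genes)
            row[sp] = round_half_up(total / len(genes))
        records[cl.pc_id] = row
    return pd.DataFrame(records).T.sort_index()
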