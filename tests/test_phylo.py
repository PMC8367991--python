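"""Anchor alignment, neighbor joining, bootstrap, subfamilies, clusters."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from gatafam import phylo
from gatafam.domain_scan import DomainHit, best_hit, scan_zf_motifs
from gatafam.phylo import (
    DomainAlignment,
    anchor_align,
    assign_subfamily,
    bootstrap_support,
    detect_clusters,
    nj_tree,
    pdistance_matrix,
    tf_per_gene_ratio,
)
from gatafam.synthetic import SimConfig, make_family


def _member(name, s1, s2, mid=None):
    protein = "Z" * 7 + "C" + "N" * s1 + "C" + (mid or "Q" * s2) + "C" + "GG" + "C" + "Y" * 25
    (hit,) = scan_zf_motifs(protein)
    return (name, protein, hit)


# ---------------------------------------------------------------------------
# alignment


def test_equal_spacers_align_without_gaps():
    aln = anchor_align([_member("a", 2, 18), _member("b", 2, 18)])
    assert "-" not in aln.rows["a"] and "-" not in aln.rows["b"]
    assert aln.rows["a"] == aln.rows["b"]


def test_shorter_s2_gains_gaps_before_third_cysteine():
    aln = anchor_align([_member("b18", 2, 18), _member("c20", 2, 20)])
    c3 = aln.anchor_columns[2]
    row = aln.rows["b18"]
    assert row[c3 - 2: c3] == "--"
    assert row[c3] == "C"
    assert aln.rows["c20"].count("-") == 0


def test_shorter_s1_gains_gaps_before_second_cysteine():
    aln = anchor_align([_member("iv4", 4, 18), _member("ivb", 2, 18)])
    c2 = aln.anchor_columns[1]
    row = aln.rows["ivb"]
    assert row[c2 - 2: c2] == "--"
    assert row[c2] == "C"


def test_anchor_columns_hold_cysteines():
    aln = anchor_align([_member("a", 2, 17), _member("b", 4, 20), _member("c", 2, 18)])
    for row in aln.rows.values():
        assert all(row[c] == "C" for c in aln.anchor_columns)


def test_partial_hit_rejected():
    partial = DomainHit("p", (1, None, None, None), None, "IV_p", (1, 30))
    with pytest.raises(ValueError, match="p"):
        anchor_align([("p", "A" * 40, partial)])
    with pytest.raises(ValueError):
        anchor_align([])


# ---------------------------------------------------------------------------
# distances


def test_pdistance_identical_rows_zero():
    aln = anchor_align([_member(x, 2, 18) for x in "abc"])
    d, ids = pdistance_matrix(aln)
    assert np.allclose(d, 0.0)


def test_pdistance_direct_ratio():
    rows = {"a": "A" * 50, "b": "A" * 45 + "K" * 5, "c": "A" * 50}
    aln = DomainAlignment(rows=rows, column_count=50, anchor_columns=(0, 1, 2, 3))
    d, ids = pdistance_matrix(aln)
    assert d[ids.index("a"), ids.index("b")] == pytest.approx(0.1)


def test_pdistance_matches_bruteforce_column_walk():
    rng = np.random.default_rng(3)
    rows = {
        f"r{i}": "".join(rng.choice(list("ACDE-"), size=60)) for i in range(6)
    }
    aln = DomainAlignment(rows=rows, column_count=60, anchor_columns=(0, 1, 2, 3))
    d, ids = pdistance_matrix(aln)
    for i, j in itertools.combinations(range(6), 2):
        a, b = rows[ids[i]], rows[ids[j]]
        comp = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        expect = sum(x != y for x, y in comp) / len(comp)
        assert d[i, j] == pytest.approx(expect)


# ---------------------------------------------------------------------------
# neighbor joining


def _additive_tree(n, rng):
    """Random binary tree with positive lengths + its additive matrix."""
    nodes = [TreeNode(name=str(i), length=float(rng.uniform(0.1, 1.0))) for i in range(n)]
    while len(nodes) > 2:
        i, j = 0, 1
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.extend([nodes[i], nodes[j]])
        nodes = nodes[2:] + [parent]
    root = TreeNode()
    root.extend(nodes)
    ids = [str(i) for i in range(n)]
    dm = root.tip_tip_distances()
    d = np.array([[dm[a, b] for b in ids] for a in ids])
    return root, d, ids


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
    tree = nj_tree(d, list("abc"))
    dm = tree.tip_tip_distances()
    assert dm["a", "b"] == pytest.approx(5)
    assert dm["a", "c"] == pytest.approx(9)
    assert dm["b", "c"] == pytest.approx(10)


@pytest.mark.parametrize("n", [4, 8, 12])
def test_nj_recovers_additive_tree(n):
    rng = np.random.default_rng(n)
    true, d, ids = _additive_tree(n, rng)
    got = nj_tree(d, ids)
    dm = got.tip_tip_distances()
    for a, b in itertools.combinations(ids, 2):
        assert dm[a, b] == pytest.approx(d[ids.index(a), ids.index(b)], abs=1e-9)
    # identical bipartitions
    assert phylo._bipartitions(got) == phylo._bipartitions(true)


def test_nj_matches_skbio_on_random_matrix():
    rng = np.random.default_rng(9)
    n = 7
    x = rng.uniform(0.1, 1.0, size=(n, 12))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    ids = [f"t{i}" for i in range(n)]
    ours = nj_tree(d, ids)
    ref = skbio_nj(DistanceMatrix(d, ids))
    assert phylo._bipartitions(ours) == phylo._bipartitions(ref)


def test_nj_least_squares_bruteforce_n6():
    """NJ on an additive matrix equals the best least-squares topology
    found by exhaustive enumeration of all unrooted 6-taxon trees."""
    rng = np.random.default_rng(17)
    _, d, ids = _additive_tree(6, rng)

    def topologies(labels):
        if len(labels) == 3:
            t = TreeNode()
            t.extend([TreeNode(name=x) for x in labels])
            yield t
            return
        head, rest = labels[-1], labels[:-1]
        for t in topologies(rest):
            edges = [nd for nd in t.traverse() if not nd.is_root()]
            for k in range(len(edges)):
                t2 = t.copy()
                edges2 = [nd for nd in t2.traverse() if not nd.is_root()]
                target = edges2[k]
                parent = target.parent
                newint = TreeNode()
                parent.remove(target)
                newint.extend([target, TreeNode(name=head)])
                parent.append(newint)
                yield t2

    def ls_error(tree, d, ids):
        tips = {t.name: t for t in tree.tips()}
        edges = [nd for nd in tree.traverse() if not nd.is_root()]
        pairs = list(itertools.combinations(ids, 2))
        A = np.zeros((len(pairs), len(edges)))
        for r, (a, b) in enumerate(pairs):
            path = set(tips[a].ancestors() + [tips[a]]) ^ set(tips[b].ancestors() + [tips[b]])
            for c, e in enumerate(edges):
                if e in path:
                    A[r, c] = 1.0
        y = np.array([d[ids.index(a), ids.index(b)] for a, b in pairs])
        x, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(((A @ x - y) ** 2).sum())

    best = min(topologies(ids), key=lambda t: ls_error(t, d, ids))
    assert phylo._bipartitions(nj_tree(d, ids)) == phylo._bipartitions(best)


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        nj_tree(np.array([[0.0, np.nan], [np.nan, 0.0]]), ["a", "b"])
    d = np.zeros((3, 3))
    d[0, 1] = -1
    with pytest.raises(ValueError):
        nj_tree(d, list("abc"))


# ---------------------------------------------------------------------------
# bootstrap


def _two_clade_alignment():
    rows = {}
    for i in range(3):
        rows[f"a{i}"] = "AAAAAAAAAA" + "KKKKKKKKKK"
        rows[f"b{i}"] = "DDDDDDDDDD" + "KKKKKKKKKK"
    return DomainAlignment(rows=rows, column_count=20, anchor_columns=(0, 1, 2, 3))


def test_separating_edge_gets_full_support():
    aln = _two_clade_alignment()
    tree = bootstrap_support(aln, replicates=100, seed=1)
    tips = {frozenset(t.name for t in nd.tips()): nd for nd in tree.non_tips()}
    sep = [nd for key, nd in tips.items()
           if key in (frozenset({"a0", "a1", "a2"}), frozenset({"b0", "b1", "b2"}))]
    assert sep and all(nd.support == 100.0 for nd in sep)


def test_bootstrap_deterministic_per_seed():
    rng = np.random.default_rng(2)
    rows = {f"r{i}": "".join(rng.choice(list("ACDEG"), size=40)) for i in range(6)}
    aln = DomainAlignment(rows=rows, column_count=40, anchor_columns=(0, 1, 2, 3))
    t1 = bootstrap_support(aln, replicates=50, seed=5)
    t2 = bootstrap_support(aln, replicates=50, seed=5)
    s1 = {frozenset(t.name for t in nd.tips()): nd.support for nd in t1.non_tips()}
    s2 = {frozenset(t.name for t in nd.tips()): nd.support for nd in t2.non_tips()}
    assert s1 == s2


def test_bootstrap_supports_permutation_equivariant():
    rng = np.random.default_rng(4)
    rows = {f"r{i}": "".join(rng.choice(list("ACDEG"), size=40)) for i in range(6)}
    aln = DomainAlignment(rows=rows, column_count=40, anchor_columns=(0, 1, 2, 3))
    ids = list(rows)
    perm = ids[::-1]
    renamed = DomainAlignment(
        rows={f"x_{k}": rows[k] for k in rows}, column_count=40, anchor_columns=(0, 1, 2, 3)
    )
    t1 = bootstrap_support(aln, replicates=40, seed=3, ids=ids)
    t2 = bootstrap_support(renamed, replicates=40, seed=3, ids=[f"x_{k}" for k in ids])
    s1 = {frozenset(t.name for t in nd.tips()): nd.support for nd in t1.non_tips()}
    s2 = {frozenset(t.name[2:] for t in nd.tips()): nd.support for nd in t2.non_tips()}
    assert s1 == s2


def test_small_alignment_returns_no_supports():
    aln = anchor_align([_member(x, 2, 18) for x in "abc"])
    tree = bootstrap_support(aln, replicates=10, seed=1)
    assert all(nd.support is None for nd in tree.non_tips(include_self=True))


# ---------------------------------------------------------------------------
# subfamilies and clusters


def test_member_takes_nearest_anchor_subfamily():
    t = TreeNode.read(["((m:0.1,anchor1:0.1):0.5,(anchor2:0.1,x:0.1):0.5);"])
    sub = assign_subfamily(t, {"anchor1": "III", "anchor2": "I"})
    assert sub["m"] == "III"
    assert sub["x"] == "I"


def test_exact_tie_is_unresolved():
    t = TreeNode.read(["((m:0.1,a1:0.5):0.1,(a2:0.3,z:0.1):0.1);"])
    sub = assign_subfamily(t, {"a1": "I", "a2": "II"})
    assert sub["m"] == "unresolved"


def test_no_anchors_errors():
    t = TreeNode.read(["((a:1,b:1):1,c:1);"])
    with pytest.raises(ValueError):
        assign_subfamily(t, {})


def test_subfamily_recovery_on_synthetic_families():
    """Planted subfamily labels recovered for >=95% of members, seeds 1-10."""
    ok = tot = 0
    for seed in range(1, 11):
        fam = make_family(SimConfig(n_species=4, n_clusters=8, mutation_rate=0.05, seed=seed))
        proteins, hits, gene_of = {}, {}, {}
        for g in fam.all_genes():
            t = max(g.coding_transcripts, key=lambda t: len(t.protein))
            h = best_hit([x for x in scan_zf_motifs(t.protein) if x.complete])
            if h:
                proteins[t.transcript_id] = t.protein
                hits[t.transcript_id] = h
                gene_of[t.transcript_id] = g.gene_id
        asub, aprot, ahits = {}, {}, {}
        for name, p, s in fam.anchors:
            hs = scan_zf_motifs(p, name)
            if hs:
                ahits[name], aprot[name], asub[name] = hs[0], p, s
        aln = phylo.align_from_hits({**proteins, **aprot}, {**hits, **ahits})
        d, ids = pdistance_matrix(aln)
        tree = nj_tree(d, ids)
        sub = assign_subfamily(tree, asub)
        truth = fam.truth_genes.set_index("gene_id")
        for m, s in sub.items():
            ok += s == truth.loc[gene_of[m], "subfamily"]
            tot += 1
    assert ok / tot >= 0.95


def _family_tree(fam, replicates=50, seed=1):
    proteins, hits, species_map, gene_of = {}, {}, {}, {}
    for g in fam.all_genes():
        t = max(g.coding_transcripts, key=lambda t: len(t.protein))
        h = best_hit([x for x in scan_zf_motifs(t.protein) if x.complete])
        if h:
            proteins[t.transcript_id] = t.protein
            hits[t.transcript_id] = h
            species_map[t.transcript_id] = g.species
            gene_of[t.transcript_id] = g.gene_id
    asub, aprot, ahits = {}, {}, {}
    for name, p, s in fam.anchors:
        hs = scan_zf_motifs(p, name)
        if hs:
            ahits[name], aprot[name], asub[name] = hs[0], p, s
    aln = phylo.align_from_hits({**proteins, **aprot}, {**hits, **ahits})
    tree = bootstrap_support(aln, replicates=replicates, seed=seed)
    return tree, species_map, gene_of, asub


def test_planted_orthogroups_recovered_exactly():
    """Noise-free 3-orthogroup family over 7 species: every planted
    cluster is extracted with one member per species."""
    fam = make_family(
        SimConfig(n_species=7, n_clusters=3, mutation_rate=0.0,
                  species_dropout=0.0, paralog_prob=0.0, seed=21)
    )
    tree, species_map, gene_of, asub = _family_tree(fam)
    clusters, unclustered = detect_clusters(tree, species_map, anchors=asub)
    assert len(clusters) == 3
    assert unclustered == []
    truth = fam.truth_genes.set_index("gene_id")
    truth_sets = {}
    for m, gid in gene_of.items():
        truth_sets.setdefault(truth.loc[gid, "cluster_id"], set()).add(m)
    assert {frozenset(c.members) for c in clusters} == set(map(frozenset, truth_sets.values()))
    for c in clusters:
        assert set(c.species_counts.values()) == {1}
        assert len(c.species_counts) == 7


def _supported(newick, supports):
    t = TreeNode.read([newick])
    for nd in t.traverse():
        nd.support = None
    for key, s in supports.items():
        for nd in t.non_tips(include_self=True):
            if frozenset(x.name for x in nd.tips()) == frozenset(key):
                nd.support = s
    return t


def test_min_species_threshold_blocks_small_clades():
    leaves = [f"sp{i}|m{i}" for i in range(1, 5)]  # 4 species only
    nwk = "((((%s:1,%s:1):1,%s:1):1,%s:1):1,anchorA:1);" % tuple(leaves)
    t = _supported(nwk, {tuple(leaves): 100.0, tuple(leaves[:3]): 100.0,
                         tuple(leaves[:2]): 100.0})
    species_map = {m: m.split("|")[0] for m in leaves}
    clusters, unclustered = detect_clusters(
        t, species_map, anchors={"anchorA"}, min_species=5
    )
    assert clusters == []
    assert sorted(unclustered) == sorted(leaves)


def test_nested_qualifying_clades_keep_only_maximal():
    inner = [f"sp{i}|a{i}" for i in range(1, 6)]
    outer = inner + [f"sp{i}|b{i}" for i in range(1, 6)]
    nwk = (
        "(((((((%s:1,%s:1):1,%s:1):1,%s:1):1,%s:1):1,"
        "((((%s:1,%s:1):1,%s:1):1,%s:1):1,%s:1):1):1,anchorA:20):1,anchorB:20);"
        % tuple(outer)
    )
    t = _supported(nwk, {tuple(inner): 99.0, tuple(outer): 88.0})
    species_map = {m: m.split("|")[0] for m in outer}
    clusters, _ = detect_clusters(t, species_map, anchors={"anchorA", "anchorB"})
    assert len(clusters) == 1
    assert sorted(clusters[0].members) == sorted(outer)
    assert clusters[0].support == 88.0


def test_leaf_partition_invariant(small_family, small_hits):
    proteins, hits, species_map = {}, {}, {}
    for g in small_family.all_genes():
        t = max(g.coding_transcripts, key=lambda t: len(t.protein))
        h = best_hit([x for x in small_hits[t.transcript_id] if x.complete])
        if h:
            proteins[t.transcript_id] = t.protein
            hits[t.transcript_id] = h
            species_map[t.transcript_id] = g.species
    asub, aprot, ahits = {}, {}, {}
    for name, p, s in small_family.anchors:
        hs = scan_zf_motifs(p, name)
        if hs:
            ahits[name], aprot[name], asub[name] = hs[0], p, s
    aln = phylo.align_from_hits({**proteins, **aprot}, {**hits, **ahits})
    tree = bootstrap_support(aln, replicates=30, seed=2)
    clusters, unclustered = detect_clusters(
        tree, species_map, anchors=asub, min_species=3
    )
    clustered = [m for c in clusters for m in c.members]
    assert len(clustered) == len(set(clustered))
    assert sorted(clustered + unclustered) == sorted(species_map)
    for c in clusters:
        assert sum(c.species_counts.values()) == len(c.members)
        assert len(c.members) >= 2


def test_unlabelled_leaf_errors():
    t = TreeNode.read(["((sp1|m:1,sp2|m:1):1,(mystery:1,anchorA:1):1);"])
    for nd in t.traverse():
        nd.support = None
    with pytest.raises(ValueError, match="mystery"):
        detect_clusters(t, {"sp1|m": "sp1", "sp2|m": "sp2"}, anchors={"anchorA"})


def test_tf_per_gene_ratio_table():
    from gatafam.phylo import GeneCluster

    cl = GeneCluster(
        pc_id="PC01",
        members=["spA|g1", "spA|g2", "spB|g3"],
        species_counts={"spA": 2, "spB": 1},
        support=90.0,
    )
    ratios = tf_per_gene_ratio(
        [cl],
        gene_of_member={"spA|g1": "g1", "spA|g2": "g2", "spB|g3": "g3"},
        species_map={"spA|g1": "spA", "spA|g2": "spA", "spB|g3": "spB"},
        isoform_counts={"g1": 3, "g2": 4, "g3": 1},
    )
    assert ratios.loc["PC01", "spA"] == 3.50
    assert ratios.loc["PC01", "spB"] == 1.00
    assert "spC" not in ratios.columns
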