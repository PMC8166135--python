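import numpy as np
import pytest

from nlrmap import nbarc
from nlrmap.grouping import (Msa, TreeNode, assign_intact_groups,
                             assign_partial_groups, bipartitions,
                             bootstrap_support, identity_distance, nj_tree,
                             progressive_align, tree_from_newick,
                             trim_columns)


class TestProgressiveAlign:
    def test_identical_sequences_gapless(self):
        msa = progressive_align({"a": "MKVLW" * 10, "b": "MKVLW" * 10})
        assert msa.length == 50
        assert "-" not in msa.rows["a"] + msa.rows["b"]

    def test_single_gap_optimal(self):
        msa = progressive_align({"x": "ACDEF", "y": "ACEF"})
        assert msa.length == 5
        assert msa.rows["x"] == "ACDEF"
        assert msa.rows["y"].replace("-", "") == "ACEF"
        assert msa.rows["y"].count("-") == 1

    def test_degapping_returns_inputs(self, clean_panel):
        recs = nbarc.select_candidates(clean_panel.reference.genes)
        seqs = {r.gene_id: nbarc.extract_nbarc(r) for r in recs[:8]}
        msa = progressive_align(seqs)
        for k, s in seqs.items():
            assert msa.degapped(k) == s

    def test_single_sequence_one_row(self):
        msa = progressive_align({"only": "MKWL" * 5})
        assert msa.ids == ["only"] and msa.length == 20


class TestTrimColumns:
    def test_all_gap_column_removed(self):
        rows = {f"s{i}": "A-C" for i in range(10)}
        msa = trim_columns(Msa(list(rows), rows))
        assert msa.length == 2

    def test_column_at_90pct_gaps_retained(self):
        rows = {f"s{i}": ("A-C" if i < 9 else "AAC") for i in range(10)}
        msa = trim_columns(Msa(list(rows), rows))
        assert msa.length == 3  # 0.90 <= 0.92 boundary

    def test_gapless_unchanged(self):
        rows = {"a": "MKV", "b": "MRV"}
        msa = trim_columns(Msa(["a", "b"], rows))
        assert msa.rows == rows

    def test_fully_trimmed_rejected(self):
        rows = {f"s{i}": "-" * 4 for i in range(5)}
        with pytest.raises(ValueError, match="fully trimmed"):
            trim_columns(Msa(list(rows), rows))


class TestIdentityDistance:
    def test_identical_rows_zero(self):
        ids, d = identity_distance(Msa(["a", "b"], {"a": "MKV", "b": "MKV"}))
        assert d[0, 1] == 0.0

    def test_five_of_hundred_mismatches(self):
        s1 = "A" * 100
        s2 = "C" * 5 + "A" * 95
        ids, d = identity_distance(Msa(["a", "b"], {"a": s1, "b": s2}))
        assert d[0, 1] == pytest.approx(0.05)

    def test_disjoint_gap_patterns_distance_one_with_warning(self):
        msa = Msa(["a", "b"], {"a": "MK--", "b": "--MK"})
        with pytest.warns(UserWarning, match="comparable"):
            ids, d = identity_distance(msa)
        assert d[0, 1] == 1.0

    def test_gap_columns_excluded_from_denominator(self):
        msa = Msa(["a", "b"], {"a": "MK-V", "b": "MRCV"})
        ids, d = identity_distance(msa)
        assert d[0, 1] == pytest.approx(1 / 3)


def random_additive_tree(rng, n_leaves):
    """Random binary tree with branch lengths; returns (tree, leaf names)."""
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.05, 0.5)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 0.5)))
        parent.children = [nodes[i], nodes[j]]
        rest = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes = rest + [parent]
    root = TreeNode(name="_root")
    root.children = nodes
    return root


def canonical_bipartitions(tree):
    """Unrooted bipartitions, each side canonicalized vs its complement."""
    all_leaves = frozenset(tree.leaves())
    out = set()
    for side in bipartitions(tree):
        comp = frozenset(all_leaves - side)
        out.add(min(side, comp, key=lambda s: tuple(sorted(s))))
    return out


def tree_distances(tree):
    """Leaf-to-leaf path-length matrix of a TreeNode tree."""
    paths = {}

    def walk(node, depth):
        if node.is_leaf():
            paths[node.name] = depth + node.length
            return
        for c in node.children:
            walk(c, depth + (0 if node.name == "_root" else node.length))

    # compute pairwise via LCA over recursive accumulation
    leaves = sorted(tree.leaves())
    idx = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    def collect(node):
        """Return {leaf: dist to node}; fill D along the way."""
        if node.is_leaf():
            return {node.name: node.length}
        groups = [collect(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for la, da in groups[gi].items():
                    for lb, db in groups[gj].items():
                        D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = da + db
        merged = {}
        for g in groups:
            for l, dist in g.items():
                merged[l] = dist + (node.length if node.name != "_root" else 0)
        return merged

    collect(tree)
    return leaves, D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(ids, d)
        lens = {c.name: c.length for c in tree.children}
        assert lens["a"] == pytest.approx(0.5 * (0.4 + 0.6 - 0.8))
        assert lens["b"] == pytest.approx(0.5 * (0.4 + 0.8 - 0.6))
        assert lens["c"] == pytest.approx(0.5 * (0.6 + 0.8 - 0.4))

    def test_additive_matrix_recovers_topology(self):
        rng = np.random.default_rng(17)
        truth = random_additive_tree(rng, 6)
        leaves, D = tree_distances(truth)
        out = nj_tree(leaves, D)
        assert canonical_bipartitions(out) == canonical_bipartitions(truth)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        truth = random_additive_tree(rng, 7)
        leaves, D = tree_distances(truth)
        t1 = nj_tree(leaves, D)
        perm = rng.permutation(len(leaves))
        leaves2 = [leaves[i] for i in perm]
        t2 = nj_tree(leaves2, D[np.ix_(perm, perm)])
        assert canonical_bipartitions(t1) == canonical_bipartitions(t2)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            nj_tree(["a", "b"], np.zeros((2, 2)))


class TestBootstrap:
    def _msa(self):
        # two tight groups separated by many columns
        rows = {
            "a1": "MKVLWAAGAV" * 4, "a2": "MKVLWAAGAV" * 4,
            "a3": "MKVLWAAGCV" * 4,
            "b1": "QEDNRTTSHH" * 4, "b2": "QEDNRTTSHH" * 4,
            "b3": "QEDNRTTSHY" * 4,
        }
        return Msa(list(rows), rows)

    def test_split_gets_full_support(self):
        tree = bootstrap_support(self._msa(), n_reps=100, seed=4)
        split = frozenset({"a1", "a2", "a3"})
        bps = {bp: node.support for bp, node in bipartitions(tree).items()}
        support = bps.get(split, bps.get(frozenset({"b1", "b2", "b3"})))
        assert support is not None and support >= 95

    def test_zero_reps_no_supports(self):
        tree = bootstrap_support(self._msa(), n_reps=0, seed=1)
        assert all(n.support is None for n in tree.walk())

    def test_fixed_seed_reproducible(self):
        t1 = bootstrap_support(self._msa(), n_reps=50, seed=7)
        t2 = bootstrap_support(self._msa(), n_reps=50, seed=7)
        s1 = {bp: n.support for bp, n in bipartitions(t1).items()}
        s2 = {bp: n.support for bp, n in bipartitions(t2).items()}
        assert s1 == s2


def make_tree(newick):
    return tree_from_newick(newick)


class TestAssignIntact:
    NWK = "((q1:0.1,r1:0.1)98:0.2,(q2:0.1,(r2:0.1,r3:0.1)95:0.1)97:0.2,r4:0.3);"

    def test_supported_clade_label(self):
        tree = make_tree(self.NWK)
        labels = {"r1": "G1", "r2": "G2", "r3": "G2", "r4": "G1"}
        out = assign_intact_groups(tree, labels, support_min=90)
        assert out["q1"] == "G1"
        assert out["q2"] == "G2"

    def test_mixed_clade_unassigned(self):
        nwk = "((q1:0.1,(r1:0.1,r2:0.1)99:0.1)99:0.2,r3:0.2,r4:0.3);"
        tree = make_tree(nwk)
        labels = {"r1": "G1", "r2": "G2", "r3": "G1", "r4": "G2"}
        out = assign_intact_groups(tree, labels, support_min=90)
        assert out["q1"] is None

    def test_no_supported_edges_all_unassigned(self):
        nwk = "((q1:0.1,r1:0.1)50:0.2,(q2:0.1,r2:0.1)60:0.2,r3:0.3);"
        tree = make_tree(nwk)
        out = assign_intact_groups(tree, {"r1": "G1", "r2": "G2",
                                          "r3": "G1"}, support_min=90)
        assert out == {"q1": None, "q2": None}

    def test_conflicting_references_warn(self):
        nwk = "((q1:0.1,(r1:0.1,r2:0.1)99:0.1)99:0.2,r3:0.2,r4:0.3);"
        tree = make_tree(nwk)
        labels = {"r1": "G1", "r2": "G2", "r3": "G1", "r4": "G2"}
        with pytest.warns(UserWarning, match="conflict"):
            out = assign_intact_groups(tree, labels, support_min=90)
        assert out["q1"] is None

    def test_smallest_clade_wins(self):
        # q sits inside a small G2 clade nested in a large mixed clade
        nwk = "(((q:0.1,r2:0.1)99:0.1,r1:0.2)99:0.1,r3:0.2,r4:0.2);"
        tree = make_tree(nwk)
        labels = {"r1": "G1", "r2": "G2", "r3": "G1", "r4": "G1"}
        out = assign_intact_groups(tree, labels, support_min=90)
        assert out["q"] == "G2"


class FakeGene:
    def __init__(self, gid, protein):
        self.gene_id = gid
        self.protein = protein
        self.accession_id = "x"


def fake_record(gid, protein):
    from nlrmap.nbarc import NlrRecord
    gene = FakeGene(gid, protein)
    return NlrRecord(gene=gene, hits=[], status="partial")


class TestAssignPartial:
    def test_majority_vote(self, clean_panel):
        recs = nbarc.select_candidates(clean_panel.reference.genes)
        by_group = {}
        for r in recs:
            g = clean_panel.subgroup_truth[r.gene_id]
            by_group.setdefault(g, []).append(r)
        refs = []
        for g, group_recs in sorted(by_group.items()):
            for r in group_recs[:3]:
                refs.append((r.gene_id, nbarc.extract_nbarc(r), g))
        # a partial = truncated member of G1
        g1 = by_group["G1"][3 if len(by_group["G1"]) > 3 else 0]
        frag = g1.gene.protein[: len(g1.gene.protein) // 2]
        partial = fake_record("frag", frag)
        out = assign_partial_groups([partial], refs)
        assert out["frag"] == "G1"

    def test_no_match_unassigned(self, clean_panel):
        recs = nbarc.select_candidates(clean_panel.reference.genes)
        refs = [(r.gene_id, nbarc.extract_nbarc(r), "G1") for r in recs[:2]]
        partial = fake_record("junk", "PG" * 40)
        assert assign_partial_groups([partial], refs)["junk"] is None

    def test_reference_order_invariance(self, clean_panel):
        recs = nbarc.select_candidates(clean_panel.reference.genes)
        refs = [(r.gene_id, nbarc.extract_nbarc(r),
                 clean_panel.subgroup_truth[r.gene_id]) for r in recs[:8]]
        frag = recs[0].gene.protein[30:150]
        partial = fake_record("p", frag)
        out1 = assign_partial_groups([partial], refs)
        out2 = assign_partial_groups([partial], list(reversed(refs)))
        assert out1 == out2

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="references"):
            assign_partial_groups([], [])
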