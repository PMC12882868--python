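"""Alignment construction/trimming, NJ trees, bootstrap and subgroup labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix, TreeNode

import mybfunnel as mf
from mybfunnel.phylo import Alignment, _bipartitions, p_distance_matrix
from mybfunnel.repeat_scan import AMINO_ACIDS, ProteinRecord


def random_tree_and_distances(rng, n_leaves):
    """Random bifurcating tree with positive branch lengths and its exact
    additive distance matrix (the generating tree is the oracle)."""
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0))) for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    leaves = [f"t{i}" for i in range(n_leaves)]
    d = np.zeros((n_leaves, n_leaves))
    for a in range(n_leaves):
        for b in range(a + 1, n_leaves):
            d[a, b] = d[b, a] = root.find(leaves[a]).distance(root.find(leaves[b]))
    return root, DistanceMatrix(d, leaves)


def mutate(rng, seq, rate):
    return "".join(
        c if rng.random() >= rate else AMINO_ACIDS[rng.integers(0, 20)] for c in seq
    )


class TestBuildMsa:
    def test_identical_sequences_align_without_gaps(self):
        recs = [ProteinRecord(f"s{i}", "ACDEFGHIK") for i in range(4)]
        aln = mf.build_msa(recs)
        assert set(aln.rows.values()) == {"ACDEFGHIK"}

    def test_unique_optimum_example(self):
        aln = mf.build_msa(
            [ProteinRecord("a", "ACD"), ProteinRecord("b", "AD")],
            match=1, mismatch=-1, gap=-1,
        )
        assert aln.rows == {"a": "ACD", "b": "A-D"}

    def test_every_row_degaps_to_its_input(self, rng):
        recs = [
            ProteinRecord(f"s{i}", "".join(rng.choice(list(AMINO_ACIDS), rng.integers(20, 50))))
            for i in range(10)
        ]
        aln = mf.build_msa(recs)
        for rec in recs:
            assert aln.rows[rec.id].replace("-", "") == rec.sequence

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mf.build_msa([ProteinRecord("a", "ACD")])


class TestTrimAlignment:
    def test_majority_gap_column_dropped(self):
        aln = Alignment(rows={"a": "AC", "b": "A-", "c": "A-", "d": "A-"})
        assert mf.trim_alignment(aln).rows == {"a": "A", "b": "A", "c": "A", "d": "A"}

    def test_gap_free_alignment_unchanged(self):
        aln = Alignment(rows={"a": "ACDE", "b": "ACDF", "c": "ACDG"})
        assert mf.trim_alignment(aln).rows == aln.rows

    def test_retention_floor_keeps_ten_percent(self):
        # 10 columns, every column at gap fraction 0.6: all would be dropped,
        # so the 10% floor keeps exactly one (the leftmost)
        rows = {
            "a": "ABCDEFGHIK",
            "b": "ABCDEFGHIK",
            "c": "-" * 10,
            "d": "-" * 10,
            "e": "-" * 10,
        }
        trimmed = mf.trim_alignment(Alignment(rows=rows))
        assert trimmed.n_columns == 1
        assert trimmed.rows["a"] == "A"

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.text(alphabet=list(AMINO_ACIDS) + ["-"] * 8, min_size=12, max_size=12),
            min_size=3,
            max_size=8,
        )
    )
    def test_trimming_properties_hold_for_arbitrary_alignments(self, row_strings):
        """Trimming never increases column count, keeps every row the same
        length, and leaves no column above the gap threshold unless the
        retention floor forced it."""
        aln = Alignment(rows={f"s{i}": r for i, r in enumerate(row_strings)})
        trimmed = mf.trim_alignment(aln)
        assert 1 <= trimmed.n_columns <= aln.n_columns
        floor = int(np.ceil(0.10 * aln.n_columns))
        frac = trimmed.column_gap_fractions()
        assert (frac <= 0.5).all() or trimmed.n_columns == floor

    def test_never_grows_and_idempotent(self, rng):
        chars = list(AMINO_ACIDS) + ["-"] * 6
        rows = {f"s{i}": "".join(rng.choice(chars, 40)) for i in range(6)}
        aln = Alignment(rows=rows)
        once = mf.trim_alignment(aln)
        assert once.n_columns <= aln.n_columns
        assert mf.trim_alignment(once).rows == once.rows


class TestNjTree:
    def test_three_taxon_closed_form(self):
        tree = mf.neighbor_joining(
            DistanceMatrix([[0, 2, 4], [2, 0, 4], [4, 4, 0]], ["a", "b", "c"])
        )
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_recovers_generating_topology_from_additive_matrices(self, rng):
        """NJ is consistent on additive distances: 50 random trees with 5-12
        leaves are reconstructed split-for-split."""
        for _ in range(50):
            n = int(rng.integers(5, 13))
            true_tree, dm = random_tree_and_distances(rng, n)
            est = mf.neighbor_joining(dm)
            tips = frozenset(dm.ids)
            assert _bipartitions(est, tips) == _bipartitions(true_tree, tips)

    def test_identical_sequences_give_zero_length_star(self):
        aln = Alignment(rows={f"s{i}": "ACDEF" for i in range(4)})
        tree = mf.nj_tree(aln)
        assert all((t.length or 0) == 0 for t in tree.traverse())

    def test_incomparable_pair_is_an_error(self):
        aln = Alignment(rows={"a": "AC--", "b": "--DE", "c": "ACDE"})
        with pytest.raises(ValueError, match="no ungapped columns"):
            p_distance_matrix(aln)


class TestBootstrapSupport:
    def _two_clade_alignment(self):
        # two 4-leaf clades separated by many fixed differences
        left, right = "ACDEFGHIKLMNPQRSTVWY" * 2, "VWYACDEFGHIKLMNPQRST" * 2
        rows = {}
        for i in range(4):
            s = list(left)
            s[i] = "W"
            rows[f"L{i}"] = "".join(s)
        for i in range(4):
            s = list(right)
            s[i + 8] = "A"
            rows[f"R{i}"] = "".join(s)
        return Alignment(rows=rows)

    def test_strong_central_split_gets_high_support(self):
        tree = mf.bootstrap_support(self._two_clade_alignment(), 100, seed=7)
        splits = {
            frozenset(t.name for t in node.tips()): node.support
            for node in tree.non_tips()
            if hasattr(node, "support")
        }
        central = [
            s for side, s in splits.items()
            if side in (frozenset({"L0", "L1", "L2", "L3"}), frozenset({"R0", "R1", "R2", "R3"}))
        ]
        assert central and all(s >= 95 for s in central)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        tree = mf.bootstrap_support(self._two_clade_alignment(), 1, seed=3)
        sups = {n.support for n in tree.non_tips() if hasattr(n, "support")}
        assert sups <= {0.0, 100.0}

    def test_fixed_seed_reproduces_supports(self):
        aln = self._two_clade_alignment()
        t1 = mf.bootstrap_support(aln, 25, seed=11)
        t2 = mf.bootstrap_support(aln, 25, seed=11)
        s1 = sorted(n.support for n in t1.non_tips() if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips() if hasattr(n, "support"))
        assert s1 == s2


class TestAssignSubgroups:
    def test_query_sister_to_single_reference(self):
        tree = TreeNode.read(["((q:0.1,ref1:0.1)100:0.5,(ref2:0.1,ref3:0.1)100:0.5);"])
        out = mf.assign_subgroups(tree, {"ref1": "S3", "ref2": "S21", "ref3": "S21"})
        assert out == [mf.SubgroupAssignment("q", "S3", 100.0, 2)]

    def test_majority_label_wins(self):
        tree = TreeNode.read(
            ["((q:0.1,(a:0.1,(b:0.1,c:0.1):0.1):0.1):0.5,(d:0.1,e:0.1):0.5);"]
        )
        out = mf.assign_subgroups(tree, {"a": "S3", "b": "S3", "c": "S21", "d": "X", "e": "X"})
        assert out[0].subgroup == "S3"

    def test_tie_yields_unclassified(self):
        tree = TreeNode.read(["((q:0.1,(a:0.1,b:0.1):0.1):0.5,(d:0.1,e:0.1):0.5);"])
        out = mf.assign_subgroups(tree, {"a": "S3", "b": "S21", "d": "X", "e": "X"})
        assert out[0].subgroup == "unclassified"

    def test_low_support_clades_are_skipped(self):
        tree = TreeNode.read(["((q:0.1,ref1:0.1)10:0.5,(ref2:0.1,ref3:0.1)90:0.5);"])
        out = mf.assign_subgroups(tree, {"ref1": "S3", "ref2": "S21", "ref3": "S21"})
        # the sister clade fails min_support; the next qualifying clade is the
        # whole tree where S21 holds the majority
        assert out[0].subgroup == "S21"

    def test_absent_query_rejected(self):
        tree = TreeNode.read(["((q:0.1,ref1:0.1):0.5,(ref2:0.1,ref3:0.1):0.5);"])
        with pytest.raises(KeyError, match="absent"):
            mf.assign_subgroups(tree, {"ref1": "S3", "ref2": "S3", "ref3": "S3"}, query_ids=["ghost"])

    def test_simulated_families_assign_correctly(self):
        """Queries mutated from per-subgroup ancestors at 10% are assigned to
        their own subgroup in >= 90% of cases over 20 seeds."""
        correct = total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ancestors = {
                f"S{k}": "".join(rng.choice(list(AMINO_ACIDS), 100)) for k in range(1, 5)
            }
            seqs, labels, truth = [], {}, {}
            for sg, anc in ancestors.items():
                for i in range(2):
                    rid = f"{sg}ref{i}"
                    seqs.append(ProteinRecord(rid, mutate(rng, anc, 0.1)))
                    labels[rid] = sg
                qid = f"{sg}query"
                seqs.append(ProteinRecord(qid, mutate(rng, anc, 0.1)))
                truth[qid] = sg
            aln = mf.trim_alignment(mf.build_msa(seqs))
            tree = mf.bootstrap_support(aln, 20, seed=seed)
            for a in mf.assign_subgroups(tree, labels):
                total += 1
                correct += a.subgroup == truth[a.query_id]
        assert correct / total >= 0.9

    def test_invariant_under_leaf_order_permutation(self):
        newick = "((q:0.1,(a:0.1,b:0.1)80:0.1)90:0.5,(d:0.1,e:0.1)95:0.5);"
        permuted = "(((b:0.1,a:0.1)80:0.1,q:0.1)90:0.5,(e:0.1,d:0.1)95:0.5);"
        labels = {"a": "S3", "b": "S3", "d": "X", "e": "X"}
        r1 = mf.assign_subgroups(TreeNode.read([newick]), labels)
        r2 = mf.assign_subgroups(TreeNode.read([permuted]), labels)
        assert {(a.query_id, a.subgroup) for a in r1} == {(a.query_id, a.subgroup) for a in r2}
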