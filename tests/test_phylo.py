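import numpy as np
import pytest

from geotax.genomes import ProteomeRecord
from geotax.phylo import (
    check_monophyly,
    concatenate_markers,
    consensus_reassignment,
    extract_markers,
    nj_tree,
    read_newick,
    write_newick,
)

from oracles import monophyletic_dendropy, random_unrooted_tree


def _tree_distance(tree, a, b):
    return tree.find(a).distance(tree.find(b))


def _splits(tree):
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        out.add(min(side, leaves - side, key=sorted))
    return {s for s in out if 1 < len(s) < len(leaves) - 1}


def _additive_matrix(newick, labels):
    t = read_newick(newick)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            d[i, j] = d[j, i] = _tree_distance(t, labels[i], labels[j])
    return d


class TestNJ:
    def test_three_taxa_exact_branch_lengths(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
        tree = nj_tree(d, labels)
        # three-point equations: a = (dAB + dAC - dBC)/2, etc.
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("B").length == pytest.approx(2.0)
        assert tree.find("C").length == pytest.approx(4.0)

    def test_four_taxon_additive_split_and_lengths(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4))
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(d, labels)
        assert _splits(tree) == {frozenset({"A", "B"})}
        for i, a in enumerate(labels):
            for j in range(i):
                assert _tree_distance(tree, a, labels[j]) == pytest.approx(d[i, j])

    def test_recovers_random_additive_trees(self, rng):
        """NJ is consistent on additive data: 20 random 8-taxon matrices."""
        labels = [f"T{i}" for i in range(8)]
        for _ in range(20):
            true = read_newick(random_unrooted_tree(labels, rng))
            d = np.zeros((8, 8))
            for i in range(8):
                for j in range(i):
                    d[i, j] = d[j, i] = _tree_distance(true, labels[i], labels[j])
            est = nj_tree(d, labels)
            assert _splits(est) == _splits(true)
            for i in range(8):
                for j in range(i):
                    assert _tree_distance(est, labels[i], labels[j]) == pytest.approx(
                        d[i, j], abs=1e-9
                    )

    def test_topology_agrees_with_reference_implementation(self, rng):
        """Cross-check against scikit-bio's independent NJ on a noisy matrix."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels = [f"T{i}" for i in range(7)]
        true = read_newick(random_unrooted_tree(labels, rng))
        d = np.zeros((7, 7))
        for i in range(7):
            for j in range(i):
                d[i, j] = d[j, i] = _tree_distance(true, labels[i], labels[j]) + rng.uniform(0, 0.01)
        ours = nj_tree(d, labels)
        theirs = skbio_nj(DistanceMatrix(d, labels))
        assert _splits(ours) == _splits(theirs)

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1, 2], [1.1, 0, 1], [2, 1, 0]]), ["a", "b", "c"])

    def test_negative_branches_clamped(self):
        d = np.array(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0]], dtype=float
        )
        tree = nj_tree(d, ["a", "b", "c", "d"])
        assert all((t.length or 0) >= 0 for t in tree.traverse())


class TestNewickIO:
    def test_round_trip(self, tmp_path):
        tree = read_newick("(A:1.0,(B:1.0,C:1.0):1.0);")
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = read_newick(p)
        assert {t.name for t in back.tips()} == {"A", "B", "C"}
        assert back.find("B").length == 1.0

    def test_support_values_preserved(self, tmp_path):
        tree = read_newick("((A:1,B:1)95:0.1,(C:1,D:1)80:0.2);")
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        assert "95" in p.read_text()

    def test_malformed_rejected(self):
        with pytest.raises(Exception):
            read_newick("((A,B)")

    def test_duplicate_leaves_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("(A:1,(A:1,C:1):1);")


class TestMonophyly:
    def test_single_label_is_monophyletic(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        v = check_monophyly(tree, {x: "G" for x in "ABCD"})
        assert v["G"].monophyletic

    def test_hand_built_example(self):
        tree = read_newick("((A1:1,A2:1):1,(B1:1,(B2:1,C1:1):1):1);")
        lab = {"A1": "A", "A2": "A", "B1": "B", "B2": "B", "C1": "C"}
        v = check_monophyly(tree, lab)
        assert v["A"].monophyletic and v["C"].monophyletic
        assert not v["B"].monophyletic
        assert v["B"].blocking_leaves == ["C1"]

    def test_unlabeled_leaf_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="unlabeled"):
            check_monophyly(tree, {"A": "x", "B": "x"})

    def test_matches_exhaustive_oracle_on_random_trees(self, rng):
        """Verdicts equal an independent rooted-MRCA oracle on 50 random trees."""
        labels = [f"L{i}" for i in range(10)]
        for _ in range(50):
            newick = random_unrooted_tree(labels, rng)
            tree = read_newick(newick)
            genera = {x: f"g{rng.integers(3)}" for x in labels}
            verdicts = check_monophyly(tree, genera)
            for genus, v in verdicts.items():
                members = {x for x in labels if genera[x] == genus}
                assert v.monophyletic == monophyletic_dendropy(newick, members), (
                    newick,
                    genus,
                    members,
                )

    def test_invariant_under_rerooting(self, rng):
        labels = [f"L{i}" for i in range(8)]
        newick = random_unrooted_tree(labels, rng)
        tree = read_newick(newick)
        genera = {x: ("g1" if i < 4 else "g2") for i, x in enumerate(labels)}
        base = {g: v.monophyletic for g, v in check_monophyly(tree, genera).items()}
        rerooted = tree.root_at(tree.find("L3").parent)
        after = {g: v.monophyletic for g, v in check_monophyly(rerooted, genera).items()}
        assert base == after


class TestMarkers:
    def _queries(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        return {m: "".join(rng.choice(aa, size=160)) for m in ("fusA", "gyrB", "recA", "rpoB")}

    def test_exact_copy_found(self, rng):
        q = self._queries(rng)
        prot = ProteomeRecord("g", {"p1": q["fusA"], "p2": "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150))})
        ms = extract_markers(prot, q)
        assert ms.markers.get("fusA") == q["fusA"]
        assert "rpoB" in ms.missing

    def test_paralogs_resolved_by_score(self, rng):
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        q = self._queries(rng)
        near = list(q["fusA"])
        for pos in rng.choice(160, size=8, replace=False):
            near[pos] = rng.choice([x for x in aa if x != near[pos]])
        far = list(q["fusA"])
        for pos in rng.choice(160, size=48, replace=False):
            far[pos] = rng.choice([x for x in aa if x != far[pos]])
        prot = ProteomeRecord("g", {"near": "".join(near), "far": "".join(far)})
        ms = extract_markers(prot, {"fusA": q["fusA"]})
        assert ms.markers["fusA"] == "".join(near)

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            extract_markers(ProteomeRecord("g", {"p": "MKV"}), {})


class TestConcatenation:
    def test_published_block_ranges(self):
        """Blocks 196/295/225/200 concatenate to 916 columns with the standard ranges."""
        genomes = ["g1", "g2"]
        widths = {"fusA": 196, "gyrB": 295, "recA": 225, "rpoB": 200}
        blocks = {
            m: {g: "A" * w for g in genomes} for m, w in widths.items()
        }
        rows, ranges = concatenate_markers(blocks)
        assert len(rows["g1"]) == 916
        assert ranges == {
            "fusA": (1, 196),
            "gyrB": (197, 491),
            "recA": (492, 716),
            "rpoB": (717, 916),
        }

    def test_single_marker_identity(self):
        blocks = {"fusA": {"g1": "MKVL", "g2": "MKIL"}}
        rows, ranges = concatenate_markers(blocks)
        assert rows == blocks["fusA"]
        assert ranges == {"fusA": (1, 4)}

    def test_missing_marker_excludes_genome_with_warning(self):
        blocks = {
            "fusA": {"g1": "MKVL", "g2": "MKIL"},
            "gyrB": {"g1": "AAAA"},
        }
        with pytest.warns(UserWarning, match="g2"):
            rows, _ = concatenate_markers(blocks)
        assert set(rows) == {"g1"}

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            concatenate_markers({"fusA": {"g1": "MKVL", "g2": "MKV"}})


class TestConsensusReassignment:
    def test_consistent_collection_is_fixed_point(self):
        tree = read_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        genus = {"A1": "GA", "A2": "GA", "B1": "GB", "B2": "GB"}
        clusters = {"A1": 1, "A2": 1, "B1": 2, "B2": 2}
        props = consensus_reassignment(clusters, tree, genus)
        assert all(p.proposal == "keep" for p in props)

    def test_isolated_strain_proposed_as_novel_genus(self):
        # one nominal genus member on its own branch and own cluster
        tree = read_newick("((A1:1,A2:1):1,(X:1,(B1:1,B2:1):1):1);")
        genus = {"A1": "GA", "A2": "GA", "B1": "GB", "B2": "GB", "X": "GB"}
        clusters = {"A1": 1, "A2": 1, "B1": 2, "B2": 2, "X": 3}
        props = {p.genome_id: p.proposal for p in consensus_reassignment(clusters, tree, genus)}
        assert props["X"] == "novel_genus"
        assert all(v == "keep" for g, v in props.items() if g != "X")

    def test_nested_genus_proposed_for_family_transfer(self):
        """A small monophyletic genus inside the other family's branch moves there."""
        tree = read_newick(
            "(((B1:1,B2:1,B3:1):1,(O1:1,O2:1):1):1,"
            "((C1:1,C2:1,C3:1):1,(A1:1,A2:1,A3:1):1):1);"
        )
        genus = {f"{g}{i}": f"G{g}" for g in "ABC" for i in (1, 2, 3)}
        genus |= {"O1": "GO", "O2": "GO"}
        fam = {"GA": "F1", "GO": "F1", "GB": "F2", "GC": "F2"}
        clusters = {}
        for ci, (g, n) in enumerate([("A", 3), ("B", 3), ("C", 3), ("O", 2)]):
            for i in range(1, n + 1):
                clusters[f"{g}{i}"] = ci + 1
        props = {p.genome_id: p.proposal
                 for p in consensus_reassignment(clusters, tree, genus, fam)}
        assert props["O1"] == props["O2"] == "transfer:F2"
        assert all(v == "keep" for g, v in props.items() if not g.startswith("O"))

    def test_split_genus_surfaces_conflict(self):
        tree = read_newick("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        genus = {"A1": "GA", "A2": "GA", "B1": "GB", "B2": "GB"}
        clusters = {"A1": 1, "B1": 1, "A2": 2, "B2": 2}
        props = consensus_reassignment(clusters, tree, genus)
        assert all(p.proposal == "conflict" for p in props)

    def test_label_leaf_mismatch_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError):
            consensus_reassignment({"A": 1, "B": 1}, tree, {"A": "g", "B": "g", "C": "g"})
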