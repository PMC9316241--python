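"""Neighbour-joining against closed forms, topology-enumeration oracles and
an independent library implementation."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from retidiv import distance_matrix, neighbor_joining, species_monophyly
from retidiv.distance import DistanceMatrix


def tree_splits(tree):
    """Nontrivial bipartitions of an unrooted tree, as frozensets of the
    smaller-or-canonical side."""
    leaves = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(leaves) - 1:
            splits.add(min(s, leaves - s, key=lambda x: (len(x), sorted(x))))
    return splits


def path_distance_matrix(edges, leaves):
    """Distances on an explicit weighted tree (edge list) — brute-force oracle."""
    import networkx as nx

    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    n = len(leaves)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = nx.shortest_path_length(g, leaves[i], leaves[j], weight="weight")
        m[i, j] = m[j, i] = d
    return DistanceMatrix(tuple(leaves), m)


def quartet_split(dm, quartet):
    """Four-point condition: the pairing with the smallest sum is the split."""
    a, b, c, d = quartet
    sums = {
        frozenset([frozenset([a, b]), frozenset([c, d])]): dm[a, b] + dm[c, d],
        frozenset([frozenset([a, c]), frozenset([b, d])]): dm[a, c] + dm[b, d],
        frozenset([frozenset([a, d]), frozenset([b, c])]): dm[a, d] + dm[b, c],
    }
    return min(sums, key=sums.get)


def enumerate_five_taxon_topologies(taxa):
    """All 15 unrooted binary 5-leaf trees as pairs of disjoint cherry splits."""
    out = []
    for pair1 in itertools.combinations(taxa, 2):
        rest = [t for t in taxa if t not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            key = frozenset([frozenset(pair1), frozenset(pair2)])
            if key not in [frozenset(t) for t in out]:
                out.append((frozenset(pair1), frozenset(pair2)))
    # deduplicate unordered pairs
    return list({frozenset([a, b]): (a, b) for a, b in out}.values())


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        )
        tree = neighbor_joining(dm)
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})

    def test_four_taxon_additive_recovery(self):
        # tree ((a,b),(c,d)) with internal edge 0.07
        edges = [
            ("a", "u", 0.02), ("b", "u", 0.05), ("u", "v", 0.07),
            ("c", "v", 0.03), ("d", "v", 0.09),
        ]
        dm = path_distance_matrix(edges, ["a", "b", "c", "d"])
        # oracle: four-point condition picks ab|cd among the 3 topologies
        expected = quartet_split(dm, ("a", "b", "c", "d"))
        assert frozenset([frozenset("ab"), frozenset("cd")]) == expected
        tree = neighbor_joining(dm)
        assert tree_splits(tree) == {frozenset("ab")} or tree_splits(tree) == {
            frozenset("cd")
        }

    def test_five_taxon_additive_recovery_by_enumeration(self):
        # caterpillar: cherries (a,b) and (d,e), c off the middle
        edges = [
            ("a", "u", 0.01), ("b", "u", 0.04), ("u", "w", 0.06),
            ("c", "w", 0.02), ("w", "v", 0.05), ("d", "v", 0.03),
            ("e", "v", 0.08),
        ]
        taxa = ["a", "b", "c", "d", "e"]
        dm = path_distance_matrix(edges, taxa)
        # oracle: the unique topology whose induced quartet splits match the
        # four-point splits of every quartet
        observed_quartets = {
            q: quartet_split(dm, q) for q in itertools.combinations(taxa, 4)
        }
        compatible = []
        for cherry1, cherry2 in enumerate_five_taxon_topologies(taxa):
            ok = True
            for q, split in observed_quartets.items():
                for cherry in (cherry1, cherry2):
                    if cherry <= set(q):
                        other = frozenset(set(q) - cherry)
                        if frozenset([cherry, other]) != split:
                            ok = False
            if ok:
                compatible.append({cherry1, cherry2})
        assert compatible == [{frozenset("ab"), frozenset("de")}]
        tree = neighbor_joining(dm)
        leaves = frozenset(taxa)
        norm = {
            min(s, leaves - s, key=lambda x: (len(x), sorted(x)))
            for s in (frozenset("ab"), frozenset("de"))
        }
        assert tree_splits(tree) == norm
        # additive input: the tree's path metric reproduces the input exactly
        tip_a = tree.find("a")
        assert tip_a.distance(tree.find("b")) == pytest.approx(dm["a", "b"])
        assert tip_a.distance(tree.find("e")) == pytest.approx(dm["a", "e"])

    def test_matches_independent_library_topology(self, small_panel):
        records = small_panel.all_records()
        dm = distance_matrix(records)
        ours = neighbor_joining(dm)
        theirs = skbio_nj(SkbioDM(dm.values, ids=list(dm.ids)))
        assert tree_splits(ours) == tree_splits(theirs)

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValueError, match=">= 3"):
            neighbor_joining(dm)

    def test_saturated_entries_rejected_listing_pairs(self):
        m = np.array([[0, 0.1, np.inf], [0.1, 0, 0.2], [np.inf, 0.2, 0]])
        dm = DistanceMatrix(("a", "b", "c"), m)
        with pytest.raises(ValueError, match="a.*c"):
            neighbor_joining(dm)


class TestSpeciesMonophyly:
    def _tree(self, newick):
        from io import StringIO
        from skbio import TreeNode

        return TreeNode.read(StringIO(newick))

    def test_clean_two_species_tree(self):
        tree = self._tree("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert species_monophyly(tree, labels) == {"A": True, "B": True}

    def test_interleaved_species_both_fail(self):
        tree = self._tree("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        assert species_monophyly(tree, labels) == {"A": False, "B": False}

    def test_unlabeled_leaf_rejected(self):
        tree = self._tree("((a1:1,a2:1):1,b1:1);")
        with pytest.raises(ValueError, match="unlabeled"):
            species_monophyly(tree, {"a1": "A", "a2": "A"})

    def test_simulated_panel_species_all_monophyletic(self, small_panel):
        records = small_panel.all_records()
        tree = neighbor_joining(distance_matrix(records))
        labels = {r.id: r.label for r in records}
        result = species_monophyly(tree, labels)
        assert all(result.values()) and len(result) == 3
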