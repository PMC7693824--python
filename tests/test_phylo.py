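"""Distance matrices, UPGMA/NJ trees, monophyly, Newick round-trip."""

import numpy as np
import pytest

import ocellatin as oc
from ocellatin.datasets import Group, PeptideRecord
from ocellatin.phylo import from_newick, leaf_depths, leaf_names, tree_distance


def _records(named_seqs):
    return [
        PeptideRecord(name=n, sequence=s, amidated=True, group=Group.novel)
        for n, s in named_seqs
    ]


@pytest.fixture(scope="module")
def family_tree(family):
    return oc.build_tree(oc.distance_matrix(family), method="upgma")


def test_distance_matrix_properties(family):
    dm = oc.distance_matrix(family[:6])
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0.0)
    assert (dm.d >= 0).all()


def test_identical_pair_distance_zero():
    dm = oc.distance_matrix(
        _records([("a", "GVLDIF"), ("b", "GVLDIF"), ("c", "AAAAAA")])
    )
    assert dm.d[dm.labels.index("a"), dm.labels.index("b")] == 0.0


def test_published_identity_transforms_to_distance(by_name):
    dm = oc.distance_matrix(
        [by_name["ocellatin-11"], by_name["ocellatin-2"], by_name["ocellatin-3"]]
    )
    i, j = dm.labels.index("ocellatin-11"), dm.labels.index("ocellatin-2")
    assert dm.d[i, j] == pytest.approx(1 - 20 / 21)


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        oc.distance_matrix(
            _records([("a", "GVLDIF"), ("a", "GVLDIW"), ("c", "AAAAAA")])
        )


def test_close_pair_becomes_sisters():
    recs = _records(
        [("A", "GVLDILKDVGKGLLSHF"), ("B", "GVLDILKDVGKGLLSHW"),
         ("C", "WWPWYPWHPWYPWHPYW")]
    )
    tree = oc.build_tree(oc.distance_matrix(recs), method="upgma")
    assert oc.is_monophyletic(tree, ["A", "B"])


def test_family_cladogram_clusters(family_tree):
    """The similarity cladogram groups oc-10 with oc-6, and oc-9/-7/-8/-5
    as a sister cluster, as observed for the L. latrans peptides."""
    assert oc.is_monophyletic(family_tree, ["ocellatin-10", "ocellatin-6"])
    assert oc.is_monophyletic(
        family_tree,
        ["ocellatin-9", "ocellatin-7", "ocellatin-8", "ocellatin-5"],
    )
    assert oc.is_monophyletic(
        family_tree, ["ocellatin-11", "ocellatin-2", "ocellatin-3"]
    )


def test_upgma_is_ultrametric(family_tree):
    depths = leaf_depths(family_tree).values()
    assert max(depths) - min(depths) < 1e-9


def test_leaf_set_preserved(family, family_tree):
    assert leaf_names(family_tree) == {r.name for r in family}


def test_monophyly_trivial_cases(family_tree, family):
    assert oc.is_monophyletic(family_tree, [r.name for r in family])
    assert oc.is_monophyletic(family_tree, ["ocellatin-4"])
    with pytest.raises(KeyError):
        oc.is_monophyletic(family_tree, ["no-such-peptide"])


def test_nj_recovers_additive_tree():
    """NJ must exactly reconstruct distances that are additive on a tree.

    The 6-leaf tree and its path-length matrix are built by hand:
    ((A:1,B:2):1,(C:1,(D:2,E:1):2):1,F:4) with the listed branch lengths.
    """
    labels = ["A", "B", "C", "D", "E", "F"]
    # adjacency of the unrooted tree; internal nodes X (AB), Y (CDE-root), Z (DE)
    edges = {
        ("A", "X"): 1.0, ("B", "X"): 2.0, ("X", "R"): 1.0,
        ("C", "Y"): 1.0, ("Z", "Y"): 2.0, ("D", "Z"): 2.0, ("E", "Z"): 1.0,
        ("Y", "R"): 1.0, ("F", "R"): 4.0,
    }
    graph: dict[str, dict[str, float]] = {}
    for (u, v), w in edges.items():
        graph.setdefault(u, {})[v] = w
        graph.setdefault(v, {})[u] = w

    def path_length(src, dst):  # brute-force DFS oracle on the known tree
        stack = [(src, 0.0, {src})]
        while stack:
            node, dist, seen = stack.pop()
            if node == dst:
                return dist
            for nxt, w in graph[node].items():
                if nxt not in seen:
                    stack.append((nxt, dist + w, seen | {nxt}))
        raise AssertionError("disconnected")

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = path_length(labels[i], labels[j])
    dm = oc.DistanceMatrix(labels=tuple(labels), d=d)
    tree = oc.build_tree(dm, method="nj")
    for i in range(n):
        for j in range(i + 1, n):
            assert tree_distance(tree, labels[i], labels[j]) == pytest.approx(
                d[i, j], abs=1e-9
            )


def test_newick_round_trip(family_tree, family):
    text = oc.to_newick(family_tree)
    reread = from_newick(text)
    assert leaf_names(reread) == {r.name for r in family}
    for a, b in [("ocellatin-10", "ocellatin-6"), ("ocellatin-11", "ocellatin-4")]:
        assert tree_distance(reread, a, b) == pytest.approx(
            tree_distance(family_tree, a, b), abs=1e-6
        )
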