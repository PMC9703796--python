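import numpy as np
import pytest

from phyloconcord.treeio import PhyloTree, TreeNode, parse_newick


def random_binary_tree(taxa, rng, with_lengths=True, with_supports=False):
    """Uniform-ish random binary tree built by sequential leaf insertion."""
    taxa = list(taxa)
    assert len(taxa) >= 2
    root = TreeNode(children=[TreeNode(name=taxa[0]), TreeNode(name=taxa[1])])
    edges = list(root.children)
    for name in taxa[2:]:
        target = edges[int(rng.integers(len(edges)))]
        moved = TreeNode(target.name, target.length, target.label, target.children)
        leaf = TreeNode(name=name)
        target.name, target.label, target.children = None, None, [moved, leaf]
        target.length = None
        edges.extend([moved, leaf])
    tree = PhyloTree(root, rooted=True)
    if with_lengths:
        for node in tree.iter_nodes():
            if node is not tree.root:
                node.length = float(np.round(rng.uniform(0.01, 3.0), 6))
    if with_supports:
        for node in tree.internal_nodes():
            node.label = str(int(rng.integers(0, 101)))
    return tree


def all_unrooted_binary_trees(taxa):
    """Every unrooted binary topology on ``taxa`` (3 leaves: 1; 6 leaves: 105),
    built by inserting each new leaf on every edge of every smaller tree."""
    taxa = list(taxa)

    def clone(node):
        return TreeNode(node.name, node.length, node.label, [clone(c) for c in node.children])

    def edges_of(root):
        out = []
        stack = [root]
        while stack:
            n = stack.pop()
            out.extend(n.children)
            stack.extend(n.children)
        return out

    base = TreeNode(children=[TreeNode(name=t) for t in taxa[:3]])
    trees = [base]
    for name in taxa[3:]:
        nxt = []
        for t in trees:
            for k in range(len(edges_of(t))):
                c = clone(t)
                target = edges_of(c)[k]
                moved = TreeNode(target.name, target.length, target.label, target.children)
                target.name, target.label = None, None
                target.children = [moved, TreeNode(name=name)]
                nxt.append(c)
        trees = nxt
    return [PhyloTree(t, rooted=False) for t in trees]


def brute_force_splits(tree):
    """Independent bipartition enumeration (no package topology code):
    walk the node structure collecting leaf sets."""
    leafsets = {}

    def walk(node):
        if not node.children:
            leafsets[id(node)] = frozenset([node.name])
        else:
            s = frozenset()
            for c in node.children:
                walk(c)
                s = s | leafsets[id(c)]
            leafsets[id(node)] = s
        return leafsets[id(node)]

    universe = walk(tree.root)
    splits = set()
    for key, clade in leafsets.items():
        if key == id(tree.root):
            continue
        if 2 <= len(clade) <= len(universe) - 2:
            splits.add(frozenset([clade, universe - clade]))
    return splits


def tip_depths(tree):
    out = {}

    def walk(node, d):
        if not node.children:
            out[node.name] = d
        for c in node.children:
            walk(c, d + (c.length or 0.0))

    walk(tree.root, 0.0)
    return out


def cherry(tree):
    """The 2-leaf clade of a 3-taxon rooted binary tree."""
    for c in tree.root.children:
        if c.children:
            return frozenset(l.name for l in PhyloTree(c, rooted=False).leaves())
    raise AssertionError("no cherry found")


@pytest.fixture(scope="session")
def balanced10():
    """Balanced 10-taxon ultrametric species tree, internal branches 2 CU."""
    return parse_newick(
        "(((A:2,B:2):2,(C:2,D:2):2):4,"
        "(((E:2,F:2):2,(G:2,H:2):2):2,(I:4,J:4):2):2);"
    )


@pytest.fixture(scope="session")
def species12():
    """12-taxon ultrametric species tree with every internal branch 5 CU."""
    return parse_newick(
        "((((A:5,B:5):5,C:10):5,((D:5,E:5):5,F:10):5):10,"
        "((((G:5,H:5):5,I:10):5,J:15):5,(K:15,L:15):5):5);"
    )
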