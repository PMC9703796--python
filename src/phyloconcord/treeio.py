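"""Phylogenetic tree data model and topology primitives.

The package's universal tree currency is :class:`PhyloTree`, a light rooted
node structure with optional branch lengths and internal support labels.
Newick text is parsed through dendropy and converted; serialization is a
deterministic custom writer (children sorted by smallest descendant leaf
name) so identical trees always produce identical text.

All topology comparison is done on *bipartitions* — the two leaf sets
separated by an internal edge of the unrooted tree.  Robinson–Foulds
distance, concordance classification and the greedy consensus estimator are
all built on :class:`Bipartition`.
"""

from __future__ import annotations

import gzip
import io
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "TreeNode",
    "PhyloTree",
    "Bipartition",
    "GeneTreeSet",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "bipartitions",
    "rf_distance",
    "restrict",
    "mean_support",
    "greedy_consensus",
]


class NewickParseError(ValueError):
    """Malformed Newick input."""


class TreeValidationError(ValueError):
    """Structurally invalid tree or incompatible arguments."""


class TreeNode:
    """A node of a rooted tree.

    ``label`` on an internal node is interpreted as a support value when it
    parses as a number; non-numeric labels are preserved verbatim but never
    enter support statistics.
    """

    __slots__ = ("name", "length", "label", "children")

    def __init__(self, name=None, length=None, label=None, children=None):
        self.name: str | None = name
        self.length: float | None = length
        self.label: str | None = label
        self.children: list[TreeNode] = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def support(self) -> float | None:
        """Numeric value of the label, or None."""
        if self.label is None:
            return None
        try:
            return float(self.label)
        except ValueError:
            return None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = self.name if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {kind}>"


class PhyloTree:
    """Rooted (or root-agnostic) tree with named leaves.

    Leaf names must be unique, non-empty strings; branch lengths, when
    present, must be >= 0.  The tree is treated as unrooted by every
    comparison operation (bipartitions, RF), per the package convention.
    """

    def __init__(self, root: TreeNode, rooted: bool | None = None):
        self.root = root
        self.rooted = rooted if rooted is not None else len(root.children) == 2
        self._validate()

    # -- construction / validation -------------------------------------

    def _validate(self) -> None:
        names = [n.name for n in self.leaves()]
        if any(not n for n in names):
            raise TreeValidationError("leaf with empty or missing name")
        if len(set(names)) != len(names):
            dup = sorted(n for n, c in Counter(names).items() if c > 1)
            raise TreeValidationError(f"duplicate leaf name(s): {', '.join(dup)}")
        for node in self.iter_nodes():
            if node.length is not None and (node.length < 0 or math.isnan(node.length)):
                raise TreeValidationError(f"negative or NaN branch length {node.length!r}")

    # -- traversal ------------------------------------------------------

    def iter_nodes(self) -> Iterator[TreeNode]:
        """Preorder traversal (root first)."""
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self, exclude_root: bool = True) -> list[TreeNode]:
        nodes = [n for n in self.iter_nodes() if not n.is_leaf]
        if exclude_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def copy(self) -> "PhyloTree":
        def _copy(node: TreeNode) -> TreeNode:
            return TreeNode(node.name, node.length, node.label, [_copy(c) for c in node.children])

        return PhyloTree(_copy(self.root), rooted=self.rooted)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_leaves} leaves>"

    # convenience mirrors of the module-level operations
    def newick(self) -> str:
        return write_newick(self)

    def bipartitions(self) -> frozenset["Bipartition"]:
        return bipartitions(self)


@dataclass(frozen=True)
class Bipartition:
    """Canonicalized two-sided split of a taxon set.

    ``{X|Y}`` equals ``{Y|X}``; equality and hashing ignore side order.
    """

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self):
        if not self.side_a or not self.side_b:
            raise TreeValidationError("bipartition sides must be non-empty")
        if self.side_a & self.side_b:
            raise TreeValidationError("bipartition sides must be disjoint")
        # canonical internal order: side containing the overall min taxon first
        a, b = self.side_a, self.side_b
        if min(a) > min(b):
            a, b = b, a
        object.__setattr__(self, "side_a", frozenset(a))
        object.__setattr__(self, "side_b", frozenset(b))

    @property
    def universe(self) -> frozenset[str]:
        return self.side_a | self.side_b

    @property
    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) < 2

    def restrict(self, taxa: Iterable[str]) -> "Bipartition | None":
        """Induced split on a taxon subset, or None if a side collapses
        below two taxa (the split carries no information there)."""
        taxa = frozenset(taxa)
        a = self.side_a & taxa
        b = self.side_b & taxa
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition(a, b)

    def is_compatible_with(self, other: "Bipartition") -> bool:
        """Two splits are compatible iff at least one of the four pairwise
        side intersections is empty (they can coexist in one tree)."""
        for x in (self.side_a, self.side_b):
            for y in (other.side_a, other.side_b):
                if not (x & y):
                    return True
        return False

    def canonical_str(self) -> str:
        sa = ",".join(sorted(self.side_a))
        sb = ",".join(sorted(self.side_b))
        # smaller side first; ties by string
        ka = (len(self.side_a), sa)
        kb = (len(self.side_b), sb)
        if kb < ka:
            sa, sb = sb, sa
        return f"{sa}|{sb}"

    def __str__(self) -> str:
        return self.canonical_str()


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced parenthesis: unexpected ')' at character offset {offset}"
                )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open (input length {len(text)})"
        )


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Internal node labels are kept as labels (numeric ones double as support
    values); branch lengths attach to the edge above each node.
    """
    if text is None or not text.strip():
        raise NewickParseError("empty Newick input")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick statement must end with ';'")
    _check_parentheses(stripped)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"Newick parse failed: {exc}") from None

    def _convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return TreeNode(name=name, length=dnode.edge.length)
        children = [_convert(c) for c in dnode.child_nodes()]
        return TreeNode(label=dnode.label, length=dnode.edge.length, children=children)

    root = _convert(dtree.seed_node)
    return PhyloTree(root)


def _format_length(x: float) -> str:
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


_NEWICK_SPECIAL = set(" (),:;[]'\t\n")


def _quote_name(name: str) -> str:
    if any(c in _NEWICK_SPECIAL for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _min_leaf(node: TreeNode) -> str:
    if node.is_leaf:
        return node.name
    return min(_min_leaf(c) for c in node.children)


def _write_node(node: TreeNode, out: list[str]) -> str:
    """Append node's Newick to ``out``; return its smallest leaf name."""
    if node.is_leaf:
        out.append(_quote_name(node.name))
        key = node.name
    else:
        parts = []
        for child in node.children:
            buf: list[str] = []
            k = _write_node(child, buf)
            parts.append((k, "".join(buf)))
        parts.sort(key=lambda p: p[0])
        out.append("(" + ",".join(p[1] for p in parts) + ")")
        if node.label is not None:
            out.append(_quote_name(str(node.label)))
        key = parts[0][0]
    if node.length is not None:
        out.append(":" + _format_length(node.length))
    return key


def write_newick(tree: PhyloTree) -> str:
    """Serialize deterministically: children sorted by smallest leaf name."""
    out: list[str] = []
    _write_node(tree.root, out)
    return "".join(out) + ";"


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_newick_file(path) -> list[PhyloTree]:
    """Read one tree per non-empty line; gzip transparently accepted."""
    trees = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(path, trees: Iterable[PhyloTree]) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# Topology primitives
# ---------------------------------------------------------------------------


def bipartitions(tree: PhyloTree) -> frozenset[Bipartition]:
    """Non-trivial bipartitions of the unrooted version of ``tree``.

    One split per internal edge; the two edges meeting at a bifurcating
    root induce the same split and are deduplicated.  Trees with fewer than
    four leaves have no non-trivial splits.
    """
    universe = tree.taxa
    n = len(universe)
    if n < 4:
        return frozenset()
    splits: set[Bipartition] = set()
    clades: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            clades[id(node)] = frozenset((node.name,))
            continue
        clade = frozenset().union(*(clades[id(c)] for c in node.children))
        clades[id(node)] = clade
        if node is tree.root:
            continue
        if 2 <= len(clade) <= n - 2:
            splits.add(Bipartition(clade, universe - clade))
    return frozenset(splits)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Unweighted Robinson–Foulds distance.

    Returns ``(raw, normalized)`` where raw is the size of the symmetric
    difference of the two non-trivial bipartition sets and normalized is
    raw / (|B1| + |B2|), taken as 0.0 when both sets are empty.
    """
    if t1.taxa != t2.taxa:
        raise TreeValidationError(
            "trees have different leaf sets; restrict() both to the shared taxa first"
        )
    b1 = bipartitions(t1)
    b2 = bipartitions(t2)
    raw = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    return raw, (raw / denom if denom else 0.0)


def restrict(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``taxa``.

    Degree-2 nodes arising from the pruning are suppressed: branch lengths
    along the suppressed path are summed and the retained edge keeps the
    larger of the two numeric supports (conservative).
    """
    taxa = frozenset(taxa)
    missing = taxa - tree.taxa
    if missing:
        raise TreeValidationError(f"taxa not in tree: {', '.join(sorted(missing))}")
    if len(taxa) < 2:
        raise TreeValidationError("restriction needs at least 2 taxa")

    def _merge_len(a: float | None, b: float | None) -> float | None:
        if a is None and b is None:
            return None
        return (a or 0.0) + (b or 0.0)

    def _merge_label(outer: TreeNode, inner: TreeNode) -> str | None:
        so, si = outer.support, inner.support
        if so is not None and si is not None:
            return outer.label if so >= si else inner.label
        if si is not None:
            return inner.label
        if so is not None:
            return outer.label
        return inner.label if inner.label is not None else outer.label

    def _restrict(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            if node.name in taxa:
                return TreeNode(node.name, node.length)
            return None
        kept = [r for r in (_restrict(c) for c in node.children) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            shell = TreeNode(label=node.label, length=node.length)
            child.length = _merge_len(shell.length, child.length)
            if not child.is_leaf:
                child.label = _merge_label(shell, child)
            return child
        return TreeNode(label=node.label, length=node.length, children=kept)

    root = _restrict(tree.root)
    assert root is not None
    if not root.is_leaf:
        root.length = None  # stem above the restricted root is meaningless
    return PhyloTree(root, rooted=tree.rooted)


def mean_support(tree: PhyloTree) -> float | None:
    """Mean of numeric support labels over internal edges; None if no
    internal edge carries a numeric label."""
    vals = [n.support for n in tree.internal_nodes() if n.support is not None]
    if not vals:
        return None
    return sum(vals) / len(vals)


def greedy_consensus(trees: "GeneTreeSet | Sequence[PhyloTree]") -> PhyloTree:
    """Greedy (majority-rule extended) consensus.

    Bipartitions are added in decreasing frequency (ties broken by the
    canonical split string) while mutually compatible; the returned tree
    displays every accepted split, with the split's percent frequency as
    its support label.
    """
    tree_list = list(trees)
    if not tree_list:
        raise TreeValidationError("cannot take consensus of an empty tree set")
    taxa = tree_list[0].taxa
    for t in tree_list[1:]:
        if t.taxa != taxa:
            raise TreeValidationError("all trees must share one leaf set")

    counts: Counter[Bipartition] = Counter()
    for t in tree_list:
        counts.update(bipartitions(t))
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].canonical_str()))
    accepted: list[tuple[Bipartition, int]] = []
    for split, cnt in ordered:
        if all(split.is_compatible_with(s) for s, _ in accepted):
            accepted.append((split, cnt))

    # Build the tree: treat each split's side *not* containing the anchor
    # taxon as a clade; compatible splits give a laminar clade family.
    anchor = min(taxa)
    root = TreeNode(children=[TreeNode(name=t) for t in sorted(taxa)])
    n_total = len(tree_list)

    def _leafset(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset((node.name,))
        return frozenset().union(*(_leafset(c) for c in node.children))

    clades = []
    for split, cnt in accepted:
        clade = split.side_b if anchor in split.side_a else split.side_a
        clades.append((clade, cnt))
    clades.sort(key=lambda c: -len(c[0]))

    for clade, cnt in clades:
        # find the deepest node whose leafset contains the clade
        host = root
        while True:
            nxt = next(
                (c for c in host.children if not c.is_leaf and clade <= _leafset(c)),
                None,
            )
            if nxt is None:
                break
            host = nxt
        grouped = [c for c in host.children if _leafset(c) <= clade]
        rest = [c for c in host.children if not (_leafset(c) <= clade)]
        label = _format_length(round(100.0 * cnt / n_total, 6))
        host.children = rest + [TreeNode(label=label, children=grouped)]

    return PhyloTree(root, rooted=False)


# ---------------------------------------------------------------------------
# Gene-tree collections
# ---------------------------------------------------------------------------


@dataclass
class GeneTreeSet:
    """Ordered collection of gene trees with per-tree id and metadata."""

    trees: list[PhyloTree]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            self.ids = [f"g{i + 1:05d}" for i in range(len(self.trees))]
        if len(self.ids) != len(self.trees):
            raise TreeValidationError("ids and trees must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise TreeValidationError("gene tree ids must be unique")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]

    def mean_supports(self) -> list[float | None]:
        return [mean_support(t) for t in self.trees]

    @classmethod
    def from_newick_file(cls, path) -> "GeneTreeSet":
        return cls(read_newick_file(path))

    def write(self, path) -> None:
        write_newick_file(path, self.trees)
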