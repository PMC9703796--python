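"""Multispecies-coalescent gene-tree simulation on a species tree.

The species tree is a rooted, binary :class:`~phyloconcord.treeio.PhyloTree`
whose branch lengths are in *coalescent units*: time scaled so that k gene
lineages coalesce at rate k(k-1)/2 per unit.  Within each species-tree
branch, lineage pairs coalesce with exponential waiting times; lineages
that fail to coalesce enter the parent branch, and coalescence continues on
an unbounded stem above the root until a single lineage remains.  This is
the classical ILS null: short internal branches produce gene trees that
disagree with the species tree, without any gene flow.

Two extensions cover the study designs this package targets:

* **Hybridization edges** (:class:`HybridizationEvent`): at a given time, a
  lineage alive on the recipient edge jumps to the donor edge with
  inheritance probability ``gamma``; ``gamma = 0`` reduces exactly to the
  pure MSC, ``gamma = 1`` moves every lineage (introgression / capture).
* **Organelle sampling** (:func:`sample_organelle_tree`): a single gene
  tree simulated after multiplying all branch lengths (and event times) by
  a scale factor, default 4, reflecting the smaller effective size of a
  haploid, uniparentally inherited genome.  With a ``gamma = 1`` event this
  models chloroplast capture: the plastid tree shows the donor placement
  while nuclear gene trees do not.

Randomness comes from ``numpy.random.default_rng`` (PCG64).  Per-gene
substreams are derived from ``(seed, gene index)`` by fixed arithmetic so
any single replicate can be reproduced in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .treeio import GeneTreeSet, PhyloTree, TreeNode, TreeValidationError

__all__ = [
    "SimConfig",
    "HybridizationEvent",
    "validate_species_tree",
    "node_heights",
    "fill_terminal_lengths",
    "scale_tree",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "simulate_gene_tree_network",
    "sample_organelle_tree",
    "derive_seed",
    "read_event_table",
    "write_event_table",
]

_HEIGHT_RTOL = 1e-6


@dataclass
class SimConfig:
    """Replication settings for a simulation run."""

    n_genes: int
    seed: int
    samples_per_species: int = 1

    def __post_init__(self):
        if self.n_genes < 1:
            raise TreeValidationError("n_genes must be >= 1")
        if self.samples_per_species < 1:
            raise TreeValidationError("samples_per_species must be >= 1")


@dataclass(frozen=True)
class HybridizationEvent:
    """A pulse of gene flow from ``donor`` into ``recipient``.

    Edges are identified by the leaf set of the clade below them (a single
    taxon name, or an iterable of names).  ``time`` is measured from the
    present in coalescent units and must fall strictly inside both edges'
    time spans.  ``gamma`` is the probability that a lineage on the
    recipient edge at that time follows the donor edge backwards in time.
    """

    recipient: frozenset[str]
    donor: frozenset[str]
    time: float
    gamma: float

    def __post_init__(self):
        object.__setattr__(self, "recipient", _as_clade(self.recipient))
        object.__setattr__(self, "donor", _as_clade(self.donor))
        if not (0.0 <= self.gamma <= 1.0):
            raise TreeValidationError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.time <= 0:
            raise TreeValidationError("event time must be positive")


def _as_clade(x) -> frozenset[str]:
    if isinstance(x, str):
        return frozenset((x,))
    return frozenset(x)


# ---------------------------------------------------------------------------
# Species-tree validation and geometry
# ---------------------------------------------------------------------------


def validate_species_tree(tree: PhyloTree) -> None:
    """Require a rooted, binary tree with finite non-negative lengths on
    every non-root edge."""
    if len(tree.root.children) != 2:
        raise TreeValidationError("species tree must be rooted with a bifurcating root")
    for node in tree.iter_nodes():
        if node is tree.root:
            continue
        if not node.is_leaf and len(node.children) != 2:
            raise TreeValidationError("species tree must be fully binary")
        if node.length is None:
            raise TreeValidationError(
                "species tree branch without a length; supply terminal lengths "
                "explicitly (see fill_terminal_lengths) — no silent default is applied"
            )
        if not math.isfinite(node.length) or node.length < 0:
            raise TreeValidationError(f"invalid branch length {node.length!r}")


def node_heights(tree: PhyloTree) -> dict[int, float]:
    """Height (time before present) of every node, keyed by ``id(node)``.

    Leaves sit at height 0.  The two children of each internal node must
    imply the same height (the tree must be time-consistent / ultrametric
    in coalescent units); inconsistency raises.
    """
    heights: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            heights[id(node)] = 0.0
            continue
        implied = [heights[id(c)] + c.length for c in node.children]
        h = max(implied)
        tol = _HEIGHT_RTOL * max(1.0, h)
        if max(implied) - min(implied) > tol:
            raise TreeValidationError(
                "species tree is not time-consistent (tip-to-node depths disagree "
                f"by {max(implied) - min(implied):g}); the coalescent needs a common "
                "time scale — consider fill_terminal_lengths(..., mode='ultrametric')"
            )
        heights[id(node)] = h
    return heights


def fill_terminal_lengths(tree: PhyloTree, fill: float | None = None, mode: str = "constant") -> PhyloTree:
    """Assign lengths to terminal branches that lack them.

    mode='constant' sets every missing terminal length to ``fill``;
    mode='ultrametric' extends each terminal branch so that all tips reach
    the depth of the deepest tip path (``fill`` then is the minimum pendant
    length added, default 0).  Species trees from summary-coalescent
    methods carry internal lengths in coalescent units but no terminal
    lengths; the choice of fill is the caller's, never defaulted.
    """
    out = tree.copy()
    if mode == "constant":
        if fill is None or fill < 0:
            raise TreeValidationError("mode='constant' requires a non-negative fill value")
        for leaf in out.leaves():
            if leaf.length is None:
                leaf.length = float(fill)
        return out
    if mode != "ultrametric":
        raise TreeValidationError(f"unknown fill mode {mode!r}")
    pad = 0.0 if fill is None else float(fill)

    # depth of each node below the root, treating missing terminal lengths as 0
    depths: dict[int, float] = {id(out.root): 0.0}
    order = list(out.iter_nodes())
    parent = {}
    for node in order:
        for c in node.children:
            parent[id(c)] = node
    for node in order:
        if node is out.root:
            continue
        depths[id(node)] = depths[id(parent[id(node)])] + (node.length or 0.0)
    max_depth = max(depths[id(leaf)] for leaf in out.leaves()) + pad
    for leaf in out.leaves():
        base = depths[id(leaf)] - (leaf.length or 0.0)
        leaf.length = max_depth - base
    return out


def scale_tree(tree: PhyloTree, factor: float) -> PhyloTree:
    """Multiply every branch length by ``factor``."""
    if factor <= 0:
        raise TreeValidationError("scale factor must be positive")
    out = tree.copy()
    for node in out.iter_nodes():
        if node.length is not None:
            node.length = node.length * factor
    return out


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------


class _Branch:
    """A species-tree edge (identified by its child node) during simulation."""

    __slots__ = ("key", "lo", "hi", "lineages")

    def __init__(self, key: str, lo: float, hi: float):
        self.key = key          # canonical clade string, for deterministic ordering
        self.lo = lo            # height at the bottom of the edge
        self.hi = hi            # height at the top (parent node); inf for root stem
        self.lineages: list[tuple[TreeNode, float]] = []  # (gene node, node height)


def _resolve_edges(tree: PhyloTree, heights: dict[int, float]):
    """Map clade leaf-sets to (node, branch interval); include root stem."""
    clades: dict[int, frozenset[str]] = {}
    parent: dict[int, TreeNode] = {}
    for node in tree.postorder():
        if node.is_leaf:
            clades[id(node)] = frozenset((node.name,))
        else:
            clades[id(node)] = frozenset().union(*(clades[id(c)] for c in node.children))
        for c in node.children:
            parent[id(c)] = node
    edges = {}
    for node in tree.iter_nodes():
        lo = heights[id(node)]
        hi = math.inf if node is tree.root else heights[id(parent[id(node)])]
        edges[clades[id(node)]] = (node, lo, hi)
    return edges, clades, parent


def _coalesce_interval(
    branch: _Branch, start: float, end: float, rng: np.random.Generator
) -> None:
    """Run the coalescent in one branch over the height window [start, end)."""
    t = start
    while len(branch.lineages) >= 2:
        k = len(branch.lineages)
        w = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        if t + w >= end:
            return
        t += w
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        node_j = branch.lineages.pop(j)
        node_i = branch.lineages.pop(i)
        for child, h in (node_i, node_j):
            child.length = t - h
        branch.lineages.append((TreeNode(children=[node_i[0], node_j[0]]), t))


def simulate_gene_tree_network(
    species_tree: PhyloTree,
    events: Sequence[HybridizationEvent],
    seed: int | np.random.Generator,
    samples_per_species: int = 1,
) -> PhyloTree:
    """One gene tree under the MSC on a species tree with optional
    hybridization edges.  With ``events=[]`` this is the pure MSC."""
    validate_species_tree(species_tree)
    heights = node_heights(species_tree)
    edges, clades, parent = _resolve_edges(species_tree, heights)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    branches: dict[frozenset[str], _Branch] = {}
    for clade, (node, lo, hi) in edges.items():
        branches[clade] = _Branch(",".join(sorted(clade)), lo, hi)

    # seed one (or more) sampled lineages per species
    for leaf in species_tree.leaves():
        br = branches[frozenset((leaf.name,))]
        for s in range(samples_per_species):
            name = leaf.name if samples_per_species == 1 else f"{leaf.name}^{s + 1}"
            br.lineages.append((TreeNode(name=name), 0.0))

    # timeline: species-node merges and hybridization pulses
    timeline: list[tuple[float, int, object]] = []
    for node in species_tree.iter_nodes():
        if not node.is_leaf:
            timeline.append((heights[id(node)], 0, node))
    seen: set[tuple[frozenset, float]] = set()
    for ev in events:
        for side, name in ((ev.recipient, "recipient"), (ev.donor, "donor")):
            if side not in edges:
                raise TreeValidationError(
                    f"{name} clade {{{','.join(sorted(side))}}} is not an edge of the species tree"
                )
            _, lo, hi = edges[side]
            if not (lo < ev.time < hi):
                raise TreeValidationError(
                    f"event time {ev.time} outside the {name} edge's span ({lo:g}, {hi:g})"
                )
        key = (ev.recipient, ev.time)
        if key in seen:
            raise TreeValidationError(
                f"two events on the same recipient edge at the same time {ev.time}"
            )
        seen.add(key)
        timeline.append((ev.time, 1, ev))
    timeline.sort(key=lambda item: (item[0], item[1], _timeline_key(item[2], clades)))

    def run_window(t0: float, t1: float) -> None:
        # deterministic branch order keeps the RNG stream reproducible
        for br in sorted(branches.values(), key=lambda b: b.key):
            lo, hi = max(t0, br.lo), min(t1, br.hi)
            if lo < hi and len(br.lineages) >= 2:
                _coalesce_interval(br, lo, hi, rng)

    t = 0.0
    for when, _, payload in timeline:
        run_window(t, when)
        t = when
        if isinstance(payload, HybridizationEvent):
            src = branches[payload.recipient]
            dst = branches[payload.donor]
            staying = []
            for lin in src.lineages:
                if rng.random() < payload.gamma:
                    dst.lineages.append(lin)
                else:
                    staying.append(lin)
            src.lineages = staying
        else:  # species-node merge: children's lineages move into this node's edge
            node = payload
            target = branches[clades[id(node)]]
            for c in node.children:
                cb = branches[clades[id(c)]]
                target.lineages.extend(cb.lineages)
                cb.lineages = []

    root_branch = branches[clades[id(species_tree.root)]]
    _coalesce_interval(root_branch, t, math.inf, rng)
    (root_node, _), = root_branch.lineages
    return PhyloTree(root_node, rooted=True)


def _timeline_key(payload, clades) -> str:
    if isinstance(payload, HybridizationEvent):
        return ",".join(sorted(payload.recipient))
    return ",".join(sorted(clades[id(payload)]))


def simulate_gene_tree(species_tree: PhyloTree, seed: int | np.random.Generator,
                       samples_per_species: int = 1) -> PhyloTree:
    """One gene tree under the pure multispecies coalescent."""
    return simulate_gene_tree_network(species_tree, [], seed, samples_per_species)


def derive_seed(seed: int, index: int) -> int:
    """Deterministic substream seed for (seed, index), in [0, 2^31).

    Uses numpy's SeedSequence hashing so consecutive indices give
    statistically independent PCG64 streams.
    """
    return int(np.random.SeedSequence((int(seed), int(index))).generate_state(1)[0]) % (2**31)


def simulate_gene_trees(
    species_tree: PhyloTree,
    config: SimConfig,
    events: Sequence[HybridizationEvent] = (),
) -> GeneTreeSet:
    """``config.n_genes`` independent MSC replicates.

    Replicate k is simulated from ``derive_seed(config.seed, k)``, so any
    single gene tree can be regenerated in isolation.
    """
    trees = [
        simulate_gene_tree_network(
            species_tree, events, derive_seed(config.seed, k), config.samples_per_species
        )
        for k in range(config.n_genes)
    ]
    return GeneTreeSet(trees, [f"sim{k + 1:05d}" for k in range(config.n_genes)])


def sample_organelle_tree(
    species_tree: PhyloTree,
    events: Sequence[HybridizationEvent] = (),
    scale: float = 4.0,
    seed: int | np.random.Generator = 0,
) -> PhyloTree:
    """One organelle (plastid/mitochondrial) gene tree.

    All branch lengths and event times are multiplied by ``scale`` before
    simulation: a haploid, uniparentally inherited genome has roughly a
    quarter of the nuclear effective population size, so its coalescent-
    unit branches are longer and ILS is rarer.  At a hybridization event
    the single organelle lineage follows the donor with probability gamma
    (chloroplast capture when gamma is large).
    """
    if scale <= 0:
        raise TreeValidationError("scale must be positive")
    scaled = scale_tree(species_tree, scale)
    scaled_events = [
        HybridizationEvent(ev.recipient, ev.donor, ev.time * scale, ev.gamma)
        for ev in events
    ]
    return simulate_gene_tree_network(scaled, scaled_events, seed)


# ---------------------------------------------------------------------------
# Sidecar event table I/O (plain text: recipient, donor, time, gamma)
# ---------------------------------------------------------------------------


def read_event_table(path) -> list[HybridizationEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TreeValidationError(
                    "event table rows need 4 tab-separated fields: "
                    "recipient, donor, time, gamma"
                )
            rec, don, time, gamma = fields
            events.append(
                HybridizationEvent(
                    frozenset(rec.split(",")), frozenset(don.split(",")),
                    float(time), float(gamma),
                )
            )
    return events


def write_event_table(path, events: Iterable[HybridizationEvent]) -> None:
    with open(path, "w") as fh:
        fh.write("#recipient\tdonor\ttime\tgamma\n")
        for ev in events:
            fh.write(
                f"{','.join(sorted(ev.recipient))}\t{','.join(sorted(ev.donor))}"
                f"\t{ev.time:g}\t{ev.gamma:g}\n"
            )
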