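"""Gene-tree / reference-tree agreement accounting.

Two complementary views of discordance are provided:

* **Node-wise concordance** — for each non-trivial bipartition of a
  reference tree, every gene tree is classified as *concordant* (it
  displays the split), *in conflict* (it displays an incompatible split),
  or *uninformative* (too few shared taxa, or unresolved).  The per-node
  tallies are the numbers behind the familiar pie-chart figures, and the
  same machinery drives the ILS test: simulate gene trees under the pure
  coalescent on the nuclear species tree, then ask what fraction of them
  is concordant with each node of an organellar (plastid) tree.  A node
  that essentially no simulated tree supports cannot be explained by
  incomplete lineage sorting alone — hybridization or introgression is the
  remaining suspect.

* **Distance distributions** — per-tree normalized Robinson–Foulds
  distances to the reference, compared between empirical and simulated
  gene-tree sets by a two-sample Kolmogorov–Smirnov test plus a histogram
  overlap coefficient.  Similar distributions mean the coalescent null is
  sufficient to explain the observed spread of gene-tree conflict.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .treeio import (
    Bipartition,
    GeneTreeSet,
    PhyloTree,
    TreeValidationError,
    bipartitions,
    mean_support,
    restrict,
)

__all__ = [
    "CONCORDANT",
    "CONFLICT",
    "UNINFORMATIVE",
    "SupportFilterResult",
    "NodeConcordance",
    "DistanceDistribution",
    "filter_by_mean_support",
    "classify_tree_at_node",
    "node_concordance",
    "concordance_table",
    "ils_node_support",
    "distance_distribution",
    "compare_distributions",
]

CONCORDANT = "concordant"
CONFLICT = "conflict"
UNINFORMATIVE = "uninformative"


class SupportFilterResult(NamedTuple):
    kept: GeneTreeSet
    n_low_support: int
    n_no_support: int


def filter_by_mean_support(trees: GeneTreeSet, threshold: float = 60.0) -> SupportFilterResult:
    """Keep gene trees whose mean internal support is strictly greater
    than ``threshold`` (the conventional "average support more than 60"
    screen against stochastic error).

    Trees without any numeric support label cannot be assessed and are
    dropped; their count is reported separately.
    """
    kept_trees, kept_ids = [], []
    n_low = n_none = 0
    for tid, tree in zip(trees.ids, trees.trees):
        ms = mean_support(tree)
        if ms is None:
            n_none += 1
        elif ms > threshold:
            kept_trees.append(tree)
            kept_ids.append(tid)
        else:
            n_low += 1
    return SupportFilterResult(GeneTreeSet(kept_trees, kept_ids), n_low, n_none)


def classify_tree_at_node(
    reference_split: Bipartition,
    gene_tree: PhyloTree,
    _gene_splits: frozenset[Bipartition] | None = None,
    _gene_taxa: frozenset[str] | None = None,
) -> tuple[str, Bipartition | None]:
    """Classify one gene tree against one reference bipartition.

    The reference split is first restricted to the gene tree's taxa; if a
    side collapses below two taxa the tree is uninformative for that node.
    Otherwise the tree is concordant if it displays the restricted split,
    in conflict if it displays an incompatible split (all four pairwise
    side intersections non-empty; the lowest-canonical-order such split is
    returned), and uninformative otherwise (unresolved/polytomy).

    ``_gene_splits`` / ``_gene_taxa`` allow callers iterating many nodes to
    reuse the gene tree's precomputed bipartitions.
    """
    gene_taxa = _gene_taxa if _gene_taxa is not None else gene_tree.taxa
    restricted = reference_split.restrict(gene_taxa)
    if restricted is None:
        return UNINFORMATIVE, None
    splits = _gene_splits if _gene_splits is not None else bipartitions(gene_tree)
    if restricted in splits:
        return CONCORDANT, None
    conflicting = [s for s in splits if not s.is_compatible_with(restricted)]
    if conflicting:
        top = min(conflicting, key=lambda s: s.canonical_str())
        return CONFLICT, top
    return UNINFORMATIVE, None


@dataclass
class NodeConcordance:
    """Per-reference-node tally of gene-tree agreement."""

    split: Bipartition
    n_concordant: int = 0
    n_conflict_top: int = 0
    n_conflict_other: int = 0
    n_uninformative: int = 0
    top_conflict: Bipartition | None = None
    _conflict_counts: Counter = field(default_factory=Counter, repr=False)

    @property
    def n_total(self) -> int:
        return (
            self.n_concordant + self.n_conflict_top + self.n_conflict_other + self.n_uninformative
        )

    @property
    def n_informative(self) -> int:
        return self.n_total - self.n_uninformative

    def fraction(self, count: int) -> float:
        return count / self.n_total if self.n_total else 0.0

    @property
    def frac_concordant(self) -> float:
        return self.fraction(self.n_concordant)

    @property
    def frac_concordant_informative(self) -> float:
        """Concordant / informative — missing-taxon trees excluded from the
        denominator so they do not dilute the signal."""
        return self.n_concordant / self.n_informative if self.n_informative else 0.0


def node_concordance(reference: PhyloTree, trees: GeneTreeSet | Sequence[PhyloTree]) -> list[NodeConcordance]:
    """Tally concordant / top-conflict / other-conflict / uninformative gene
    trees for every non-trivial bipartition of the reference tree.

    Rows are ordered by canonical split string for deterministic output;
    ties for the top conflicting split break toward the lowest canonical
    split string.
    """
    tree_list = list(trees)
    if not tree_list:
        raise TreeValidationError("node_concordance needs at least one gene tree")
    ref_splits = sorted(bipartitions(reference), key=lambda s: s.canonical_str())
    rows = [NodeConcordance(split=s) for s in ref_splits]
    gene_info = [(bipartitions(t), t.taxa) for t in tree_list]
    for row in rows:
        for (splits, taxa), tree in zip(gene_info, tree_list):
            cls, conflict = classify_tree_at_node(row.split, tree, splits, taxa)
            if cls is CONCORDANT:
                row.n_concordant += 1
            elif cls is CONFLICT:
                row._conflict_counts[conflict] += 1
            else:
                row.n_uninformative += 1
        if row._conflict_counts:
            top = min(
                row._conflict_counts.items(),
                key=lambda kv: (-kv[1], kv[0].canonical_str()),
            )[0]
            row.top_conflict = top
            n_conf = sum(row._conflict_counts.values())
            row.n_conflict_top = row._conflict_counts[top]
            row.n_conflict_other = n_conf - row.n_conflict_top
    return rows


def concordance_table(rows: Iterable[NodeConcordance]) -> pd.DataFrame:
    """Tabular (TSV-ready) form of a node-concordance accounting."""
    recs = []
    for i, r in enumerate(rows, start=1):
        recs.append(
            {
                "node": f"n{i}",
                "split": r.split.canonical_str(),
                "n_concordant": r.n_concordant,
                "n_conflict_top": r.n_conflict_top,
                "n_conflict_other": r.n_conflict_other,
                "n_uninformative": r.n_uninformative,
                "frac_concordant": r.frac_concordant,
                "frac_conflict": r.fraction(r.n_conflict_top + r.n_conflict_other),
                "frac_uninformative": r.fraction(r.n_uninformative),
                "frac_concordant_informative": r.frac_concordant_informative,
                "top_conflict": r.top_conflict.canonical_str() if r.top_conflict else "",
            }
        )
    return pd.DataFrame.from_records(recs)


def ils_node_support(
    plastid_tree: PhyloTree,
    simulated: GeneTreeSet | Sequence[PhyloTree],
    not_ils_threshold: float = 0.01,
) -> pd.DataFrame:
    """Fraction of coalescent-simulated gene trees concordant with each
    node of a (plastid) reference tree.

    The headline fraction uses the informative-trees denominator
    (concordant / (total - uninformative)); the all-trees variant is also
    reported for transparency.  Nodes whose fraction falls at or below
    ``not_ils_threshold`` are flagged ``not_explicable_by_ils``: the
    coalescent on the nuclear species tree essentially never produces
    them, so ILS cannot account for that conflict.
    """
    rows = node_concordance(plastid_tree, simulated)
    recs = []
    for i, r in enumerate(rows, start=1):
        frac = r.frac_concordant_informative
        recs.append(
            {
                "node": f"n{i}",
                "split": r.split.canonical_str(),
                "n_concordant": r.n_concordant,
                "n_informative": r.n_informative,
                "ils_fraction": frac,
                "ils_fraction_all_trees": r.frac_concordant,
                "not_explicable_by_ils": frac <= not_ils_threshold,
            }
        )
    return pd.DataFrame.from_records(recs)


@dataclass
class DistanceDistribution:
    """Normalized RF distances from a set of trees to one reference."""

    label: str
    distances: list[float]
    skipped_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        for d in self.distances:
            if not (0.0 <= d <= 1.0):
                raise TreeValidationError(f"normalized distance {d} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.distances)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.distances, dtype=float)


def distance_distribution(
    trees: GeneTreeSet | Sequence[PhyloTree],
    reference: PhyloTree,
    label: str = "trees",
) -> DistanceDistribution:
    """Per-tree normalized RF distance to ``reference``.

    Each gene tree is compared on the taxa it shares with the reference
    (both trees restricted first); trees sharing fewer than four taxa have
    no comparable splits and are skipped, with their ids reported.
    """
    if isinstance(trees, GeneTreeSet):
        ids, tree_list = trees.ids, trees.trees
    else:
        tree_list = list(trees)
        ids = [f"g{i + 1:05d}" for i in range(len(tree_list))]
    ref_taxa = reference.taxa
    # cache reference restrictions per shared-taxon set: gene trees from one
    # study mostly share a few missingness patterns
    ref_cache: dict[frozenset[str], frozenset[Bipartition]] = {}
    distances, skipped = [], []
    from .treeio import rf_distance  # local alias for clarity

    for tid, tree in zip(ids, tree_list):
        shared = tree.taxa & ref_taxa
        if len(shared) < 4:
            skipped.append(tid)
            continue
        if shared not in ref_cache:
            ref_r = reference if shared == ref_taxa else restrict(reference, shared)
            ref_cache[shared] = bipartitions(ref_r)
        b_ref = ref_cache[shared]
        tree_r = tree if tree.taxa == shared else restrict(tree, shared)
        b_tree = bipartitions(tree_r)
        raw = len(b_ref ^ b_tree)
        denom = len(b_ref) + len(b_tree)
        distances.append(raw / denom if denom else 0.0)
    return DistanceDistribution(label, distances, skipped)


def compare_distributions(
    empirical: DistanceDistribution,
    simulated: DistanceDistribution,
    bin_width: float = 0.05,
) -> dict[str, float]:
    """Two-sample KS statistic (with p-value) plus a histogram overlap
    coefficient on shared bins over [0, 1].

    KS is computed on the raw distance samples; the overlap coefficient is
    the summed bin-wise minimum of the two histogram proportions, so 1
    means identical binned shapes and 0 disjoint support.
    """
    if len(empirical) == 0 or len(simulated) == 0:
        raise TreeValidationError("compare_distributions needs non-empty samples")
    e = empirical.as_array()
    s = simulated.as_array()
    ks = stats.ks_2samp(e, s, method="asymp" if (len(e) > 50 or len(s) > 50) else "auto")
    nbins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, nbins + 1)
    he, _ = np.histogram(e, bins=edges)
    hs, _ = np.histogram(s, bins=edges)
    overlap = float(np.minimum(he / len(e), hs / len(s)).sum())
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "overlap_coefficient": overlap,
    }
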