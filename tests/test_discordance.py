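"""Concordance accounting, ILS test, and distance-distribution comparison."""

import itertools

import dendropy
import numpy as np
import pytest

from phyloconcord.coalsim import SimConfig, derive_seed, simulate_gene_trees
from phyloconcord.discordance import (
    CONCORDANT,
    CONFLICT,
    UNINFORMATIVE,
    classify_tree_at_node,
    compare_distributions,
    concordance_table,
    distance_distribution,
    filter_by_mean_support,
    ils_node_support,
    node_concordance,
)
from phyloconcord.treeio import (
    Bipartition,
    GeneTreeSet,
    TreeValidationError,
    bipartitions,
    parse_newick,
    rf_distance,
    write_newick,
)

from conftest import brute_force_splits, random_binary_tree


def with_supports(newick, value):
    t = parse_newick(newick)
    for node in t.internal_nodes():
        node.label = str(value)
    return t


# ---------------------------------------------------------------------------
# support filter
# ---------------------------------------------------------------------------


class TestSupportFilter:
    def test_strictly_greater_than_threshold(self):
        trees = GeneTreeSet(
            [with_supports("((A,B),(C,D));", v) for v in (59, 60, 61)], ["a", "b", "c"]
        )
        result = filter_by_mean_support(trees, 60)
        assert result.kept.ids == ["c"]
        assert result.n_low_support == 2

    def test_all_high_support_kept(self):
        trees = GeneTreeSet([with_supports("((A,B),(C,D));", 100) for _ in range(4)])
        assert len(filter_by_mean_support(trees, 60).kept) == 4

    def test_unsupported_trees_dropped_and_counted(self):
        trees = GeneTreeSet([parse_newick("((A,B),(C,D));")])
        result = filter_by_mean_support(trees, 60)
        assert len(result.kept) == 0
        assert result.n_no_support == 1


# ---------------------------------------------------------------------------
# per-node classification
# ---------------------------------------------------------------------------


def oracle_classify(ref_split, gene_tree):
    """Brute-force re-derivation: enumerate every gene-tree split and test
    the four-intersection condition directly."""
    shared = gene_tree.taxa
    a = frozenset(ref_split.side_a) & shared
    b = frozenset(ref_split.side_b) & shared
    if len(a) < 2 or len(b) < 2:
        return UNINFORMATIVE
    for split in brute_force_splits(gene_tree):
        x, y = tuple(split)
        if {x, y} == {a, b}:
            return CONCORDANT
    for split in brute_force_splits(gene_tree):
        x, y = tuple(split)
        if all(len(s & t) > 0 for s in (a, b) for t in (x, y)):
            return CONFLICT
    return UNINFORMATIVE


class TestClassify:
    def test_identical_tree_concordant_everywhere(self):
        ref = parse_newick("((A,B),((C,D),E));")
        for split in bipartitions(ref):
            assert classify_tree_at_node(split, ref.copy())[0] == CONCORDANT

    def test_collapsed_side_uninformative(self):
        split = Bipartition(frozenset("AB"), frozenset("CDE"))
        gene = parse_newick("((A,C),(D,E));")  # B missing: side_a collapses
        assert classify_tree_at_node(split, gene)[0] == UNINFORMATIVE

    def test_five_taxon_conflict_with_returned_split(self):
        split = Bipartition(frozenset("AB"), frozenset("CDE"))
        gene = parse_newick("((A,C),(B,(D,E)));")
        cls, top = classify_tree_at_node(split, gene)
        assert cls == CONFLICT
        assert top is not None and not top.is_compatible_with(split)

    def test_polytomy_is_uninformative_not_conflicting(self):
        split = Bipartition(frozenset("AB"), frozenset("CD"))
        assert classify_tree_at_node(split, parse_newick("(A,B,C,D);"))[0] == UNINFORMATIVE

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_binary_tree("ABCDEFG", rng)
        taxa = sorted(ref.taxa)
        keep = [t for t in taxa if rng.random() > 0.25]
        gene = random_binary_tree(taxa, rng)
        if len(keep) >= 4:
            from phyloconcord.treeio import restrict

            gene = restrict(gene, keep)
        for split in bipartitions(ref):
            assert classify_tree_at_node(split, gene)[0] == oracle_classify(split, gene)


# ---------------------------------------------------------------------------
# node concordance tallies
# ---------------------------------------------------------------------------


class TestNodeConcordance:
    def test_copies_of_reference(self):
        ref = parse_newick("((A,B),((C,D),E));")
        rows = node_concordance(ref, GeneTreeSet([ref.copy() for _ in range(10)]))
        for r in rows:
            assert (r.n_concordant, r.n_conflict_top, r.n_conflict_other, r.n_uninformative) == (
                10, 0, 0, 0)

    def test_six_four_split(self):
        ref = parse_newick("((A,B),(C,D));")
        other = parse_newick("((A,C),(B,D));")
        genes = GeneTreeSet([ref.copy() for _ in range(6)] + [other.copy() for _ in range(4)])
        rows = node_concordance(ref, genes)
        (row,) = rows
        assert (row.n_concordant, row.n_conflict_top, row.n_conflict_other) == (6, 4, 0)
        assert row.top_conflict == Bipartition(frozenset("AC"), frozenset("BD"))

    def test_full_table_against_oracle_on_handmade_fixture(self):
        rng = np.random.default_rng(123)
        ref = random_binary_tree("ABCDE", rng)
        genes = GeneTreeSet([random_binary_tree("ABCDE", rng) for _ in range(20)])
        rows = node_concordance(ref, genes)
        for row in rows:
            expected = {CONCORDANT: 0, CONFLICT: 0, UNINFORMATIVE: 0}
            for gene in genes:
                expected[oracle_classify(row.split, gene)] += 1
            assert row.n_concordant == expected[CONCORDANT]
            assert row.n_conflict_top + row.n_conflict_other == expected[CONFLICT]
            assert row.n_uninformative == expected[UNINFORMATIVE]

    def test_tallies_conserve_tree_count(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(5, 10))
            taxa = [f"t{i}" for i in range(n)]
            ref = random_binary_tree(taxa, rng)
            genes = GeneTreeSet(
                [random_binary_tree(taxa, rng) for _ in range(int(rng.integers(1, 15)))]
            )
            for row in node_concordance(ref, genes):
                assert row.n_total == len(genes)

    def test_invariant_to_gene_tree_order_and_rerooting(self):
        rng = np.random.default_rng(21)
        taxa = list("ABCDEF")
        ref = random_binary_tree(taxa, rng)
        genes = [random_binary_tree(taxa, rng) for _ in range(12)]

        def table_of(trees):
            return concordance_table(node_concordance(ref, GeneTreeSet(trees))).drop(
                columns=["node"])

        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert table_of(shuffled).sort_values("split").reset_index(drop=True).equals(
            table_of(genes).sort_values("split").reset_index(drop=True))

        rerooted = []
        ns = dendropy.TaxonNamespace()
        for t in genes:
            dt = dendropy.Tree.get(data=write_newick(t), schema="newick", taxon_namespace=ns)
            leaf = dt.find_node_with_taxon_label("C")
            dt.reroot_at_edge(leaf.edge, update_bipartitions=False)
            rerooted.append(parse_newick(dt.as_string(schema="newick").strip()))
        assert table_of(rerooted).equals(table_of(genes))

    def test_empty_set_rejected(self):
        with pytest.raises(TreeValidationError):
            node_concordance(parse_newick("((A,B),(C,D));"), [])

    def test_concordant_topology_dominates_under_msc(self, balanced10):
        """Positive control: with every internal branch >= 2 coalescent
        units, the concordant class is the most frequent at every node."""
        genes = simulate_gene_trees(balanced10, SimConfig(n_genes=2000, seed=6))
        for row in node_concordance(balanced10, genes):
            assert row.n_concordant > row.n_conflict_top


# ---------------------------------------------------------------------------
# ILS node support
# ---------------------------------------------------------------------------


class TestIlsNodeSupport:
    def test_long_branches_fully_explained(self, species12):
        """With every internal branch 5 coalescent units, per-node
        concordance is at least 1 - e^-5 ~ 0.993 analytically; 0.97 leaves
        room for Monte-Carlo noise at 500 replicates."""
        sims = simulate_gene_trees(species12, SimConfig(n_genes=500, seed=3))
        table = ils_node_support(species12, sims)
        assert (table["ils_fraction"] >= 0.97).all()
        assert not table["not_explicable_by_ils"].any()

    def test_three_taxon_minor_topology_fraction(self):
        """A plastid tree showing a minor topology is concordant with a
        simulated gene tree at rate (1/3) e^-t.  With three taxa the only
        comparable node is the root split of a 4-taxon extension, so an
        outgroup is added to make the node non-trivial."""
        import math

        t = 1.0
        species = parse_newick(f"(((A:1,B:1):{t},C:{1 + t}):10,O:{11 + t});")
        plastid = parse_newick(f"(((A:1,C:1):{t},B:{1 + t}):10,O:{11 + t});")
        n = 6000
        sims = simulate_gene_trees(species, SimConfig(n_genes=n, seed=12))
        table = ils_node_support(plastid, sims)
        row = table[table["split"] == "A,C|B,O"].iloc[0]
        p = (1 / 3) * math.exp(-t)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(row["ils_fraction"] - p) < 3 * se

    def test_empty_simulated_set_rejected(self):
        with pytest.raises(TreeValidationError):
            ils_node_support(parse_newick("((A,B),(C,D));"), [])


# ---------------------------------------------------------------------------
# distance distributions
# ---------------------------------------------------------------------------


class TestDistanceDistribution:
    def test_identical_trees_all_zero(self):
        ref = parse_newick("((A,B),((C,D),E));")
        dist = distance_distribution(GeneTreeSet([ref.copy() for _ in range(5)]), ref)
        assert dist.distances == [0.0] * 5

    def test_maximally_different_all_one(self):
        ref = parse_newick("((A,B),(C,D));")
        other = parse_newick("((A,C),(B,D));")
        dist = distance_distribution(GeneTreeSet([other.copy() for _ in range(3)]), ref)
        assert dist.distances == [1.0] * 3

    def test_composition_matches_per_tree_rf(self):
        rng = np.random.default_rng(4)
        taxa = list("ABCDEFGH")
        ref = random_binary_tree(taxa, rng)
        genes = [random_binary_tree(taxa, rng) for _ in range(10)]
        dist = distance_distribution(GeneTreeSet(genes), ref)
        assert dist.distances == [rf_distance(g, ref)[1] for g in genes]

    def test_few_shared_taxa_skipped_and_reported(self):
        ref = parse_newick("((A,B),((C,D),E));")
        small = parse_newick("((A,B),C);")
        dist = distance_distribution(GeneTreeSet([small], ["tiny"]), ref)
        assert dist.distances == [] and dist.skipped_ids == ["tiny"]

    def test_missing_taxa_compared_on_shared_subset(self):
        ref = parse_newick("(((A,B),(C,D)),(E,F));")
        gene = parse_newick("((A,B),((C,D),E));")  # F absent, same induced splits
        dist = distance_distribution(GeneTreeSet([gene]), ref)
        assert dist.distances == [0.0]


class TestCompareDistributions:
    def mk(self, label, values):
        from phyloconcord.discordance import DistanceDistribution

        return DistanceDistribution(label, list(values))

    def test_identical_samples(self):
        d = self.mk("a", [0.0, 0.2, 0.4])
        result = compare_distributions(d, self.mk("b", [0.0, 0.2, 0.4]))
        assert result["ks_statistic"] == 0.0
        assert result["overlap_coefficient"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        result = compare_distributions(self.mk("a", [0.0] * 5), self.mk("b", [1.0] * 5))
        assert result["ks_statistic"] == 1.0
        assert result["overlap_coefficient"] == 0.0

    def test_ks_matches_ecdf_sweep(self):
        """D for {.1,.2,.3} vs {.2,.3,.4} equals a brute-force ECDF scan."""
        e, s = [0.1, 0.2, 0.3], [0.2, 0.3, 0.4]
        grid = sorted(e + s)
        d_oracle = max(
            abs(sum(x <= g for x in e) / 3 - sum(x <= g for x in s) / 3) for g in grid
        )
        result = compare_distributions(self.mk("e", e), self.mk("s", s))
        assert d_oracle == pytest.approx(1 / 3)
        assert result["ks_statistic"] == pytest.approx(d_oracle)

    def test_empty_rejected(self):
        with pytest.raises(TreeValidationError):
            compare_distributions(self.mk("a", []), self.mk("b", [0.1]))

    def test_msc_self_consistency_single_draw(self, balanced10):
        a = distance_distribution(
            simulate_gene_trees(balanced10, SimConfig(n_genes=300, seed=1)), balanced10)
        b = distance_distribution(
            simulate_gene_trees(balanced10, SimConfig(n_genes=300, seed=2)), balanced10)
        result = compare_distributions(a, b)
        assert result["ks_pvalue"] > 0.01
        assert result["overlap_coefficient"] > 0.8
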