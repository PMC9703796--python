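"""Synthetic study-data generation.

Everything the analysis pipeline consumes can be generated here with known
ground truth: a Yule species tree in coalescent units, MSC (optionally
hybridizing) gene-tree sets, Jukes–Cantor alignments evolved along those
gene trees, an organelle tree, and VCF-like site records whose filter
outcomes are planted and recorded in a truth ledger — so every downstream
count is exactly predictable.

What this emulates, and what it does not: the generator reproduces the
*statistical structure* a genome-skimming phylogenomics study relies on
(ILS-driven gene-tree discordance, cyto-nuclear conflict from organellar
capture, depth/quality/heterozygosity call noise, missing data), but not
read-level artefacts (mapping bias, paralogy, indels, rate heterogeneity).
Tests passing on these fixtures validate the accounting and the simulator,
not any claim about a particular empirical data set.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import coalsim, snpmatrix
from .coalsim import HybridizationEvent, SimConfig, derive_seed
from .treeio import GeneTreeSet, PhyloTree, TreeNode, TreeValidationError, write_newick
from .snpmatrix import AlignmentMatrix, SiteRecord, SampleCall

__all__ = [
    "FixtureConfig",
    "generate_species_tree",
    "evolve_sequences",
    "generate_site_records",
    "generate_study_fixture",
    "jc_distance_matrix",
    "nj_tree",
]

_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}
_I2B = np.array(["A", "C", "G", "T"])


@dataclass
class FixtureConfig:
    """Knobs of the synthetic study.

    Rates are per coalescent-unit time; the substitution scale is in
    substitutions per site per coalescent unit.  Depth is Poisson with the
    given mean; site quality is normal (truncated at 0).  The planted
    violation rates make each masking rule's hit count exactly countable.
    """

    n_taxa: int = 12
    speciation_rate: float = 1.0
    tree_depth: float | None = 5.0  # rescale the Yule tree to this root height (CU)
    n_genes: int = 100
    hybridization_events: list[HybridizationEvent] = field(default_factory=list)
    alignment_length: int = 500
    substitution_scale: float = 0.05
    organelle_scale: float = 4.0
    mean_depth: float = 20.0
    quality_mean: float = 45.0
    quality_sd: float = 8.0
    low_depth_rate: float = 0.0      # per sample-site
    low_quality_rate: float = 0.0    # per site (quality is site-level)
    heterozygosity_rate: float = 0.0  # per sample-site
    missing_rate: float = 0.0        # per sample-site, uncalled genotype
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise TreeValidationError("n_taxa must be >= 3")
        for name in ("speciation_rate", "alignment_length", "n_genes"):
            if getattr(self, name) <= 0:
                raise TreeValidationError(f"{name} must be positive")
        for name in ("low_depth_rate", "low_quality_rate", "heterozygosity_rate",
                     "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise TreeValidationError(f"{name} must be a rate in [0, 1]")


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------


def generate_species_tree(
    n_taxa: int,
    rate: float = 1.0,
    seed: int = 0,
    depth: float | None = None,
) -> PhyloTree:
    """Ultrametric Yule species tree in coalescent units.

    A pure-birth process at ``rate``: starting from two lineages, each
    split waits Exp(k * rate); after the (n-1)th split the tree is cut at
    the next waiting time so every tip reaches the same height.  With
    ``depth`` the tree is rescaled so the root sits at that height.
    """
    if n_taxa < 2:
        raise TreeValidationError("need at least 2 taxa")
    if rate <= 0:
        raise TreeValidationError("speciation rate must be positive")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    names = [f"T{i + 1:0{width}d}" for i in range(n_taxa)]

    # forward simulation: active tips with their birth times
    t = 0.0
    root = TreeNode()
    active: list[tuple[TreeNode, float]] = []
    first = TreeNode()
    second = TreeNode()
    root.children = [first, second]
    active = [(first, 0.0), (second, 0.0)]
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.length = t - born
        a, b = TreeNode(), TreeNode()
        node.children = [a, b]
        active.extend([(a, t), (b, t)])
    t += rng.exponential(1.0 / (len(active) * rate))
    order = rng.permutation(n_taxa)
    for (node, born), name_idx in zip(active, order):
        node.length = t - born
        node.name = names[int(name_idx)]
    tree = PhyloTree(root, rooted=True)
    if depth is not None:
        if depth <= 0:
            raise TreeValidationError("depth must be positive")
        tree = coalsim.scale_tree(tree, depth / t)
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution (Jukes–Cantor)
# ---------------------------------------------------------------------------


def evolve_sequences(
    gene_tree: PhyloTree,
    length: int,
    rate: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> AlignmentMatrix:
    """Evolve a JC69 alignment along ``gene_tree``.

    The root sequence is uniform over {A,C,G,T}; along an edge of length d
    (coalescent units) with substitution scale ``rate``, each site differs
    from its parent with probability (3/4)(1 - exp(-4*rate*d/3)), mutating
    to one of the three other bases uniformly.
    """
    if length < 1:
        raise TreeValidationError("alignment length must be >= 1")
    if rate < 0:
        raise TreeValidationError("substitution rate must be >= 0")
    for node in gene_tree.iter_nodes():
        if node is not gene_tree.root and node.length is None:
            raise TreeValidationError("gene tree has edges without branch lengths")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows: dict[str, np.ndarray] = {}

    def _evolve(node: TreeNode, parent_seq: np.ndarray) -> None:
        if node is gene_tree.root:
            seq = parent_seq
        else:
            p_diff = 0.75 * (1.0 - np.exp(-4.0 * rate * node.length / 3.0))
            mut = rng.random(length) < p_diff
            seq = parent_seq.copy()
            n_mut = int(mut.sum())
            if n_mut:
                seq[mut] = (seq[mut] + rng.integers(1, 4, size=n_mut)) % 4
        if node.is_leaf:
            rows[node.name] = seq
        # children visited in sorted order: one RNG stream per tree shape
        for child in sorted(node.children, key=_min_leaf_name):
            _evolve(child, seq)

    root_seq = rng.integers(0, 4, size=length)
    _evolve(gene_tree.root, root_seq)
    taxa = sorted(rows)
    data = _I2B[np.stack([rows[t] for t in taxa])]
    return AlignmentMatrix(taxa, data)


def _min_leaf_name(node: TreeNode) -> str:
    while not node.is_leaf:
        node = min(node.children, key=_min_leaf_name)
    return node.name


# ---------------------------------------------------------------------------
# Site records with a truth ledger
# ---------------------------------------------------------------------------


@dataclass
class TruthLedger:
    """Which masking rule, if any, applies to each (site, sample).

    Attribution precedence is depth, then quality, then heterozygosity,
    then uncalled genotype: a sample-site failing several rules is counted
    once, under the first.
    """

    reasons: dict[tuple[int, str], str]  # (0-based site index, sample) -> rule

    def count(self, rule: str) -> int:
        return sum(1 for r in self.reasons.values() if r == rule)

    def masked_sample_sites(self) -> int:
        return len(self.reasons)


def generate_site_records(
    truth: AlignmentMatrix,
    config: FixtureConfig,
    chrom: str = "chr1",
    seed: int | None = None,
) -> tuple[list[SiteRecord], TruthLedger]:
    """VCF-like records for each column of a truth alignment.

    Depths are Poisson(``mean_depth``) conditioned to pass, except for a
    ``low_depth_rate`` fraction of sample-sites planted below 4; site
    qualities are truncated-normal conditioned to pass, except for a
    ``low_quality_rate`` fraction of sites planted below 20; sample-sites
    are planted heterozygous at ``heterozygosity_rate`` and uncalled at
    ``missing_rate``.  The ledger records exactly which rule masks which
    sample-site, with depth > quality > heterozygosity > no-call
    precedence, making every downstream filter count exactly predictable.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples = list(truth.taxa)
    records: list[SiteRecord] = []
    reasons: dict[tuple[int, str], str] = {}
    min_depth, min_quality = 4, 20.0

    for j in range(truth.n_sites):
        col = truth.data[:, j]
        ref = col[0] if col[0] in _B2I else "A"
        low_q = rng.random() < config.low_quality_rate
        if low_q:
            qual = float(rng.uniform(0.0, min_quality - 1e-6))
        else:
            qual = float(max(min_quality, rng.normal(config.quality_mean, config.quality_sd)))
        calls = {}
        for i, s in enumerate(samples):
            base = col[i] if col[i] in _B2I else None
            u = rng.random(3)
            low_d = u[0] < config.low_depth_rate
            het = u[1] < config.heterozygosity_rate
            nocall = u[2] < config.missing_rate or base is None
            depth = int(rng.integers(0, min_depth)) if low_d else int(
                max(min_depth, rng.poisson(config.mean_depth))
            )
            if nocall and not (low_d or low_q or het):
                calls[s] = SampleCall((None, None), depth)
                reasons[(j, s)] = "nocall"
                continue
            if base is None:  # truth gap/N: nothing to call regardless of plan
                calls[s] = SampleCall((None, None), depth)
                reasons[(j, s)] = "nocall"
                continue
            if het:
                other = _I2B[(_B2I[base] + int(rng.integers(1, 4))) % 4]
                alleles = (base, str(other))
            else:
                alleles = (base, base)
            calls[s] = SampleCall(alleles, depth)
            if low_d:
                reasons[(j, s)] = "depth"
            elif low_q:
                reasons[(j, s)] = "quality"
            elif het:
                reasons[(j, s)] = "heterozygous"
        records.append(SiteRecord(chrom, j + 1, ref, qual, calls))
    return records, TruthLedger(reasons)


# ---------------------------------------------------------------------------
# Whole-study fixture
# ---------------------------------------------------------------------------


def generate_study_fixture(config: FixtureConfig, outdir) -> dict:
    """Write a complete synthetic study to ``outdir``; return the manifest.

    Layout: ``trees/`` (species, gene, organelle Newick), ``alignments/``
    (per-gene FASTA), ``variants/`` (one VCF over the first gene's truth
    alignment plus its truth ledger), and ``manifest.tsv`` with the seed
    and sha256 of every file.  Everything derives from ``config.seed`` by
    fixed arithmetic, so reruns are byte-identical.
    """
    out = Path(outdir)
    for sub in ("trees", "alignments", "variants"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    seeds = {
        "species_tree": derive_seed(config.seed, 1),
        "gene_trees": derive_seed(config.seed, 2),
        "organelle": derive_seed(config.seed, 3),
        "alignments": derive_seed(config.seed, 4),
        "variants": derive_seed(config.seed, 5),
    }
    species = generate_species_tree(
        config.n_taxa, config.speciation_rate, seeds["species_tree"], depth=config.tree_depth
    )
    genes = coalsim.simulate_gene_trees(
        species,
        SimConfig(n_genes=config.n_genes, seed=seeds["gene_trees"]),
        events=config.hybridization_events,
    )
    organelle = coalsim.sample_organelle_tree(
        species, config.hybridization_events, config.organelle_scale, seeds["organelle"]
    )

    files: dict[str, Path] = {}
    files["trees/species.nwk"] = out / "trees" / "species.nwk"
    files["trees/species.nwk"].write_text(write_newick(species) + "\n")
    files["trees/genetrees.nwk"] = out / "trees" / "genetrees.nwk"
    genes.write(files["trees/genetrees.nwk"])
    files["trees/organelle.nwk"] = out / "trees" / "organelle.nwk"
    files["trees/organelle.nwk"].write_text(write_newick(organelle) + "\n")
    if config.hybridization_events:
        files["trees/events.tsv"] = out / "trees" / "events.tsv"
        coalsim.write_event_table(files["trees/events.tsv"], config.hybridization_events)

    alignments = {}
    for k, tree in enumerate(genes):
        aln = evolve_sequences(
            tree, config.alignment_length, config.substitution_scale,
            derive_seed(seeds["alignments"], k),
        )
        name = f"gene_{k + 1:04d}"
        alignments[name] = aln
        path = out / "alignments" / f"{name}.fasta"
        snpmatrix.write_fasta(path, aln)
        files[f"alignments/{name}.fasta"] = path

    first = alignments["gene_0001"]
    records, ledger = generate_site_records(first, config, seed=seeds["variants"])
    files["variants/sites.vcf"] = out / "variants" / "sites.vcf"
    snpmatrix.write_vcf(files["variants/sites.vcf"], list(first.taxa), records,
                        contigs={"chr1": first.n_sites})
    files["variants/ledger.json"] = out / "variants" / "ledger.json"
    files["variants/ledger.json"].write_text(
        json.dumps({f"{j}:{s}": r for (j, s), r in sorted(ledger.reasons.items())}, indent=0)
        + "\n"
    )

    manifest_rows = []
    for rel in sorted(files):
        digest = hashlib.sha256(files[rel].read_bytes()).hexdigest()
        manifest_rows.append((rel, digest))
    cfg = asdict(config)
    cfg["hybridization_events"] = [
        [sorted(e["recipient"]), sorted(e["donor"]), e["time"], e["gamma"]]
        for e in cfg["hybridization_events"]
    ]
    manifest = {"seed": config.seed, "derived_seeds": seeds, "config": cfg,
                "files": dict(manifest_rows)}
    with open(out / "manifest.tsv", "w") as fh:
        fh.write(f"#seed\t{config.seed}\n")
        for name, val in seeds.items():
            fh.write(f"#derived_seed.{name}\t{val}\n")
        for rel, digest in manifest_rows:
            fh.write(f"{rel}\t{digest}\n")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Test-only estimation utilities (not part of the analysis pipeline)
# ---------------------------------------------------------------------------


def jc_distance_matrix(alignment: AlignmentMatrix) -> np.ndarray:
    """Pairwise JC69 distances (substitutions/site) between rows."""
    codes = np.vectorize(lambda b: _B2I.get(b, -1))(alignment.data)
    n = alignment.n_taxa
    dm = np.zeros((n, n))
    max_d = 5.0  # cap for saturated pairs
    for i in range(n):
        for j in range(i + 1, n):
            ok = (codes[i] >= 0) & (codes[j] >= 0)
            if not ok.any():
                d = max_d
            else:
                p = float((codes[i][ok] != codes[j][ok]).mean())
                d = max_d if p >= 0.749999 else -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            dm[i, j] = dm[j, i] = min(d, max_d)
    return dm


def nj_tree(alignment: AlignmentMatrix) -> PhyloTree:
    """Neighbor-joining tree from JC distances (scikit-bio's NJ).

    A naive estimator used only to verify that synthetic alignments carry
    recoverable phylogenetic signal; the analysis pipeline itself takes
    gene trees as inputs.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj
    from .treeio import parse_newick

    dm = DistanceMatrix(jc_distance_matrix(alignment), ids=list(alignment.taxa))
    sk = nj(dm)
    for node in sk.traverse():  # NJ can emit negative lengths; clamp pre-parse
        if node.length is not None and node.length < 0:
            node.length = 0.0
    buf = io.StringIO()
    sk.write(buf, format="newick")
    return parse_newick(buf.getvalue().strip())
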