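# phyloconcord

Multispecies-coalescent simulation, gene-tree concordance accounting, and
genome-skimming SNP-matrix filtering — the toolkit behind a common question
in plant phylogenomics: **when nuclear gene trees and the plastid tree
disagree, is incomplete lineage sorting (ILS) enough to explain it, or do
we need hybridization?**

## What it does

* **`coalsim`** — simulate gene trees under the multispecies coalescent
  (MSC) on a species tree with branch lengths in coalescent units; extend
  the model with hybridization pulses (inheritance probability γ) and
  sample organelle trees (branch lengths scaled ×4 by default for the
  smaller effective size of haploid, uniparentally inherited genomes).
* **`discordance`** — classify every gene tree at every node of a
  reference tree as concordant / in conflict / uninformative (the numbers
  behind PhyParts-style pie charts); compute the fraction of
  MSC-simulated trees concordant with each plastid node (the ILS test —
  a node with fraction ≈ 0 is *not explicable by ILS*); compare
  normalized Robinson–Foulds distance distributions of empirical vs
  simulated gene trees (Kolmogorov–Smirnov + histogram overlap).
* **`snpmatrix`** — post-mapping SNP supermatrix construction from
  genome-skimming data: per-site depth (< 4), quality (< 20) and
  heterozygosity masking, VCF → aligned FASTA, most-common-base consensus
  with IUPAC ties, missing-data column thresholds (inclusive),
  invariant-site removal, gene length filters, coverage masking, and
  concatenation with a RAxML-style partition table.
* **`treeio`** — the tree model: Newick I/O (deterministic output),
  bipartitions, RF distances, taxon restriction, greedy consensus.
* **`synthetic`** — generate complete synthetic studies (species tree,
  gene trees, JC69 alignments, VCF-like records with a truth ledger) so
  every pipeline stage can be validated with exactly predictable outcomes.

The key quantity of the ILS test: under the MSC, a species-tree branch of
length *t* coalescent units is concordant in a fraction

    P(concordant) = 1 − (2/3) e^(−t)

of gene trees (3-taxon case), so short branches generate abundant
discordance without any gene flow. The package's simulator reproduces this
closed form and is cross-validated against msprime.

## Worked example

Generate a synthetic study in which the plastid genome of taxon `A` was
captured from the `C` lineage (γ = 1 hybridization), then test which
plastid nodes ILS can explain:

```python
from phyloconcord import (HybridizationEvent, SimConfig, parse_newick,
                          sample_organelle_tree, simulate_gene_trees,
                          ils_node_support)

species = parse_newick(
    "((((A:5,B:5):5,C:10):5,((D:5,E:5):5,F:10):5):10,"
    "((((G:5,H:5):5,I:10):5,J:15):5,(K:15,L:15):5):5);")
capture = HybridizationEvent(recipient="A", donor="C", time=2.5, gamma=1.0)

plastid = sample_organelle_tree(species, [capture], scale=4.0, seed=20)
sims = simulate_gene_trees(species, SimConfig(n_genes=10_000, seed=77))
table = ils_node_support(plastid, sims)
print(table[["split", "ils_fraction", "not_explicable_by_ils"]].to_string())
```

Output (abridged):

```
                     split  ils_fraction  not_explicable_by_ils
  A,B,C|D,E,...,L    0.9997                False
  A,C|B,D,...,L      0.0016                 True
  D,E|A,B,C,F,...    0.9949                False
  ...
```

Every node of the plastid tree is supported by ≥ 99% of the coalescent
simulations — except the `A,C` cherry created by the plastid capture,
which virtually no simulated gene tree displays (fraction 0.0016): that
conflict cannot be explained by ILS, exactly the planted truth.

The same analyses are available from the shell:

```bash
phyloconcord fixture --n-taxa 12 --n-genes 200 --seed 1 --outdir fx
phyloconcord sim-genetrees --species-tree fx/trees/species.nwk \
    --n-genes 10000 --seed 2 --outdir sim
phyloconcord ils-test --plastid-tree fx/trees/organelle.nwk \
    --simulated sim/genetrees.nwk --outdir ils
phyloconcord distdist --reference fx/trees/species.nwk \
    --empirical fx/trees/genetrees.nwk --simulated sim/genetrees.nwk \
    --plot --outdir dd
```

## Layout

```
src/phyloconcord/   treeio, coalsim, discordance, snpmatrix, synthetic, cli
tests/              unit + property + end-to-end validation suite
scripts/            acceptance.py
docs/methods.md     models, assumptions, parameter defaults, limitations
```
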