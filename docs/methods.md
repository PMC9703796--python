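# Methods

## The problem

Phylogenomic studies routinely observe that individual nuclear gene trees
disagree with each other, with the species tree, and — often most
strikingly — with the plastid (chloroplast) phylogeny.  Two biological
processes dominate the explanations: **incomplete lineage sorting (ILS)**,
in which gene lineages fail to coalesce within a species-tree branch and
sort discordantly by chance, and **hybridization/introgression**, in which
genetic material (often the whole uniparentally inherited plastome —
"chloroplast capture") crosses species boundaries.  Distinguishing them
matters because ILS is a neutral consequence of rapid radiations while
hybridization implies gene flow.

phyloconcord implements the standard simulation-based test: simulate many
gene trees under the multispecies coalescent (MSC) on the nuclear species
tree — the ILS-only null — and ask (a) whether the distribution of
gene-tree-to-species-tree distances of empirical gene trees matches that
of simulated ones, and (b) what fraction of simulated gene trees is
concordant with each node of the plastid tree.  A plastid node that
essentially no coalescent replicate supports cannot be explained by ILS;
hybridization is the remaining suspect.  The package also implements the
post-mapping construction of nuclear SNP supermatrices from genome-skimming
data, whose filtering rules (depth, quality, heterozygosity, missing-data
thresholds, invariant sites) feed the same kind of phylogenies.

## Models and procedures

### Multispecies coalescent (`coalsim`)

The species tree is rooted, binary, with branch lengths in **coalescent
units** (time scaled so k lineages coalesce at rate k(k−1)/2).  The
simulator runs backwards in time over a global timeline of node heights:
within each branch, pairs of lineages coalesce with exponential waiting
times; survivors enter the parent branch; above the root, coalescence
continues on an unbounded stem.  For the 3-taxon tree with internal branch
t this yields the textbook concordance probability 1 − (2/3)e⁻ᵗ, which the
tests and the acceptance script verify by simulation.

Node heights are computed bottom-up from branch lengths; the tree must be
*time-consistent* (tips contemporaneous — ultrametric in coalescent
units), because hybridization events are specified at absolute times and
lineage transfer between simultaneously existing branches requires a
common clock.  Species trees from summary-coalescent methods (ASTRAL-like)
carry internal lengths in coalescent units but no terminal lengths; there
is deliberately **no silent default** for these.  `fill_terminal_lengths`
must be called explicitly, either with a constant or with
`mode="ultrametric"` (extend every terminal so all tips reach the deepest
tip path).  A guessed fill would directly bias every ILS quantity the
package reports, so the choice is forced onto the caller and recorded.

**Hybridization** is modelled as a pulse: at `time`, each lineage on the
recipient edge independently jumps to the donor edge with inheritance
probability γ.  γ=0 reduces exactly to the pure MSC; γ=1 moves every
lineage.  Edges are addressed by the leaf set of the clade below them, a
plain-text-friendly id used in the sidecar event table.

**Organelle trees** are sampled by multiplying all branch lengths (and
event times) by a scale factor, default 4: a haploid, uniparentally
inherited genome has roughly one quarter of the nuclear effective
population size, so its coalescent branches are longer and ILS rarer.
The default is overridable; 4 corresponds to diploid biparental nuclear
inheritance versus haploid uniparental organellar inheritance.

**Randomness.**  All generators are numpy PCG64.  Per-replicate seeds are
derived from `(seed, index)` through `numpy.random.SeedSequence` hashing,
so replicate k of a run is bit-identical to a fresh single simulation with
the derived seed.  (A simple linear congruential derivation was measurably
correlated across substreams at the 10⁻³ level in topology frequencies and
was replaced.)  Branch iteration inside a simulation is ordered by
canonical clade string so the stream is platform-independent.

### Concordance accounting (`discordance`)

For each non-trivial bipartition of the reference tree, every gene tree is
classified: the reference split is restricted to the gene tree's taxa
(fewer than two taxa on a side ⇒ *uninformative*); if the gene tree
displays the restricted split it is *concordant*; if it displays an
incompatible split (all four pairwise side intersections non-empty) it is
*in conflict*, and the most frequent conflicting split per node is tracked
(ties broken by lowest canonical split string); otherwise it is
uninformative (unresolved).  Per-node counts always sum to the number of
gene trees.

The **support filter** keeps gene trees whose mean internal support is
*strictly greater* than the threshold (default 60), the conventional
screen against stochastic error in poorly resolved gene trees; trees with
no numeric supports cannot be assessed and are dropped and counted.

The **ILS fraction** at a plastid node is concordant / (total −
uninformative).  Excluding uninformative trees keeps gene trees with
missing taxa from diluting the signal; because the choice is not innocent,
the all-trees variant is reported alongside it in the same table.  A node
at or below `not_ils_threshold` (default 0.01) is flagged
`not_explicable_by_ils`.

**Distance distributions** use the unweighted Robinson–Foulds distance,
normalized by the total split count of the two trees, each gene tree
compared on the taxa it shares with the reference (both restricted; trees
with fewer than four shared taxa are skipped and reported).  Distributions
are compared with the two-sample Kolmogorov–Smirnov statistic on the raw
samples plus a histogram overlap coefficient on bins of width 0.05 over
[0, 1] — the granularity at which such distributions are usually plotted.

### Tree primitives (`treeio`)

Newick parsing is delegated to dendropy and converted into a light node
structure; a pre-scan reports the character offset of unbalanced
parentheses.  Serialization is custom and deterministic: children are
ordered by smallest descendant leaf name, so equal trees produce equal
text (reproducible diffs, checksummable fixtures).  Internal node labels
are support values when numeric; non-numeric labels are preserved but
excluded from support statistics.  All comparisons treat trees as
unrooted.  `restrict` suppresses degree-2 nodes by summing branch lengths
and keeping the larger of the two numeric supports (conservative: the
retained edge is at least as well supported as claimed).
`greedy_consensus` adds splits in decreasing frequency (ties by canonical
split string) while mutually compatible — pairwise compatibility suffices
for joint compatibility of splits on one leaf set — and is provided as a
parameter-recovery device for tests, not as a species-tree method.

### SNP matrices (`snpmatrix`)

Per-site filtering deletes a sample's call when read depth < 4, when the
site quality score < 20, or when the genotype is heterozygous; the
boundaries 4 and 20 **pass** (deletion is strictly "less than").  Quality
is the site-level score by default, with a flag for per-genotype quality;
heterozygous masking is per-sample, with a flag to drop the whole site.
Column filters: the missing-data threshold is **inclusive** (a threshold
names a tolerated level, so a column at exactly 40% missing survives 0.4),
while the support filter above is strict — the asymmetry follows the two
rules' conventional phrasings and is deliberately documented here.  Gap
"-" counts as missing for the threshold and as a non-state for invariance;
an invariant column is one with fewer than two distinct states among
A/C/G/T.  Consensus calling takes the most common base, emitting the IUPAC
ambiguity code on ties (information-preserving and deterministic) and "N"
with no data.  Coordinates are 1-based in variant records, 0-based
half-open in interval sets (BED convention), converted only at I/O
boundaries.  Concatenation pads absent taxa with "N" and records 1-based
inclusive partitions; splitting by the partition table inverts it exactly.

### Synthetic data (`synthetic`)

The generator produces every input the pipeline consumes with known ground
truth: Yule species trees (pure birth, made ultrametric, rescalable to a
target depth in coalescent units), MSC gene trees with optional
hybridization, Jukes–Cantor alignments evolved along the gene trees, an
organelle tree, and VCF-like site records.  Record noise is *planted*:
depths are Poisson (mean 20) conditioned to pass except for a configured
fraction forced below 4; site qualities are truncated normal (mean 45,
sd 8) conditioned to pass except for a configured fraction forced below
20; heterozygous and uncalled sample-sites are planted at configured
rates.  A **truth ledger** records which rule masks each sample-site, with
precedence depth → quality → heterozygosity → no-call (a sample-site
failing several rules is counted once, under the first), so every
downstream filter count is exactly predictable.  Default scales — 12 taxa,
species-tree depth 5 coalescent units, 100 genes of 500 bp at substitution
scale 0.05/site/unit — give a small radiation with appreciable but not
saturating ILS and alignments with usable signal, the regime the analysis
is designed for.

What the generator does *not* emulate: read-level artefacts (mapping bias,
base-calling error correlated along reads), paralogy and orthology
mis-assignment, indels and alignment error, substitution-rate
heterogeneity.  Passing tests therefore validate the accounting and the
simulator, not robustness to those real-data pathologies.

A neighbor-joining utility (scikit-bio NJ on JC distances, negative
branch lengths clamped to zero) exists solely so tests can verify that
synthetic alignments carry recoverable signal; it is not part of the
analysis pipeline, which takes gene trees as inputs.

## Numerical choices

* Height consistency tolerance 1e-6 (relative) when validating species
  trees; tip-depth equality asserted to 1e-9 in tests.
* Monte-Carlo assertions use 3 standard errors at the stated replicate
  counts; repeated-test properties (e.g., the γ=0 reduction) bound the
  number of α=0.01 rejections across independent repetitions instead of
  asserting a single p-value, so they are robust to the choice of stream.
* JC distances cap at 5 substitutions/site for saturated pairs.
* Ties everywhere (top-conflict split, consensus ordering, consensus
  bases) break deterministically, by canonical split string or IUPAC code.

## Problem sizes

The validation suite and the acceptance script use: 10,000 replicates for
closed-form MSC checks and the planted-hybridization ILS test (12 taxa);
all 5,460 pairs of the 105 six-leaf trees for RF; 1,000 random sets for
tally conservation; 100 repetitions of 200-vs-2,000-tree KS comparisons
for the distance-distribution null; 500-site × 8-sample record sets for
filter exactness; 100 seeded replicates of 1,000 trees for consensus
recovery; and 20,000 replicates per tree for the msprime cross-validation
(total-variation distance on unrooted topology classes — rooted triplet
classes in the degenerate 3-taxon case, where all unrooted labelled
topologies coincide).

## Known limitations

* The MSC simulator requires time-consistent species trees; branch-length
  matrices that are coalescent-unit consistent but not clock-like must be
  made so explicitly (`fill_terminal_lengths`).
* One sampled lineage per species is the default (and the tested path);
  multi-sample gene trees simulate but concordance accounting treats each
  tip label as a taxon.
* Hybridization events are instantaneous pulses, not continuous
  migration, and γ is a simulation input, never estimated from data.
* The distance-distribution comparison is a descriptive
  goodness-of-similarity check, not a formal model test: the KS p-value
  treats simulated trees as an i.i.d. sample, which they are, but the
  empirical gene trees of a real study carry estimation error the null
  does not model.
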