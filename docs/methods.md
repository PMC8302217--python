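# Methods

This note documents the models, conventions and parameter choices behind
`igpipe`, in the spirit of a statistical-software methods appendix.  It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Species ladder

All analyses are anchored on a fixed rooted binary tree over seven
vertebrates — mouse, rat, human, chimp, opossum, chick, zebrafish — with
named internal nodes Muridae, Primates, Eutheria, Theria, Tetrapoda and
Vertebrata.  Five of the internal labels double as conservation-age
groups; "Primates" is only a topological label for the human+chimp
cherry (a mouse-anchored LCA can never be Primates, and the age module
folds it into Eutheria defensively).  Branch lengths are uniformly 1:
the simulator's per-branch event rates are therefore expected event
counts per branch, not per unit time.

## Gene-family simulator

Families evolve top-down from a single ancestral gene at the root.  On
each species-tree branch a lineage experiences duplications and losses
as a competing-exponential (Poisson) process at rates λ_dup and λ_loss
per branch; a duplication splits the lineage into two copies that
continue independently from the duplication point; a loss terminates the
lineage.  Defaults λ_dup = 0.3, λ_loss = 0.2 give families with a
realistic mix of single-copy orthologs, lineage-specific expansions and
losses while keeping most families small (medians in single digits).

Two extant genes are *true orthologs* iff their last common ancestor in
the event tree is a speciation node.  This relation is a cograph by
construction, contains no same-species pairs, and is the ground truth
for every round-trip test.

Gene architecture (IG/MEG) evolves along the event tree: the root state
is IG with probability 0.3, and each event-tree edge flips the state
with probability 0.1.  These two knobs reproduce the qualitative pattern
that most orthologs of an intronless gene keep the architecture while a
minority switch, with switching accumulating over divergence.

### Observable versus raw event counts

The simulator records both the *raw* event census (every duplication and
loss drawn, checked against the node census of the emitted tree) and the
*observable* totals: the events recoverable in principle from the
cross-species orthology relation.  Events are unobservable when every
witness is gone — a clade lost entirely collapses to a single loss on
its topmost branch; a duplication whose second copy left no extant
descendant is invisible; a paralog clade confined to one species has no
orthology edge at all and drops out of the analysis.  Observable counts
are computed per connected component of the true orthology relation, on
the pruned true event tree, with adjacent duplication nodes flattened
(two duplications with no surviving speciation between them are
indistinguishable from one burst) and lineage passages shared where
copies can coalesce at a lower duplication.  This is precisely the
most-parsimonious embedding a reconstruction method can aspire to, so
the parameter-recovery tests demand *exact* equality between planted
observable totals and the inferred totals at zero noise — and get it.

### Emitters

* **Annotations.**  One GTF per species; an IG becomes a single-exon
  gene with the CDS inside the exon, a MEG a two-exon gene with a split
  CDS.  A configurable decoy fraction plants records that exercise each
  exclusion filter: mitochondrial contig (MT), non-coding biotype,
  missing CDS, multi-transcript genes, and uiSEG-style genes (one coding
  exon plus a separate UTR exon).  Expected calls for every decoy are
  written alongside the GTF.
* **Similarity.**  BLAST-tabular records (qseqid, sseqid, pident,
  length, bitscore).  All true-ortholog pairs of one family share a
  single identity draw from U(70, 90); cross-species non-ortholog pairs
  draw per-pair from U(10, 35); within-species pairs emit nothing.  The
  shared draw makes one-to-many orthology recoverable through co-best
  ties.  A noise parameter adds per-record Gaussian jitter
  (sd = 40·noise identity points), eroding both the 50% threshold margin
  and the tie structure; BBH recall degrades monotonically with it.
  The generator does not emulate alignment-specific features of real
  similarity searches — coverage variation, compositional bias,
  asymmetric scores, domain-level partial hits — so passing round-trip
  tests demonstrate the graph machinery, not robustness to alignment
  artifacts.
* **Counts.**  A gene × 8 matrix (4 replicates per stage).  Expressed
  genes draw negative-binomial counts with lognormal base means
  (median 100) and dispersion 0.1; planted UP/DN genes shift the stage-B
  mean by 2^±2 by default; planted NE genes are capped below the
  expression floor.  Library-size imbalance, batch effects and
  gene-length bias are not modeled.
* **PTM tables.**  Per-protein Bernoulli draws at the configured
  per-class proportions, in long format.

All emitters are bit-reproducible under a fixed seed; batch seeds are
spawned from a `SeedSequence` so family streams are independent.

## Architecture cascade

The ordered cascade: (1) non-protein-coding biotype → excluded;
(2) mitochondrial contig (configurable name set {MT, chrM, chrMT}) →
excluded; (3) no CDS → excluded (incomplete annotation); (4) more than
one transcript → MEG; (5) ≥ 2 CDS-overlapping exons → MEG (multi-exon);
(6) ≥ 2 exons with exactly one coding exon → MEG (UTR intron, the
"uiSEG" case); (7) otherwise IG.  UTR-intron detection is purely
geometric, from the exon/CDS intervals of the same annotation, rather
than an external intron database: the decision boundary is identical and
the package stays self-contained.  Coordinates are 1-based inclusive
end-to-end (GTF convention); nothing is re-based internally.

## Orthology

Best hits are computed per (query, target-species) over **all** records,
ranked by (bitscore, identity); the identity threshold (default 50%,
boundary inclusive) is applied afterwards to both best directions.
Applying the filter first would break monotonicity: raising the
threshold could promote a weaker hit to "best" and create a new edge.
Exact ties are all kept as co-best partners, so a gene may have BBH
edges to several in-paralogs of one species — necessary for one-to-many
orthology.  Both directions of a pair must be present in the input.

Orthogroups default to connected components, which are exact at the
scale this package targets; a density-based minimum-cut splitter is
available behind a flag for loosely connected components.  Isolated
genes (no orthology evidence) are retained in the graph but form no
orthogroup.

## Gene-tree reconstruction and reconciliation

Cograph recognition and modular decomposition use the classic recursion:
a disconnected graph is a parallel composition of its components, a
graph with disconnected complement a series composition of the
co-components, anything else contains a prime module.  The cotree is
kept canonical (adjacent like-labeled nodes merged).  An independent
exhaustive induced-P4 search provides the cross-check, and the two
agree on every non-isomorphic graph with ≤ 7 vertices.

Noisy graphs are repaired by a greedy editor: among all vertex pairs
participating in induced P4s, toggle the single pair that leaves the
fewest P4s; ties prefer removal over addition, then lexicographic order;
edges between same-species genes are never added.  The edit list is
returned for logging.  This is a heuristic, not a minimum cograph
editing solver (that problem is NP-hard); on a lone P4 it provably uses
one edit, and on noise-free simulated families it makes zero edits.

Series nodes become speciations, parallel nodes duplications.  A
speciation node whose child subtrees share a species is flagged
inconsistent, never silently relabeled.

Reconciliation uses LCA mapping: each node maps to the species-tree LCA
of its descendant species.  A duplication with k children counts k−1
events, attributed to the branch above its image.  Losses are counted as
skipped species-tree branches with two resolution rules for the
multifurcations a canonical cotree allows:

* a **speciation** multifurcation is resolved against the ladder
  topology — children grouped by the side of the image node containing
  them, each group descending as one lineage (its members are mutually
  orthologous and meet at the deeper speciation);
* a **duplication** multifurcation's children are mutually
  *non*-orthologous, so children on different sides of a species node
  must cross it separately, while children on the same side may coalesce
  at a lower duplication and cross once.  Each crossing of a species
  node charges one loss per side it abandons.

The second rule makes the embedding most parsimonious; charging every
child of a merged duplication separately would overcount losses whenever
successive duplications collapse into one multifurcation.  Duplications
are attributed to the multifurcation's image even when the minimal
embedding would let some of them slide lower; totals are unaffected,
per-branch gains inherit this convention.

## Conservation ages

Two rules are shipped because the cumulative wording of age groups is
ambiguous for gappy profiles (e.g. an ortholog in rat and human but not
chimp).  `strict` (default) takes the largest clade whose *every*
non-mouse species has an ortholog; `deepest` takes the clade of the
ladder-LCA of mouse plus all species with any ortholog.  Strict never
exceeds deepest, both are monotone under adding orthologs, and a gene
with no orthologs is mouse-specific under both.  Per-species
architecture of a multi-ortholog gene is decided by majority vote with
ties counted as "Other".

## Expression

CPM = count / library size × 10⁶, library size defaulting to the column
sum.  The expression floor marks a gene NE unless ≥ 4 of 8 samples have
≥ 5 reads (both thresholds configurable; the complementary reading of
the rule can be obtained by adjusting them).  log2 fold change uses
pseudo-count 0.5 on condition-mean CPM.  The per-gene test is pluggable:
default Welch t on log2(CPM + 0.5) — chosen because with 4 + 4
replicates it holds its nominal size on negative-binomial null data
(verified by simulation at 2,000 genes) — or a pooled-count exact
binomial test.  Dispersion-moderated NB testing (edgeR/DESeq2 style) is
deliberately out of scope; the classification rules, not the test
engine, are the fixed part of the procedure.  NE overrides everything;
UP/DN require p ≤ α and a signed log2FC; the rest is NC.  The "strong"
DE subset for enrichment uses |log2FC| ≥ 2 by default.

## Enrichment

Upper-tail hypergeometric P(X ≥ k) per term, BH step-up q-values,
terms as flat opaque labels (no GO DAG propagation).  The background
defaults to whatever gene universe the caller passes; genes without
terms still count in N.  The implementation is checked against
brute-force urn enumeration for every configuration with N ≤ 12 and is
conservative under permutation of random study sets (discrete test,
false-positive rate ≤ α).

## PTM comparison and microprotein screen

Per modification type, a pooled two-proportion Z-test
(z = (p̂₁−p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)), two-sided normal p) with
α = 0.05 and no correction across types.  A modification present in only
one population is "unique" — decided before any test, since the Z
approximation is meaningless at zero counts.  Continuity correction is
off by default.

The microprotein screen encodes three criteria with explicit defaults:
candidate length ≤ 250 aa, exactly one annotated domain, and existence
of a partner ≥ 400 aa with ≥ 2 domains sharing that domain.  The length
default sits below the reported IG peptide length mode; both thresholds
are package-level choices, exposed as parameters, and the screen is a
deliberate simplification of full microprotein prediction (no e-value
modeling, no complex-membership evidence).

## Synteny

A locus is the coordinate-ordered list of genes overlapping a query
interval by any amount, tagged with orthogroups.  Pairwise comparison
reports matched / lost / novel orthogroups, expansions (more copies in
the second locus), strand flips, and local order inversions counted as
maximal strictly-descending runs of matched partner indices — adequate
at single-locus scale and deliberately short of breakpoint-graph
machinery.  The SVG output is a minimal two-track box drawing.

## Pipeline and problem sizes

The orchestrator runs all stages on one config with per-stage toggles, a
run manifest (version, seed, parameters) and per-stage TSV/JSON outputs;
reruns with the same config are bit-identical.  The enrichment stage on
simulated data builds a small synthetic term map (an IG-biased term plus
a background term) since domain annotations are otherwise caller-side
inputs.

Default problem sizes — 500 families for parameter recovery, 150
families for the similarity round-trip, 2,000 genes for expression
calibration, 10,000 permutation draws for enrichment calibration, all
non-isomorphic graphs on ≤ 7 vertices for the cograph sweeps — were
chosen so the full check battery completes in a few minutes on one core
while keeping binomial standard errors small relative to the margins
being tested.

## Known limitations

* The cograph editor is greedy; heavily corrupted graphs may be repaired
  far from the minimum edit set.
* Reconciliation assumes the fixed ladder; arbitrary species trees work
  through `SpeciesLadder.from_newick`, but only fully named, rooted,
  binary trees are supported.
* The synthetic similarity model abstracts away alignment; conclusions
  about real BLAST/DIAMOND input quality do not follow from the tests.
* The DE engine is a simple two-sample test, not a dispersion-moderated
  NB model; with very few replicates or strong outliers its power
  profile differs from edgeR/DESeq2.
* Per-branch (as opposed to total) duplication attribution follows the
  image-of-the-multifurcation convention described above.
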