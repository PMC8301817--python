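# Methods

This note documents the models, parameters and design choices behind
the package, the way the synthetic data are generated, and what the
tests do and do not demonstrate about real data.

## Pairwise similarity

`align_local` computes the optimal local alignment under BLOSUM62 with
affine gap costs: a gap of length *k* costs `gap_open + (k−1)·gap_extend`
(defaults −11/−1).  The dynamic programme is exact (no seeding, banding
or X-drop); `Bio.Align.PairwiseAligner` supplies the optimized kernel
and the package layers identity bookkeeping, coordinates and statistics
on top.  Unknown residues are mapped to `X`, which scores 0 against
everything.  Percent identity counts identical columns over the full
alignment length including gap columns (the blastp `pident`
convention), because the 70%/55% dereplication thresholds downstream
are interpreted on that scale.  Co-optimal alignments are resolved by
canonicalizing the argument order, which makes identity and coordinates
invariant under query/subject swap.

E-values follow the Karlin–Altschul form `E = K·m·n·exp(−λS)` with the
classical ungapped BLOSUM62 constants λ = 0.267, K = 0.041 and the
product of sequence lengths as search space.  Composition-based
statistics and effective-length corrections are deliberately omitted:
the E-value here is a reproducible edge weight, not a database
significance estimate.  E-values are floored at 1e−180 so −log₁₀ E
stays finite.

## Homology graph

Candidates require a hit to the Lhr profile (COG1201 stand-in) with
E ≤ 1e−4 covering ≥ 30% of the profile.  One strain per species is kept
(lexicographically smallest strain key — deterministic and auditable).
For each (query, target species) the best subject is the minimal
E-value (ties: higher bit score, then smaller id).  An edge exists only
for reciprocal best hits between different species; its weight is the
mean −log₁₀ E over the two directions and its identity the mean percent
identity.  Reciprocal pairs whose E-values are ≥ 1 in both directions
(weight ≤ 0) are not edges.

## Markov clustering

Canonical MCL on the column-normalized weighted adjacency matrix:
expansion (matrix square), inflation (entrywise power, column
re-normalization), pruning of entries below 1e−6, until the iterate
changes by less than 1e−8 or 200 iterations.  Self-loops default to
each node's maximum incident edge weight so that loops live on the same
−log₁₀ E scale as the data; a unit loop against weights of order 100
would be invisible.  Clusters are the attractor systems of the
converged matrix; overlapping systems resolve to the lowest-indexed
cluster, and the whole procedure is deterministic under the sorted node
ordering.  All tolerances are exposed on `MclParams`.

**Inflation stability.**  MCL granularity is non-decreasing in the
inflation factor, and for clusters with near-uniform internal weights
there is a critical inflation beyond which the cluster genuinely
shatters into singletons (the diagonal of the expanded matrix dominates
each column, so strong inflation drives the iteration toward the
identity matrix; this is intrinsic to the algorithm, not an
implementation artifact, and insensitive to the self-loop convention).
A stability rule anchored at the top of the scan grid would therefore
fail whenever the grid extends past the critical inflation.
`scan_inflation` instead reports the *plateau*: the smallest inflation
opening the longest run of consecutive tested values whose partitions
agree pairwise (ARI ≥ 0.999 and equal cluster counts; ties between
equally long runs go to the larger inflations; a lone value is not a
plateau).  On published scans where a partition persists to the top of
the grid, both readings coincide.

## Medoid dereplication

After removing edges below the identity threshold (70% for the Lhr set,
55% for the Sfth outgroup), the pruned graph is re-clustered with MCL
(same inflation as the main run by default).  Singleton groups
represent themselves; each multi-member group contributes its medoid:
among members whose length lies within ±10% of the group median
(relaxed to the nearest-length members when the window is empty), the
member with minimal mean dissimilarity to the rest, ties to the
smallest id.  The ±10% window quantifies "length close to the median";
it is a package choice exposed on `ReductionParams`.  Dissimilarity is
`100 − identity%` from the pairwise hits, with 100 for pairs lacking a
significant alignment — bounded and on the same scale as the pruning
threshold.  Keep-list sequences (the re-added study strains) are
restored after selection; representatives missing either core profile
are then discarded, keep-list members included unless explicitly
exempted.

## Architecture calls and family rules

Per protein: the helicase core requires hits to both PF00270 and
PF00271.  Domain 4 is *intact* when a PF08494 hit (E ≤ 1e−3) covers at
least half the profile, *deteriorated* when hits exist but all cover
less, *absent* otherwise.  The cysteine-rich C-terminal motif is ≥ 4
cysteines within the 120 residues after the Domain 4 end (after the
last core-domain end when Domain 4 is absent).  An intein insertion is
a PF14890 hit nested inside a core-domain interval.  The 0.5 coverage
threshold and the 4-in-120 cysteine rule quantify qualitative
descriptions ("highly deteriorated", "cysteine-rich motif"); both are
exposed on `ClassifierParams`, and the cysteine rule is a stand-in for
whatever manual or profile-based annotation produced the original
calls.

The label rules: no core → unclassified; Domain 4 absent → Lhr-like
(any taxon); Bacteria with Domain 4 present → bLhr-HTH or bLhr by the
HTH_42 flag; Archaea/Asgard with deteriorated Domain 4 → aLhr3;
otherwise aLhr1 with the cys-rich motif, aLhr2 without (HTH_42 is
tolerated in aLhr2, as in Methanomassiliicoccales).  The mapping is
total over the flag space.  One corner has no described natural
counterpart — bacterial proteins with a *deteriorated* Domain 4 — and
is mapped with the other Domain-4-present bacterial proteins (bLhr /
bLhr-HTH) rather than to Lhr-like, keeping Lhr-like strictly "Domain 4
absent".  A cluster-consensus mode can relabel every member of an MCL
cluster with the cluster's majority label, mirroring how whole subtrees
are named; per-protein rules are the default.

Core extraction concatenates the protein segments covered by the best
PF00270 and PF00271 hits (best = lowest E-value; overlapping intervals
merged first), so the output length always equals the interval-union
size.

## Alignment post-processing

Column trimming keeps exactly the columns whose non-gap fraction is at
least the threshold (default 0.1, the `trimal -gt` meaning); `.` is
normalized to `-` on read; trimming is idempotent.  Concatenation
builds a supermatrix over a master taxon list, inserting all-gap blocks
for taxa missing from a marker, and reports 1-based block boundaries
that slice back exactly to the inputs.

## Genomic context

Neighborhoods contain genes on the same contig whose
boundary-to-boundary distance from the focal gene is below 4000 bp
(0 for overlapping genes) — the most permissive natural reading of a
"within 4 kb" rule; membership is symmetric.  Upstream/downstream is
defined on the focal gene's own strand.  Conservation tables count, per
(focal family, neighbor profile), the genomes with the profile
in-window over the genomes carrying the family, with side and
orientation breakdowns.  Co-occurrence over two families is a 2×2
genome contingency; the mutual-exclusivity flag requires an empty
"both" cell with non-empty exclusive cells.  Contigs are linear;
circular chromosomes are not modeled.

## Tree concordance

Trees are consumed as newick (inference is external).  Rooting places
the root on the single edge separating two named leaf sets, at its
midpoint when lengths are present.  A class is monophyletic when some
edge of the unrooted topology isolates exactly its leaves;
multifurcations are accepted.  Discordance per class is the minimum
over tree edges of (intruders inside the candidate clade) + (class
members outside it), capped at class size − 1; this edge-scan is exact
at the scales exercised here and is used for all class sizes.  The
concordant fraction is 1 − (total removals)/(leaf count).

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not sequence evolution:

* **Families.**  Each family descends from its own ancestor; ancestors
  descend from one root.  Substitutions are uniform over the
  alternative residues (identity, not realism, is the controlled
  variable).  Per-branch keep probabilities are calibrated so that
  *pairwise* identity among members matches `within_identity` (default
  0.85) and identity between ancestors matches `between_identity`
  (default 0.25), by inverting `q² + (1−q)²/(A−1) = target`.
* **Species layout.**  Member *i* of a family goes to species
  `i mod n_species`; the default `n_species = 20` equals the largest
  family, so every family has at most one member per genome — the
  orthologous-group structure BBH assumes.  Planting same-species
  co-members instead demonstrably fragments the BBH graph (same-species
  pairs can never be linked and best-hit reciprocity becomes a coin
  flip between equidistant paralogs), which is a property of BBH, not
  of the clustering.
* **Architectures.**  Profile hits realize each family's architecture
  at fixed coordinates: full-coverage core hits, an intact (coverage
  1.0) or deteriorated (coverage 0.30, safely below the 0.5 classifier
  threshold) Domain 4 hit or none, an optional HTH_42 hit, and for
  cys-rich families six cysteines planted inside the classifier's
  120-residue window.  Substitutions are drawn from a cysteine-free
  alphabet so the cys-rich flag is never set by mutational accident:
  generator and classifier are co-designed to sit on opposite sides of
  the thresholds, which is why 100% label recovery is an invariant
  here and *not* evidence about real annotation noise.
* **Gene layout.**  One linear contig per genome, all genes on the +
  strand, 200 bp between genes inside a block and > 4 kb between
  blocks so neighborhoods never overlap.  The conserved neighbor (a
  metallophosphoesterase stand-in, TIGR0024) is placed immediately
  upstream of a focal gene with probability 0.6 by default
  (overridable per family); an XOR mode plants it near one of two
  designated families per genome, never both.
* **Determinism.**  One master seed; per-entity streams are derived by
  stable hashing of entity ids, so generation is insertion-order
  independent and fixture bundles are byte-identical across runs.

Default problem sizes — six families of 20/12/8/4/3/2 proteins
(~49 proteins, ~300–550 aa) for recovery experiments, 50 genomes for
neighborhood statistics — keep the exact all-vs-all aligner the
dominant cost at a few seconds per run; they are large enough for the
binomial checks (±0.15 at n = 50) yet small enough that every test is
exact.

What passing tests show: the algorithms implement their definitions
exactly (oracle equivalences), and the pipeline recovers planted
structure when families are separated (85% vs 25% identity) and
genomes carry one ortholog each.  What they do not show: robustness to
annotation noise, paralogy, horizontal transfer, fragmented assemblies,
or realistic indel/rate heterogeneity — all explicitly outside the
generator's model.

## Numerical and degenerate-input conventions

Empty sequences, empty alignments, unknown keep-list ids, asymmetric
dissimilarity matrices, unlabeled leaves and overlapping rooting clades
raise `ValueError`.  MCL non-convergence is flagged on the returned
partition (with a warning), not raised.  Ties are always broken
lexicographically (medoids, best hits, cluster consensus) so every
stage is deterministic across platforms.
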