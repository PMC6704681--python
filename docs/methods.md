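# Methods

## Data model

The primary object is a query × array matrix **X** of signed
genetic-interaction scores.  Row and column labels are free-form gene
identifiers; a gene assayed under several conditions must carry distinct
labels (e.g. `GENE__27C`) and is treated as a separate gene throughout —
the reader never merges labels.  "Not measured" is a first-class state: an
empty cell in the tab-separated input maps to NaN internally, and a reader
flag (`unmeasured="zero"`) supports deposited matrices that use a literal
0 as the filler, since the two conventions cannot be distinguished from
the file alone.

The **one-square** transformation folds **X** into a symmetric supermatrix
**R** over the gene universe (the lexicographically sorted union of query
and array labels).  Each measured cell lands at the position of its
unordered gene pair; when both the query–array and the array–query cross
were measured, the two scores are arithmetically averaged.  Unmeasured
pairs are stored as 0 and flagged in a boolean mask; downstream code
treats them as 0 (so that profile vectors are total) but the mask is kept
so statistics could exclude them.  The diagonal is always unmeasured: a
screen does not produce self-crosses.  The **two-squares** route instead
scores query rows and array columns separately (blocks **Q** and **A**),
maps both blocks into the gene-universe frame, and averages entries
present in both; a pair where one gene was only a query and the other only
an array gene gets no value in either block and stays *undefined* —
undefined entries are excluded from summaries and never become network
edges.

## Similarity measures

Binary measures act on profiles thresholded at 0.5 — the conventional
cutoff for these screens; a score exactly equal to the threshold maps to 0
(the strict inequality is a determinism choice, as scores at exactly the
cutoff carry no evidence either way).  Pearson acts on the raw signed
rows.  Degenerate inputs are made total rather than erroring: a binary
measure involving an empty support is 0 ("no shared interactions"), and
Pearson of a constant vector is 0 with the pair flagged in the `defined`
mask.  The Dice coefficient is implemented as 2a/(|x|+|y|), which is the
harmonic mean of the two Braun-Blanquet coefficients; where a
"Braun-Blanquet" measure is requested without a variant the max-normalized
(classical) form is used, with the min-normalized form available
explicitly.  Summary statistics (mean, population variance, median, min,
max) are computed over defined, off-diagonal, upper-triangle entries only;
self-similarities of 1.0 would otherwise distort them.  Summaries are
computed on the full similarity matrix, before any edge thresholding.

## Network construction

The top-k heaviest defined pairs become edges (k = 20,000 at full screen
scale, the package default; benchmarks use smaller k matched to their
size).  Ties at the rank-k boundary are broken by ascending lexicographic
gene-pair order so that runs are reproducible; with a different tie rule
node counts could shift by a few.  Self-loops never occur (the diagonal is
undefined) and nodes are exactly the endpoints of retained edges.  Only
the giant connected component is kept for module detection, with size ties
broken by smallest node label.

## Module detection

Girvan–Newman recursive edge-betweenness removal, on the *unweighted*
graph: after thresholding, edge weights are similarities, and inverting
them into path lengths is a separate modelling decision — a weighted mode
(length = 1/weight) is available behind a flag.  Betweenness uses
shortest-path counting with fractional splitting among tied shortest
paths; the computation is delegated to igraph's C implementation of
Brandes' algorithm and is checked in the test suite against exhaustive
enumeration of all shortest paths on small random graphs.  One edge — the
highest-betweenness one, ties broken by lexicographic edge order — is
removed per iteration until no edges remain.

Every connected component whose size falls in [5, 50] (the plausible size
range of a functional module) at *any* step is recorded, the initial state
included; the recorded set is deduplicated, and modules may therefore be
nested.  Two equivalent optimizations are applied and tested for
equivalence against the plain single-sequence reference: components are
processed independently (removals in one component never change
betweenness in another), and components that fall below the minimum size
are dropped (they can never grow back).

## Clustering assessment

*Clustering Error.*  CE(S, S′) = max(0, |U| − D)/|U|, where U is the set
of distinct genes appearing in any module of either solution and D the
maximum total shared-gene count over one-to-one module matchings (Hungarian
algorithm, via `scipy.optimize.linear_sum_assignment`; verified against
permutation brute force).  For partitions this is the standard index with
CE(S, S) = 0.  For solutions with nested or overlapping modules the
matched total can count a gene several times and exceed |U|; the explicit
floor at 0 preserves the zero-at-identity property, which would otherwise
fail for exactly the clustering solutions this pipeline produces.

*Biological Homogeneity Index.*  For a cluster with n ≥ 2 annotated genes,
the fraction of annotated pairs sharing at least one functional term
(ordered and unordered pair counting give the identical ratio); clusters
with fewer than two annotated genes are undefined and excluded from the
solution-level unweighted mean.  Annotations are a flat gene → term-set
table; no term-hierarchy propagation is performed (pre-propagate if
needed), and a gene absent from the table is *uncharacterized*.

*Enrichment and overlap.*  Uncharacterized-gene enrichment and shared-gene
overlap between solutions use exact hypergeometric tails (equivalent to
one-sided Fisher tests), taken in the direction of the observed deviation;
a two-sided option doubles the tail.  The gene universe for these tests is
a parameter, since either all screened genes or only giant-component genes
are defensible choices.

*Consistency and module types.*  A module is *consistent* with a reference
clustering when ≥80% of its genes fall in one reference cluster and the
largest fraction of its genes sharing one annotation term reaches 0.8
(modules of ≥10 genes) or 0.5 (smaller).  The Type 1/Type 2 split (more
vs less than half of a module's genes already known to be functionally
linked) is implemented as an annotation-share proxy — the original labels
came from manual curation, which an automated pipeline cannot reproduce.

## Synthetic screens

The generator emulates the *shape* of a real screen: a signed score matrix
in which the genes of a planted module interact (scores above the 0.5
cutoff, drawn from (0.6, 1.0)) with a designated 15-gene partner set, all
other tested pairs interact spuriously with probability 0.005, and
non-interacting pairs carry signed noise in (−0.2, 0.2) — below the cutoff
in magnitude, mirroring the small negative scores real screens contain.
Module genes interact with their partners rather than with each other
because network edges encode profile similarity: shared partners, not
direct interaction, are what make a module recoverable.  Partner sets are
drawn per module from the 200-gene background pool, independently, so
cross-module partner sharing (and hence weak cross-module similarity)
arises naturally.  Defaults — 8 modules of 6–10 genes, 15 partners each,
p_within = 0.95, every gene in both query and array sets — constitute the
canonical benchmark used by the test suite (~270 genes, a scale at which
the full pipeline runs in seconds).  Interaction truth is decided once per
unordered gene pair; the two reciprocal measurements then draw independent
scores, exercising the one-square averaging rule.  One annotation term per
module is assigned to its members, with a configurable fraction left
unannotated; the truth clustering has BHI exactly 1 when fully annotated.

What the generator does *not* model: batch effects, linkage of array genes
to the query locus, replicate conditions beyond label suffixes, realistic
score distributions, or the dense correlated background of a real screen.
That last omission matters for one benchmark property: with independent
spurious interactions at 0.005, the thresholded network decomposes into
module cliques and partner cliques whose profile supports are disjoint by
construction, so the two layers connect only through rare spurious
bridges.  The giant-component filter then discards a variable subset of
planted module cliques, and end-to-end recovery of planted modules at
Jaccard ≥ 0.8 plateaus around 50–90% depending on measure and seed rather
than approaching 100%.  This is a property of the instrument, not of the
pipeline stages, each of which is verified against independent oracles;
passing tests demonstrate correctness of the transformations, not that the
generator reproduces the connectivity of real screens.  Recovery does
respond to signal as it should: lowering p_within lowers the recovered
fraction in expectation over seeds, which the suite checks.

## Numerical and reproducibility choices

All randomness flows from a single explicitly seeded NumPy generator per
synthetic screen; gene labels are zero-padded so lexicographic and
generation order coincide.  Pipelines write every intermediate artifact
(matrix, per-measure similarity, edge list, clustering) in plain
tab-separated text, floats at full `repr` precision so write/read round
trips are bit-exact; report tables use 6 significant digits with an
additional 2-decimal rounded variant.  Re-running a configuration produces
byte-identical reports, and a report can be rebuilt from written
similarity matrices alone (`resume=True`).  The command-line interface is
a thin layer over the library; every subcommand corresponds to one library
call.

## Known limitations

* Girvan–Newman is cubic-ish in practice; full 20,000-edge screen-scale
  networks take many hours, which is why module-stage validation relies on
  small-graph oracles and the synthetic benchmark (minutes).
* The two-squares merge follows one reading of the block-mapping rule
  (pairs absent from both blocks are undefined); other readings are
  conceivable.
* CE between solutions with heavy module nesting saturates quickly and is
  best compared between pipelines run with the same recording rules.
* No figure generation; the report tables contain the numbers the figures
  would show.
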