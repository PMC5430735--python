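# Methods

## Problem and model

`yhap` implements haplogroup analysis of the human Y chromosome from binary
SNP genotypes, specialised to the refined phylogeny of haplogroup
O2a1c-002611 in Han Chinese. The Y chromosome (outside the pseudoautosomal
regions) is paternally inherited without recombination, so its SNPs fall on
a single genealogy: each biallelic marker has an *ancestral* and a *derived*
state, and — assuming each site mutated only once — every marker marks
exactly one branch. This is the perfect-phylogeny model on binary rooted
characters, and it is the entire inferential machinery here:

- **Equivalence.** Two markers carried (derived) by exactly the same samples
  sit on the same branch and are phylogenetically equivalent.
- **Containment.** If marker B's carriers are a strict subset of marker A's,
  B arose on a branch below A. The parent of B's branch is the *smallest*
  class strictly containing it.
- **Incompatibility.** Carrier sets that overlap without nesting cannot be
  placed on one tree; they indicate recurrent mutation or genotyping error.

Tree construction (`yhap.placement.build_refined_tree`) restricts the matrix
to samples derived at a designated root marker (here IMS-JST002611, written
`002611`), drops markers with no observed carriers there, merges markers
into equivalence classes with a union–find over pairwise relations, attaches
each class to its unique minimal strict container, and raises a hard error
if that container is not unique. This is equivalent to the classical
O(nm)-style perfect-phylogeny construction but is implemented via explicit
pairwise classification because the pairwise contingency counts (both
derived / A-only / B-only / neither) are themselves a required output for
reporting violations.

## Missing data

Array genotypes contain no-calls. Every pairwise relation is evaluated only
on samples observed at **both** markers — the one convention that never
fabricates a call. Consequences, all surfaced in the placement report
rather than silently absorbed:

- Two markers with no jointly observed derived carrier are "equivalent by
  vacuity": merged, but flagged ambiguous.
- A sample ancestral (or missing) at the root marker but derived downstream
  is excluded from that marker's carrier set and listed as a root conflict.
- Masking calls can only merge or disconnect classes; on data generated
  from a true tree it can never manufacture an incompatibility (tested as
  the monotone-degradation property).

## Nomenclature

Clade names follow the Y Chromosome Consortium convention: the name of the
k-th child appends `a, b, c, …` to a name ending in a digit and the decimal
digits of k to a name ending in a letter (`O2a1c → O2a1c1 → O2a1c1a`).
There are no double letters; requesting a 27th lettered child is an error.
Sibling order is **not** identifiable from genotypes, so it is
configuration: a priority list of primary markers (the packaged reference
tree hard-codes the published order); the default is lexicographic by
primary marker. Each clade also carries a mutation-based alias
(`O-F11`) built from the first marker of its class under the configured
ordering.

Latent nodes — clades whose defining SNP was not genotyped, like O2a1c1a6 —
are declared in configuration only, carry no markers, and are never merged
or inferred. The calling walk treats a latent child as qualifying when any
marker in its subtree is derived; without this look-through, typed clades
below an untyped one would be unreachable. The observable cost is that a
sample belonging *exclusively* to the latent lineage is indistinguishable
from its parent's paragroup, and is called as such (verified in the tests).
A second latent placeholder (O2a1c1a6a1) exists solely to keep the
published child index of O2a1c1a6a2.

## Calling and paragroups

`call_sample` walks from the root, descending into the unique child with at
least one derived defining marker. Where the walk stops is the call; if the
stopping node has typed subclades the call is a *paragroup*, printed with a
star (`O2a1c1a*`). Unresolved paragroups (all downstream markers no-call)
are distinguished from confirmed ones in the `Assignment` object but
collapsed in frequency tables, which is how printed count tables treat
them. Anomalies are recorded as conflicts, never resolved by guessing:
mixed derived/ancestral within one equivalence class on the path; more than
one qualifying child (impossible without error — the call conservatively
stays at the parent); derived evidence below a branch the walk could not
enter.

## Quality control

Call-rate filtering removes samples, then markers, below the threshold
(default 0.985, the conventional array cut-off), iterating to a fixed
point; the result is idempotent by construction. Relatedness exclusion
consumes precomputed pairwise scores (e.g. genome-wide IBD estimates;
kinship estimation itself is out of scope) with threshold 0.125
(third-degree relatives). Rather than scanning pairs sequentially — which
on a chain A–B–C can remove two samples where one suffices — the exclusion
is computed as an exact minimum vertex cover per connected component of the
violation graph (brute force by increasing subset size; components here
are small, and a greedy max-degree fallback guards components above 20
samples). Ties between equally small covers are broken by removing the
lower-call-rate samples, then the lexicographically larger ids, making the
output deterministic and independent of input order.

## Frequencies and rounding

Frequency tables count samples whose call terminates at each row
(*exclusive*) and aggregate over subtrees (*cumulative*; always exactly
exclusive + children's cumulative, in integer arithmetic). All percentages
— including the East/North/South columns — are percentages of the **whole**
genotyped cohort (n = 2139 in the reference data), so regional columns sum
across regions to the overall column, not to 100% within a region.

Rounding is decimal half-up, with raw counts always retained. Two printing
styles exist because the reference table itself is internally inconsistent:
its overall column was evidently printed from values first rounded to
thousandths of a percent (14/2139 prints as 0.66, 57/2139 as 2.67, 17/2139
as 0.80 — all three need the double rounding), while its regional columns
were rounded once (17/2139 prints as 0.79 in a regional cell). `table1`
style reproduces exactly that; `plain` rounds once everywhere. Similarly,
regional clade sums offer a `rounded`/`table1` mode that sums the printed
two-decimal per-row values (reproducing the published 1.12/0.47/0.61 for
the O2a1c1b clade) and a default `raw` mode that sums counts first.

Regional integer counts for the reference fixture are reconstructed from
the printed percentages as `round(pct · 2139 / 100)`; every reconstructed
row sums exactly to its printed total count, and the reconstruction is
flagged as such in the fixture docstring. (The printed South total of
4.87% is not consistent with any such reconstruction — the reconstructed
South total is 104/2139 → 4.86%; the discrepancy is in the source total
row, not the per-row data.)

## Synthetic cohorts

The generator emulates the study design: n males (default study size 2139),
each drawing a true haplogroup from configured exclusive frequencies (the
packaged defaults are the published counts / 2139) or the outside-clade
remainder; the error-free genotype is derived along the root-to-node path
and ancestral elsewhere. Noise is layered on as independent symmetric A↔D
flips (per-genotype error rate) followed by no-call masking — deliberately
simple, chosen because the source study reports no error model; it is
sufficient to exercise every conflict path. Regions are drawn independently
of haplogroup. What the simulator does **not** emulate: linkage between
error events (batch effects), haplogroup-correlated geography, recurrent
mutation, or marker-specific missingness; a pass on synthetic data
therefore demonstrates algorithmic correctness under the stated model, not
robustness to structured artefacts in real arrays.

`expected_counts_cohort` is the deterministic variant: exactly the
requested count per node (and per region), no randomness. The reference
analysis regenerates the published cohort this way, which is why every
published percentage is recovered exactly: they are pure functions of the
printed counts and the tree topology.

## Reference fixture

The packaged tree has 27 nodes (2 latent). Marker equivalence classes for
17 nodes are the published ones; ten deeper nodes whose defining SNPs
appear only in the source's figure image carry synthetic placeholder names
`FX1`–`FX10`. These placeholders affect nothing measurable: YCC names
derive from topology and child order, and counts attach to names.
Rebuilding the tree from regenerated genotypes recovers 24 nodes — the two
latent nodes are invisible to genotype data, and the edge above
O2a1c1a1a1a1 (an internal node with zero exclusive carriers) merges with
its child's edge, exactly as perfect-phylogeny theory predicts when a node
has no exclusive carriers.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline on the 2139 × 68
regenerated cohort (seconds on one core), property checks on random trees
of ≤ 12 nodes with ≤ ~500 samples, and exhaustive oracles (vertex cover,
tree enumeration) on ≤ 8 elements. Placement and calling contain no
randomness; all set iterations are in sorted order, so identical inputs
give byte-identical outputs. Simulation is reproducible from a single
integer seed via `numpy.random.default_rng`.

## Known limitations

- No likelihood or quality-score model: calling is strictly rule-based.
- Recurrent-mutation suffixes (`L133.2`) are opaque strings; `.1/.2`
  assignment is input, not computed.
- The homoplasy `drop-lower-callrate` policy drops one marker per
  conflicting pair greedily; with dense conflicts a minimal drop set is not
  guaranteed (the default policy is a hard error instead).
- Branch lengths, coalescent dating and Y-STR diversity are out of scope.
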