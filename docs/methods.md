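# Methods

## Arm model

A chromosome arm is an ordered tuple of unique, opaque segment labels
(`SegmentOrder`). The model is **unsigned**: published banding notation for
these surveys records only the order of lettered fragments, not
within-fragment orientation, so an inversion is a plain reversal of a
half-open index window `[start, end)`. An arm has a fixed
centromere-to-telomere reading direction; an order and its mirror image are
therefore distinct (no dihedral symmetry). Windows spanning a single segment
are rejected rather than treated as identities — in practice they indicate
data-entry errors, since a one-segment reversal changes nothing observable.

Breakpoints are counted against a reference order with virtual anchors
before the first and after the last segment: an adjacency of the query that
does not occur in the reference in either orientation is one breakpoint.
One reversal can repair at most two breakpoints, so `ceil(b/2)` is an
admissible lower bound on the reversal distance.

Band-level characters without definable windows (the IL-eb band elaboration
and the IIIS-hb1/hb2 heterochromatic band changes) are carried in the
rearrangement registry as windowless presence characters; nothing in the
published material localizes their extent.

## Scenario search

`reversal_distance` is A* over arrangement space with the breakpoint bound
as heuristic; `enumerate_minimal_series` is a depth-first search at exactly
the minimal depth, pruned wherever `steps_remaining < ceil(b/2)`. Unsigned
sorting by reversals is NP-hard in general, so the search refuses
arrangements longer than 20 segments and enumeration deeper than 6 steps
rather than approximate — the real instances here are length 14 at distance
4, where the pruned enumeration finishes in well under a second.

Scenario output is fully deterministic: series are generated, and ties
broken, in lexicographic order of successive window index pairs.
`constrained_scenarios` scores each minimal series by how many of its
intermediate arrangements (the final, target-producing arrangement is never
counted) exactly match a supplied set of observed extant arrangements, and
reports whether the maximal score is attained uniquely — published
derivations tend to assert uniqueness, and the implementation verifies it
instead of assuming it. Matching is exact sequence equality; whether
Y-chromosome-borne arrangements belong in the observed set is left to the
caller.

## Population statistics

Frequencies are per chromosomal homologue (denominator `2n` over scored
larvae; larvae unreadable at a locus drop out of that locus's denominator
only). The Hardy–Weinberg test is the **uncorrected** Pearson χ² against
`n(1−p)², 2np(1−p), np²` with df = 1 (three genotype classes, one estimated
frequency); the published statistics this package reproduces (0.06, 7.25,
3.16, 0.28, 1.39) match the uncorrected statistic and not the
continuity-corrected one. Expected counts below 1 attach a warning but do
not block the test — surveys of this kind routinely test cells with small
expectations. Monomorphic samples are untestable and rejected.

Sex-linkage detection is an explicitly heuristic screen. A Y-linked pattern
(every carrier male, every male carrier heterozygous, no female carriers)
or an X-linked pattern (significant female association, or hemizygous
males never inverted-homozygous while inverted-homozygous females exist) is
only called when the carrier-by-sex Fisher exact test is informative;
sparse evidence yields `autosomal` with a low-evidence flag. Published role
assignments rest on direct observation of chromosome pairing and should be
passed as overrides to `build_profile`, which logs every override so
detected and published roles stay auditable against each other.

`build_profile` assigns roles from frequency (0 → absent, 1 → fixed,
otherwise polymorphic, promoted to X-/Y-linked by the screen above).
Frequencies are reported at 2 decimals in files, full precision in memory.
Mean autosomal heterozygosity averages heterozygous calls per larva over
polymorphic autosomal inversions only. Published per-cytoform means (1.06,
0.16, 1.74) cannot be recomputed from any desk data — the larva-level
genotypes behind them were never published — so they serve as simulation
targets only, never as assertions.

## Cladistics

Characters are polarized by outgroup rooting against the rearrangement-free
central sequence: absence is ancestral, any presence — fixed, polymorphic,
X- or Y-linked — is the single derived state. This "any presence" rule is
load-bearing: the Korean pair is united by two shared *polymorphisms*
(IS-21, IIS-5) and the Japanese pair by IIIL-38, polymorphic in one member
and fixed in the other; a fixed-only coding would dissolve both clades. It
reflects the standard cytogenetic argument that a rearrangement with
identical breakpoints marks one mutational origin whatever role it has
locally assumed.

Evolution is gains-only (Camin–Sokal-style irreversibility). Two characters
conflict iff their presence-taxon-sets properly overlap; a conflict-free
matrix admits a unique perfect phylogeny, built here as the inclusion
hierarchy of presence sets. Conflicting characters (losses, recurrent
gains) are excluded from grouping but flagged, never silently dropped.
Characters present in every ingroup taxon attach to the ingroup stem; the
inclusion hierarchy likewise settles where a rearrangement that is sex-linked
in one taxon and fixed in others attaches (at the deepest node covering all
carriers). Children are ordered alphabetically by smallest leaf name, so
output is deterministic. Each inferred synapomorphy is re-verified against
the matrix after construction.

`fixed_difference` counts the symmetric difference of fixed-rearrangement
sets — a pseudometric on profiles. Counts quoted against standards outside
the packaged survey (e.g. a subgeneric standard) require inversion lists
from prior literature and are treated as documented constants, not computed.

Newick output carries synapomorphy lists as node comments
(`[&syn=IS-21|IIS-5]`); reading goes through dendropy with underscores
preserved.

## Synthetic data

`simulate_population` draws sexes Bernoulli(sex ratio), autosomal genotypes
from Hardy–Weinberg proportions at the specified homologue frequency, fixed
loci always `I/I`, and sex-linked loci mechanistically through explicit X/Y
chromosome variants, each variant carrying a set of inversions at a stated
frequency (females draw two X's, males an X and a Y; genotype = dose). The
`hwe_deviation` parameter is a single inbreeding-style coefficient
F ∈ [−1, 1]: genotype probabilities `(q²+Fpq, 2pq(1−F), p²+Fpq)`, positive F
depleting heterozygotes. It is the simplest mechanism able to produce the
one Hardy–Weinberg rejection seen in the survey (a heterozygote deficit).
All randomness flows from one mandatory seed through
`numpy.random.default_rng`; equal seeds give identical tables.

The generator emulates the sampling design of a cytoform survey — it does
not model drift, migration, selection, clines, or linkage (each autosomal
locus is drawn independently), and B-chromosome/mermithid flags are plain
Bernoulli draws kept only so record schemas round-trip. Passing tests
therefore show that the statistics recover the parameters of this idealized
design, not that they are robust to population structure in field data.

`simulate_clade` stacks populations on a gains tree: characters gained on
the root-to-tip path are fixed at the tip unless the tip spec keeps them
polymorphic; a tip declaring a gained character absent is rejected as
inconsistent. Topology recovery through
`build_profile → build_character_matrix → infer_cladogram` succeeds exactly
when every internal edge carries at least one gain; a zero-gain edge shows
up as an unresolved polytomy, by design.

### The packaged survey reconstruction

The reference bundle rebuilds the published five-cytoform survey (A, B from
Korea; C from Hokkaido; D from Okinawa; K from Malaysia; 216 larvae; 41
rearrangements). The larva-level genotype tables are **synthetic
reconstructions**: the survey published only aggregate marginals, so the
tables are constructed deterministically to reproduce every printed summary
— per-site sample sizes and sex ratios, all five testable genotype triples
(15/24/11, 16/6/6, 12/9/7, 23/23/4, 25/23/2), the 27/25/29 carrier/union
structure of the partially linked IIIL-37/38 pair (79.3% co-carriage), the
sex-chromosome combination counts of all four Malaysian sites, and the
rounded homologue frequencies. Genotype classes are spread over a
sex-interleaved larva order so that no class lands on a single sex by
construction artifact.

Three published values resist exact reconstruction and are documented
rather than forced: the two C-cytoform IIIL-37/38 frequency cells (0.27 and
0.31) are inconsistent with their own footnote counts (which imply 0.31 and
0.27 — apparently swapped; the genotype tables follow the counts, the
profile table the cells); the D-cytoform band-enhancement frequency prints
0.04 where the stated counts (2 heterozygous males of 88 homologues) give
0.02; and the Malaysian IL-13 polymorphism has per-site counts printed for
one site only, so the remaining ten inversion-bearing homologues are placed
at the two other polymorphic sites in an arbitrary but documented split
consistent with the quoted per-site frequency ranges.

## Numerical and design notes

* Coordinates are 0-based half-open in every machine-facing format; the
  published 1-based bracket/pipe notation is accepted on input.
* All tabular formats are UTF-8 TSV with headers and `#` comments; trees
  are newick. Writers round-trip through readers, including profile rows
  for taxa that carry nothing (the outgroup), via a `-` placeholder row.
* χ² p-values come from `scipy.stats.chi2.sf`; Fisher exact tests from
  `scipy.stats.fisher_exact`.
* Test-suite problem sizes: oracle equivalence of the A* search against
  breadth-first search uses random arrangements of length ≤ 7; HWE type-I
  calibration uses 2,000 multinomial replicates at n = 50, p = 0.46 (the
  rejection count is checked against the exact binomial 99% interval);
  power against F = 0.5 uses 300 replicates at n = 50, p = 0.3; parameter
  recovery uses n = 1,000 larvae within 3 binomial standard errors.
* Known limitations: no signed (orientation-aware) reversal model, no
  weighted or length-penalized reversals, no Dollo/Fitch parsimony or
  branch support, no linkage-disequilibrium coefficients beyond carrier
  co-occurrence, and the sex-linkage screen is a heuristic — it will call
  `autosomal` on X-linked loci whose carriage pattern is statistically
  indistinguishable from autosomal segregation at survey sample sizes.
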