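# cytophylo

Macrogenomic cytotaxonomy toolkit: inversion-scenario reconstruction and
chromosomal cladistics for polytene karyotype surveys.

## The problem

Black flies (Diptera: Simuliidae) and other Diptera with giant polytene
chromosomes are surveyed by reading the banding sequence of each chromosome
arm larva by larva. Paracentric inversions — reversals of a contiguous block
of bands — accumulate in populations as fixed differences, floating
(polymorphic) variants, or sex-chromosome markers, and because independent
inversions essentially never share breakpoints, they are near-ideal
phylogenetic characters. A survey of this kind produces three things this
package makes computable:

1. **Arrangements** — each arm is an ordered sequence of uniquely labelled
   segments (`abcdefghijklmn` for a 14-segment arm). One inversion reverses a
   window of that sequence. Given two arrangements, what is the *minimum*
   number of inversions separating them, and which minimal series passes
   through arrangements that still segregate in extant populations?
2. **Genotype tables** — each larva is scored `S/S`, `S/I` or `I/I` at every
   named rearrangement. From these come per-homologue frequencies
   `p = (n_SI + 2·n_II) / 2n`, the uncorrected Pearson χ² goodness-of-fit
   test against Hardy–Weinberg proportions `(1−p)², 2p(1−p), p²` at df = 1,
   per-larva autosomal heterozygosity, carrier co-occurrence of linked
   inversion pairs, and a sex-linkage heuristic — all collected into a
   per-cytoform *profile* (role + frequency per rearrangement).
3. **Profiles across cytoforms** — treating each rearrangement as a binary
   character (derived if present in *any* role), polarized by an outgroup
   carrying none of them, a conflict-free matrix has a unique perfect
   phylogeny under gains-only evolution: the inclusion hierarchy of
   presence-taxon-sets, with each clade annotated by its synapomorphies.

The packaged reference dataset reconstructs a five-cytoform survey of the
*Simulium suzukii / S. tani* lineage (cytoforms A, B, C, D and K; 216 larvae;
41 named rearrangements), including synthetic larva-level genotype tables
that reproduce every published marginal (genotype triples, frequencies,
sex-chromosome counts, co-carriage structure).

## Worked example

Write the reference bundle and run the three main analyses:

```bash
cytophylo simulate --out-dir demo
cytophylo hwe --table demo/genotypes_C.tsv --locus IS-16
cytophylo derive --source suzukii_tani_standard --target cytoform_D \
    --observed cytoform_A,cytoform_B \
    --arrangements demo/arrangements.tsv --out demo/scenarios.tsv
cytophylo tree --profiles demo/profiles.tsv --outgroup tani_central \
    --out demo/tree.nwk
```

The Hardy–Weinberg test on the Hokkaido (cytoform C) IS-16 polymorphism
prints

```
all	IS-16	n=50	freq=0.46	chi2=0.06	df=1	P=0.8110
```

— 50 larvae, inverted-homologue frequency 0.46, χ² = 0.06 at df = 1: the
genotype counts (15, 24, 11) sit almost exactly on Hardy–Weinberg
proportions. The scenario search prints

```
7 minimal scenario(s); optimum unique: True; truncated: False
rank	steps	observed_hits	matched_names	hypothetical_count
1	[3,9);[7,11);[7,13);[1,5)	2	-,cytoform_A,cytoform_B,-	1
```

— seven distinct 4-step inversion series connect the standard sequence
`abcdefghijklmn` to the Okinawan (cytoform D) order `ahicbgfmledjkn`, and
exactly one of them passes through two extant arrangements: after step 2 it
matches cytoform A, after step 3 cytoform B, with a single hypothetical
intermediate after step 1. Its windows are the named inversions IIIL-35,
IIIL-36, IIIL-37 and IIIL-38 (0-based half-open coordinates). The tree
command prints the newick cladogram

```
((((A,B)[&syn=IIS-5|IS-21],(C,D)[&syn=IIIL-38]) ... ,K),tani_central);
```

(abridged): Korean cytoforms A and B are united by the shared IS-21 and
IIS-5 polymorphisms, Japanese cytoforms C and D by IIIL-38, with the
*S. tani* cytoform K outside and the rearrangement-free central sequence as
the root.

The same stages are available as library functions
(`cytophylo.reversal_distance`, `cytophylo.constrained_scenarios`,
`cytophylo.hwe_chisq`, `cytophylo.build_profile`, `cytophylo.infer_cladogram`,
…) and as one orchestrated run (`cytophylo run --config run.yaml`).

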