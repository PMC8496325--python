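# Methods

## Model and assumptions

`synorth` treats orthology inference as a graph problem constrained by
two independent lines of evidence. Sequence-similarity orthogroups
supply *candidate* orthology but overmerge when paralogs are retained or
rates of evolution vary; collinearity blocks supply positional evidence
but are pairwise and, in genomes with ancient duplications, frequently
chain segments descended from different ancestral regions. The method
assumes:

* the genomes are closely related enough that most true orthologs lie
  in conserved gene order;
* the upstream orthogroups are reliable where copy numbers are low —
  specifically, where each species contributes no more *gene sets*
  (tandem-collapsed orthology units) than its relative ploidy allows;
* tandem duplicates are a local, resolvable special case of syntenic
  orthology and can be collapsed to one unit for counting and chained
  as edges in the final graph.

Relative ploidy is a per-species positive integer giving the expected
multiplier of gene copies relative to the base lineage (default 1; 2
for a tetraploid among diploids). It enters the algorithm in exactly one
place — the tether filter's per-species gene-set budget — which is what
lets an allopolyploid be analysed unsplit.

## Decision rules and their edge cases

The scoring and filtering rules are stated in the README. The genuinely
open corners were resolved as follows, and the choices are regression
tested:

* **Block acceptance tie.** A block with equally many Pass and Not Pass
  scores is kept: only a strict excess of Not Pass discards.
* **One-sided scoring within a species.** When gene *a* is tethered and
  its same-species partner *b* is not, the tether blocks the pair (Not
  Pass) only if it contains a gene of that species *other than both a
  and b*: a gene's own tether membership never testifies against its own
  pair. A gene degenerately paired with itself scores No Call.
* **End rule on PASS-free ends.** From each end, removal runs through
  the last Not Pass that precedes the first Pass; No Call pairs distal
  to the first Pass are retained. In a block with no Pass at all both
  ends trim independently, which may empty the block (such blocks are
  discarded regardless).
* **Window rule.** The window is the first six scored (Pass/Not Pass)
  pairs from an end — all of them when fewer than six exist. Three or
  more Not Pass trigger removal of the endmost pair; the end rule is
  re-applied and the window recomputed after every single removal, and
  removal continues until Pass strictly outnumbers Not Pass in the
  window (ties keep removing) or the block is exhausted.
* **Split rule.** A run is a maximal stretch of Not Pass with no
  intervening Pass; No Call pairs neither break nor rescue it. The run
  (including interior No Calls) is dropped and cannot belong to either
  child, since it would immediately violate the end rule there.
* **Rule order.** End rule → window rule → split → acceptance filters;
  split children re-enter at the end rule; the cycle repeats until a
  fixed point. Termination is guaranteed because every productive step
  removes at least one pair. The minimum surviving block size of five is
  counted in gene *pairs* (block rows), not distinct genes.
* **Tether minimum.** "At least two species within ploidy" is read as at
  least two species with a *nonzero* gene-set count in `[1, ploidy]`: a
  tether must anchor something on two sides. Zero-count species are
  permitted (orthology can be inferred past lineage-specific loss) but
  do not count toward the two.
* **Tandem edges.** Tandem-array chain edges are added for *all* arrays,
  including arrays that touch no block edge; a purely tandem array of
  two or more genes therefore surfaces as a species-specific orthogroup.
  This is what produces substantial species-specific group counts, which
  similarity-only groupers largely lack.
* **Non-adjacent tandem pairs.** A declared tandem pair whose members
  are not adjacent in gene order (possible disagreement between the
  tandem caller and the annotation) is merged with a warning — the
  upstream call is trusted.

## Gene naming

`translate` converts annotation IDs to `<speciesIndex>_<geneIndex>`:
species indices follow input order, gene indices restart at zero per
species and follow chromosomal order (ascending start, ties by end then
ID). The mapping is an explicit bijection written to `name_map.tsv`, and
OrthoFinder's own `SequenceIDs.txt`/`SpeciesIDs.txt` can be loaded in
its place (`NameMap.from_orthofinder`) for interoperability with real
runs. Coordinates are kept 1-based inclusive throughout. Parsed
collinearity e-values are retained for reports but never influence the
algorithm.

## Synthetic data generator

`simulate` emulates the four-taxon study design the method targets: an
outgroup, two diploids, and an allotetraploid whose two subgenomes
descend from the two diploid lineages. A shared ancestral gene order
(default two chromosomes × 250 genes, i.e. 500 genes per diploid
genome) evolves independently along each of the five lineages through
per-gene loss, per-gene tandem duplication (one extra adjacent copy),
and optional segmental inversions and translocations (segments of 5–30
genes). Defaults are noiseless; the ploidy-equivalence analyses use 5%
loss and 5% tandem duplication, which are realistic per-lineage scales
for closely related congeners.

Collinearity blocks are emitted *pre-chained*: maximal runs of shared
surviving ancestral genes, monotone in both genomes' gene order, with a
minimum of five anchors — what a pairwise collinearity caller would
report on these genomes, run for every genome pair including the
tetraploid against itself. The orthogroup table contains the true groups
(every group of two or more surviving copies), optionally perturbed by
the two characteristic failure modes of similarity clustering: merging
two groups or dropping a gene. Every gene is traceable to one ancestral
gene in the truth table, and the same seed with the split/unsplit flag
toggled yields the identical genomes under the two species labelings
(lineage evolution is keyed only by seed and lineage).

What the generator does **not** emulate: sequence evolution (FASTA
records are placeholders), misassembly, fractionation bias between
subgenomes, micro-rearrangements below the five-gene block floor, and
collinearity-caller noise such as spuriously chained blocks bridging
unrelated regions. Passing the planted-recovery test therefore shows
that the decision rules are implemented faithfully and lose nothing on
clean input; it does not bound performance on real genomes, where block
quality dominates.

## Numerical and determinism choices

There is no randomness anywhere in the core pipeline; the generator is
fully determined by its seed (separate, lineage-keyed random streams).
All outputs are sorted deterministically: gene order by (chromosome,
start, end, name), orthogroups by their lexicographically smallest
member under (speciesIndex, geneIndex) ordering, reports in input order.
Re-running any stage on identical inputs produces byte-identical files,
and the file writers round-trip exactly against the readers.

## Evaluation measures

`evaluate_against_truth` reports the fraction of planted groups (with
at least two surviving genes) recovered with exactly their planted
membership, plus precision and recall over unordered co-membership gene
pairs. The two-run comparison normalizes species labels (subgenomes to
the unsplit label) and gene names (back to annotation IDs), counts
groups with identical membership, and classifies the remaining
overlapping groups — clustered by shared genes — as *conflicting* (some
species has nonempty but different gene sets in the two runs) or
*complementary* (one run simply includes genes the other omitted). The
identical fraction is taken over the larger run's group count. The
acceptance script runs at 500 genes per diploid genome, which keeps the
full recomputation under a few seconds while leaving hundreds of groups
to measure.

## Known limitations

* Orthogroups are connected components, so one spurious edge can fuse
  two true groups; the trimming rules bound but cannot eliminate this.
* Genes that are genuinely non-syntenic (transposed copies, assembly
  artifacts) are never placed.
* The window and split thresholds (six-pair window, three Not Pass) are
  fixed constants of the method, not tunable parameters.
* Comparison of two runs requires the same underlying gene universe;
  runs over different annotation versions are rejected.
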