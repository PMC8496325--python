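# synorth

Ploidy-aware syntenic orthology networks for multiple genomes.

## The problem

When several closely related genomes are available, conserved gene
order (synteny) is powerful evidence for orthology that pure
sequence-similarity clustering ignores. Polyploidy makes similarity-only
methods struggle further: an allotetraploid carries two homoeologous
copies of most genes, breaking the 1:1 copy-number expectation that
orthogroup inference implicitly relies on.

`synorth` infers genome-wide orthogroups by combining two standard
upstream results:

* **orthogroups** from a sequence-similarity grouper (OrthoFinder-style
  `Orthogroups.tsv`), and
* **pairwise collinearity blocks** and **tandem duplicate pairs** from a
  synteny caller (MCScanX-style `.collinearity` / `.tandem` files),

together with an optional per-species table of *relative ploidy* (e.g.
2 for a tetraploid analysed alongside diploids), so that polyploid
genomes can be analysed without splitting them into subgenomes first.

## The algorithm

Four stages, all deterministic:

1. **Tethers.** Tandem duplicates are collapsed into *gene sets* (a gene
   plus all immediately neighboring tandem copies). An orthogroup
   becomes a *tether set* if at least two species contribute between 1
   and ploidy(s) gene sets; species exceeding their ploidy are excluded
   from the tether. Tethers are high-confidence orthology anchors.
2. **Scoring.** Every gene pair *(a, b)* of every collinear block is
   scored against the tethers: **Pass** if *a* and *b* share a tether;
   **Not Pass** if they sit in different tethers, or exactly one is
   tethered and its tether already contains a different gene of the
   partner's species; **No Call** otherwise. The score is symmetric, and
   intra-genome blocks (a polyploid aligned to itself) use the same
   decision tree. Blocks with fewer than two Pass scores, or more Not
   Pass than Pass, are discarded.
3. **Trimming.** Block ends are trimmed (any Not Pass more distal than
   the first Pass is cut, together with everything beyond it), a
   six-pair sliding window removes end regions where Not Pass
   accumulates, and internal runs of three or more Not Pass split the
   block in two. The rules are re-applied recursively until every
   surviving block satisfies all of them and keeps at least five pairs.
4. **Network.** A graph over all genes receives one edge per gene pair
   of every surviving block plus edges chaining every tandem array; its
   connected components (of two or more genes) are the final
   orthogroups.

Stages 1–4 live in `tethers`, `scoring`, `trimming` and `network`;
`formats_io` reads and writes every file dialect (including the
`translate` step that converts GFF3 + protein FASTA inputs to compact
`<speciesIndex>_<geneIndex>` gene names); `simulate` generates synthetic
multi-genome datasets with planted ground truth; `pipeline` and `cli`
orchestrate.

## Worked example

Generate a synthetic four-taxon dataset — three diploids and one
allotetraploid, one chromosome of 100 ancestral genes, 5% gene loss and
5% tandem duplication per lineage — then run the pipeline on it:

```sh
synorth simulate --out-dir demo/sim --seed 42 --chromosomes 1 \
    --genes-per-chromosome 100 --loss-rate 0.05 --tandem-rate 0.05
synorth run \
    --positions    demo/sim/translated/genes.gff \
    --orthogroups  demo/sim/orthogroups.tsv \
    --collinearity demo/sim/genes.collinearity \
    --tandem       demo/sim/genes.tandem \
    --translation  demo/sim/translated/name_map.tsv \
    --ploidy       demo/sim/ploidy.tsv \
    --out-prefix   demo/run
```

which prints:

```
genes	499
orthogroups_in	100
tethers	100
blocks_in	10
blocks_passing	10
blocks_surviving	10
edges	932
total_groups	100
singleton_groups	60
tether_groups	100
species_specific_groups	0
genes_in_groups	499
```

The five genomes carry 499 genes in total (starting from 5 × 100
ancestral copies, the 5% losses and 5% tandem duplications nearly
cancel), and every one of them is placed into one of 100 orthogroups —
one per ancestral gene. Every group is a *tether group* (each species
contributes at most ploidy-many singletons or tandem arrays); 60 are
*singleton groups*, meaning every diploid contributed exactly one gene
and the tetraploid exactly two — the remaining 40 groups carry a gene
loss or a tandem duplication somewhere. Full reports are written under
the prefix: `demo/run.orthogroups.tsv` (and `.named.tsv` with original
gene IDs), per-group gene and gene-set counts, the tether report,
per-block score statistics, the trim log and the used-blocks list.

To compare the ploidy-aware treatment of the tetraploid against an
a-priori subgenome split, run the same dataset with
`--split-polyploid`, pipeline both, and use
`synorth compare --run1 <prefix1> --run2 <prefix2> --species-map map.tsv
--out report.tsv`, where the species map sends both subgenome labels to
the unsplit species label.

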