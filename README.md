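# scramblekit

Comparative analysis of **scrambled genomes** from pairwise whole-genome
alignments.  Some animal genomes — the tunicate *Oikopleura dioica* is the
extreme case — conserve gene content at the chromosome-arm scale while
almost completely randomising gene order and orientation within arms.
`scramblekit` quantifies that phenomenon for anyone with a one-to-one
pairwise genome alignment, gene annotations and (optionally) an orthology
table:

* **Collinearity segmentation** under the strictest definition: chains of
  alignments uninterrupted by inversions or translocations of any length,
  partitioning the target genome exactly into *collinear alignments*,
  *bridges*, *breakpoint regions* and *isolated alignments*.
* **Scrambling index** per chromosome or arm:
  `|L_same − L_opposite| / (L_same + L_opposite)` over aligned lengths,
  averaged with full-unit-length weights — 1 means orientations fully
  conserved, 0 means orientations look random.
* **Breakpoint statistics and accumulation rates** — breakpoint regions per
  megabase aligned per million years diverged.
* **Macrosynteny blocks** from single-copy orthologs (strand-independent
  consecutive-rank runs) with size histograms and dot-plot exports.
* **Operons**: calling (same-strand runs with intergenic gaps ≤ 500 bp),
  cross-genome equivalence (exact / one-substitution-inexact, at HOG or OG
  granularity), sharing counts, breakpoint-overlap proportions and the
  operonic-status contingency test.
* **Profiles**: feature enrichment around segment boundaries and
  percent-of-chromosome-length profiles with arm-class rank tests.
* A **rearrangement simulator** that evolves annotated genomes by recorded
  inversions/translocations/duplications/deletions and emits true
  one-to-one alignments — ground truth for every stage above.

Input formats: PAF (primary) or two-species MAF alignments, GFF3 gene
models, BED feature tracks, TSV layout and ortholog tables.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a diverged genome pair (three chromosomes, ~6 Mb, ~1,500 genes,
40 rearrangement events per branch) and run the full comparison:

```sh
scramblekit simulate --seed 1 --outdir demo
scramblekit compare \
    --paf demo/A_vs_B.paf \
    --gff3-target demo/A.gff3 --gff3-query demo/B.gff3 \
    --orthologs demo/orthologs.tsv \
    --target-genome A --query-genome B \
    --divergence-time 5 \
    --outdir demo/out
```

`demo/out/report.json` then contains (abridged):

```
scrambling_index.weighted_mean   0.0715053
  per chromosome: chr1 0.147037, chr2 0.0178758, chrX 0.04546
class_coverage fractions         collinear 0.0466857, bridge 0.0275547,
                                 breakpoint 0.0331612, isolated 0.892598
breakpoints                      n 155 (2 of positive width),
                                 width mean 1264.5, SD 14936.2
breakpoint_rate                  5.58398 per Mbp aligned per My (at 5 My)
operons                          target: 259 operons, 771 operonic genes
breakpoint_overlap               operon 27/259 (0.104), gene 53/1483 (0.0357),
                                 exon 127/3740 (0.034)
synteny_blocks                   130 blocks from 1390 single-copy pairs,
                                 largest 57 genes
operonic_status                  chi2 1283.79 (df 3), p 4.9e-278
```

Reading it: after 80 events the genomes are heavily scrambled — the
weighted scrambling index has collapsed from 1.0 toward 0, and almost all
aligned sequence is *isolated* (aligned but collinear with nothing).  The
155 breakpoint regions are mostly zero-width points where rearranged
blocks abut (the simulator's default leaves no eroded sequence at event
flanks; real breakpoint regions also accumulate unalignable sequence —
see `flank_loss` in the config).  Operons overlap breakpoint regions
about three times as often as genes, and operonic genes in one genome are
overwhelmingly operonic in the other (the df = 3 chi-squared against
independent marginals), even though few operons survive as exact
orthogroup multisets.

Every stage is also a library call (`scramblekit.segment`,
`scramblekit.scrambling_index`, `scramblekit.call_operons`, ...) operating
on `AlignmentSet`, `SegmentationResult`, `Operon` and friends; the CLI is
a thin wrapper.

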