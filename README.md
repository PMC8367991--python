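# gatafam

Genus-wide analysis of GATA transcription-factor (TF) gene families from
annotated genomes: domain detection and typing, alternative-splicing
classification, domain phylogenetics with orthogroup extraction,
conservation profiling, family statistics, expression clustering and
transmembrane-helix flagging — with a seeded synthetic-genome generator
that supplies ground truth for every stage.

## Who this is for

Plant comparative genomicists running gene-family surveys of the kind
published for *Populus*, *Arabidopsis*, *Glycine* or *Oryza* GATA
factors: given several congeneric annotated genomes (FASTA + GFF3), the
package identifies family members, characterizes their splice forms and
domains, and produces the standard family tables and trees.

## The model

GATA TFs bind the DNA consensus WGATAR through a **class-IV zinc
finger**, the motif

```
C-X(2-4)-C-X(17-20)-C-X(2)-C
```

followed by a basic (K/R-rich) region. Subtypes are named by the spacer
lengths *(s1, s2, s3)* between consecutive cysteines:

| type | spacers | note |
|------|---------|------|
| IV_a | 2/17/2  | rare in plants |
| IV_b | 2/18/2  | the common plant type |
| IV_c | 2/20/2  | typical of subfamily III |
| IV_4 | 4/18/2  | subfamily II variant |
| IV_p | —       | partial tetrad, called by a log-odds profile |

The pipeline scans every protein isoform for the motif (exhaustive
cysteine-quadruple enumeration with a deterministic overlap tie-break),
classifies each gene's splice forms against its canonical isoform
(identical-protein / UTR-only / domain-loss / other), aligns domains by
their cysteine anchors, builds a neighbor-joining tree on p-distances
with bootstrap support, assigns subfamilies I–IV by proximity to labelled
anchor sequences, and extracts **gene clusters** (orthogroups): maximal
well-supported clades of in-genus members spanning most species.

## Worked example

```bash
# simulate a 4-species family with 5 planted orthogroups
gatafam simulate demo_ds --seed 13 --n-species 4 --n-clusters 5

# run the full pipeline
gatafam run demo_ds demo_out --seed 1 --min-species 3 --bootstrap 100
```

The run prints its headline summary, e.g.

```json
{
  "genus_as_ratio": 33.33,
  "motif_variability_pct": 7.35,
  "n_clusters": 5,
  "n_pc_full_coherent": 4,
  "n_tmh_bearing_tfs": 2,
  "n_unclustered": 0,
  "pc_evenness_pct": 40.0,
  ...
}
```

meaning: 33.33 % of family genes carry alternative splice forms; 7.35 %
of motif-region alignment positions vary within an orthogroup; all 5
planted orthogroups were recovered as supported clades with no leftover
genes; 4 of them are fully co-expressed blocks in the simulated FPKM
matrix; two isoforms carry a predicted transmembrane helix. `demo_out/` holds the per-stage tables (domain hits, splice
categories, domain alignment and newick tree, cluster membership,
conservation patterns, family table, type census, chromosome maps,
expression coherence, TMH spans).

Library use mirrors the CLI:

```python
from gatafam import scan_zf_motifs

hits = scan_zf_motifs("MSNRA" + "CVDCGATSTPLWRNGPRGPKSLCNACGIRQRKARRAMAEAA")
print(hits[0].type, hits[0].spacers)   # IV_b (2, 18, 2)
```

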