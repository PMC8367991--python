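# Methods

## Family identification

A protein isoform is a family member ("TF") when it carries at least one
complete class-IV zinc finger, the motif `C-X(2-4)-C-X(17-20)-C-X(2)-C`;
a gene is a member when at least one of its coding isoforms is. The
scanner enumerates every cysteine quadruple whose spacers *(s1, s2, s3)*
fall inside the bounds 2–4 / 17–20 / 2 and resolves overlapping
solutions deterministically: leftmost first cysteine wins, then the
smallest *s1*, then the smallest *s2*. The residue `X` (unknown) never
matches a cysteine. Complete hits are typed by their spacer triple
(IV_a 2/17/2, IV_b 2/18/2, IV_c 2/20/2, IV_4 4/18/2, anything else
`IV_other(s1,s2,s3)`).

The basic (K/R-rich) region downstream of the fourth cysteine is
reported as an annotation (fraction of K/R in a 15-residue window) but
never used as a membership filter: detection keys on the zinc finger
alone.

### Partial (IV_p) domains

Partial domains lack at least one cysteine of the tetrad. They are
called with a position-specific log-odds profile built from at least
five aligned complete reference domains: per-column Laplace-smoothed
frequencies against the reference background composition, `X` scoring
the background-expected column score. The calling threshold defaults to
the minimum self-score of the references minus a margin of **10 nats**.
The margin was sized to the cost of the event the call is for — losing
one cysteine from an otherwise intact domain costs roughly 6 nats
(a ~3-nat conserved-column reward replaced by a ~−3-nat mismatch) —
while random sequences of the same composition score far below any
plausible threshold (hundreds of nats down), so specificity is
insensitive to the margin. Windows containing a complete motif are never
reported as partial: the complete call wins.

This profile scheme is this package's own operationalization of
partial-domain detection; published surveys obtain IV_p calls from
external domain-annotation services whose score cutoffs and post-filters
are not printed, so thresholds here are documented package parameters
rather than reproductions.

## Splice-form classification

The canonical isoform of a gene is its longest protein (ties broken by
lexicographically smallest transcript ID). Every other coding isoform
receives one category, tested in order:

1. **identical_protein** — encodes exactly the canonical protein. If its
   CDS intervals equal the canonical's and only exon/UTR structure
   differs, a `utr_only` flag is set: splicing confined to untranslated
   regions. (In genomic coordinates an identical CDS always implies an
   identical protein, so the UTR-only situation is reported through this
   flag rather than as a separate category.)
2. **utr_only_variant** — identical CDS intervals but a different exon
   set, kept for completeness of the contract.
3. **domain_loss** — the canonical isoform has a domain, this isoform
   has none (a putative negative regulator that can compete for binding
   sites without activating transcription).
4. **other** — any remaining difference.

Genes whose isoforms all lack the domain are excluded from the family;
domain-less isoforms of member genes count as the member's splice forms.
Per-species summaries report A (member genes), the TF count, B (members
with ≥ 2 coding isoforms), the ratio 100·B/A and the average number of
forms among spliced genes. The genus-level ratio sums B over all species
but can exclude species from the gene-count denominator, reproducing the
mixed-denominator convention of published family tables in which a
species without any splice forms is dropped from the total. All
percentages are rounded half-up to two decimals, matching printed table
precision.

## Domain alignment and phylogeny

Domains are aligned by their cysteine anchors rather than by an
optimizing aligner: the four cysteines are forced into common columns;
within each spacer, gaps are right-justified (inserted immediately
before the next cysteine); seven upstream and twenty-five downstream
flanking residues are included and end-gap padded. For this motif family
the anchor construction is exact, deterministic, and keeps column
semantics fixed across runs. Partial domains cannot be anchor-aligned
and are excluded from trees and conservation profiles.

Distances are p-distances (mismatches over comparable columns, pairwise
deletion of gaps). Trees are classic Saitou–Nei neighbor joining with
two documented conventions: Q-matrix ties break to the smallest
(row, column) index pair, and a negative branch length is clamped to
zero with the deficit transferred to the sister edge. Bootstrap support
resamples alignment columns with replacement (seeded generator; default
1000 replicates at desk scale, configurable upward) and reports, per
internal edge of the reference tree, the percentage of replicate trees
containing the same bipartition.

**Subfamily assignment.** Anchor sequences with known subfamily labels
(I–IV) are placed in the same tree; each member takes the subfamily of
its nearest anchor by patristic distance, with exact ties (relative
tolerance 1e−9) reported as `unresolved`.

**Gene clusters (orthogroups).** After midpoint rooting, a clade
qualifies as a cluster when all its tips are in-genus (no anchors), it
spans at least `min_species` distinct species (default 5 of 7), and its
bootstrap support is at least `min_support` (default 50 %). Only
maximal qualifying clades are reported; the tree root itself never
qualifies. Remaining members are listed as unclustered
(species-specific genes). Clusters are numbered PC01… by subfamily
(order III, II, I, IV) and, within a subfamily, by preorder position —
a labelling convention, not a biological claim.

## Conservation profiling

For any member group (cluster, subfamily, genus) the per-column count of
distinct non-gap residues is recorded together with the majority residue
(ties resolved alphabetically); all-gap columns print as `.`. The
motif-region variability statistic sums, over per-cluster pattern rows,
the non-gap positions inside the C…C tetrad and reports the percentage
with more than one residue. Group-versus-group comparisons flag columns
100 % conserved in each group and whether the conserved residues agree;
columns conserved to *different* residues in two groups are marked
subfamily-diagnostic.

## Family statistics

The family table aggregates the per-species splicing records and, when
whole-genome gene totals are available, the family proportion
100·A/total. The domain-type census is TF-level (one representative
type per isoform: its best-scoring hit), matching the convention in
which census denominators count TFs rather than genes. A cluster is
"even" when it covers every analysed species with the same member
count. Chromosome maps pool unplaced-scaffold genes under `ChrUn` and
report density as genes per Mb. The species-level PCA standardizes a
documented default set of 19 characteristics (length and exon/isoform
summaries, splicing ratio, type and subfamily fractions, domain
placement, `ChrUn` fraction, counts, basic-region composition — a
surrogate feature set, since published survey PCAs do not enumerate
their characteristics), drops constant features, and fixes signs so
each component's largest-magnitude loading is positive.

## Expression

FPKM matrices are log2(x+1)-transformed by default (raw values can be
kept) and genes are clustered with agglomerative hierarchical clustering
(euclidean/complete by default, correlation and average linkage
available) via scipy, whose deterministic merge ordering serves as the
tie-break rule. The dendrogram is cut into *k* flat clusters (default:
the number of gene clusters with ≥ 2 expressed members — published
heatmap boxes are drawn by eye, so a flat cut is the reproducible
surrogate); each gene cluster is labelled `full` when all expressed
members share one flat cluster, `partial` when at least two do, `none`
otherwise, `not_assessable` below two expressed members.

## Transmembrane helices

A sliding Kyte–Doolittle window (default 19 residues, centered, ends
undefined) flags maximal runs of window means ≥ 1.6 of length ≥ 15 as
candidate transmembrane helices, marking putative membrane-bound TFs.
This hydropathy method is a deliberately simple, fully documented
predictor; spans produced by a dedicated external predictor can be
imported from TSV for real-data runs. Counts are per isoform.

## Synthetic data generator

The generator emulates the data regime of a seven-genome genus survey:
21 orthologous clusters, one or two genes per species per cluster
(paralog probability 0.5, giving ~30–40 family genes per species), a
domain-type mix of 70 % IV_b / 26 % IV_c / 4 % IV_4, four tissue
conditions, 19 chromosomes with a 3 % unplaced-scaffold fraction, and a
1.5 % membrane-protein fraction. Cluster ancestors diverge from
handcrafted subfamily consensus templates (drift 0.15), members diverge
from a shared genus ancestor (stem 0.15 below the cluster ancestor,
then a per-gene mutation rate, default 0.02), and every cluster gets an
out-genus anchor ortholog (drift 0.08 from the cluster ancestor) plus
one deep anchor per subfamily. The stem/anchor structure mirrors how a
reference species' members scatter through a real family tree and is
what makes planted clusters monophyletic with their anchor as sister.

Mutations never touch the four cysteines or the subfamily-diagnostic
template residues, so planted type and subfamily labels remain
well-defined truth; a separate degrade mode substitutes the fourth
cysteine to serine to create IV_p truth. Splice variants are planted as:
UTR-boundary changes (identical CDS), frame-preserving intron slides
(different CDS intervals, identical protein — the slide copies the
3 bp at the intron start from the downstream exon), skipping of the
codon-aligned domain exon (domain loss), and truncation of the final
coding exon (other). Expression is a Gaussian copula per cluster
(within-block correlation 0.9, between 0.0 by default) with exponential
marginals scaled per cluster. Everything derives from a single seeded
generator: identical seeds give byte-identical output files.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: background sequence is cysteine-free (the
planted motif is the only occurrence, so scanner recall on synthetic
data says nothing about paralogous near-motifs), introns are phase-0
(codon-aligned exon boundaries make exon skipping trivially
frame-preserving), there are no indels, no codon-usage bias, no
heterogeneous annotation dialects, and anchors exist for every cluster
(real reference sets cover clusters unevenly).

## Numerical and scale choices

Percentages print half-up at two decimals. Internal coordinates are
0-based half-open; GFF3 I/O converts to and from 1-based inclusive.
Test-suite and acceptance runs use desk-scale problem sizes chosen to
exercise every code path on one CPU in minutes: families of 4–7 species
and 3–21 clusters, 50 bootstrap replicates inside recovery loops (the
50 % support threshold does not need tighter resolution), 20 seeded
families for the orthogroup-recovery rate, and 12 expression conditions
in the block-recovery test (with only four conditions, 21 random block
centroids are not geometrically separable, which is also why real
four-tissue heatmaps show only partial cluster coherence).

## Known limitations

Anchor alignment assumes the complete tetrad; surveys with many partial
domains would need a profile-based aligner. The clade-extraction rule
depends on anchors interleaving the family tree; with sparse anchors,
adjacent orthogroups can merge into one maximal clade. The PCA feature
set and the expression flat-cut rule are surrogates for choices that
published surveys made manually or did not document. No attempt is made
to normalize heterogeneous annotation versions beyond GFF3 parsing.
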