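"""Alternative-splicing form classification and family splicing statistics.

Each coding isoform of a family gene is placed in one category relative
to the gene's canonical isoform (the longest protein, ties by transcript
ID):

* ``identical_protein`` — encodes exactly the canonical protein; when the
  CDS intervals also match and only exon/UTR structure differs, the
  ``utr_only`` flag is set (splicing confined to untranslated regions);
* ``utr_only_variant``  — identical CDS intervals but different exon set
  (only reachable for coordinate-free corner cases; kept for completeness);
* ``domain_loss``       — the canonical isoform carries a zinc-finger
  domain but this isoform has none (putative negative regulator);
* ``other``             — any remaining difference.

Genes whose isoforms all lack the domain are not family members; a gene
with at least one domain-bearing isoform is, and its domain-less isoforms
count as the member's splice forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from ._util import round_half_up
from .genome_io import GeneModel

CATEGORIES = ("canonical", "identical_protein", "utr_only_variant", "domain_loss", "other")


@dataclass
class SpliceProfile:
    gene_id: str
    n_isoforms: int
    categories: dict  # isoform_id -> category
    utr_only_flags: dict  # isoform_id -> bool
    n_domain_bearing: int
    canonical: str


def classify_isoforms(gene: GeneModel, hits_by_isoform: Mapping[str, Sequence]) -> SpliceProfile:
    """Classify every coding isoform of one gene against its canonical form.

    ``hits_by_isoform`` maps transcript IDs to their DomainHit lists.
    """
    coding = gene.coding_transcripts
    if not coding:
        raise ValueError(f"gene {gene.gene_id} has no coding isoform")
    canonical = max(coding, key=lambda t: (len(t.protein), _neg_id(t.transcript_id)))
    can_domain = bool(hits_by_isoform.get(canonical.transcript_id))
    categories = {canonical.transcript_id: "canonical"}
    flags = {canonical.transcript_id: False}
    have_coords = bool(canonical.exons) and canonical.exons != canonical.cds
    for t in coding:
        if t is canonical:
            continue
        same_cds = set(t.cds) == set(canonical.cds)
        same_exons = set(t.exons) == set(canonical.exons)
        if t.protein == canonical.protein:
            cat = "identical_protein"
            flags[t.transcript_id] = bool(have_coords and same_cds and not same_exons)
        elif same_cds and not same_exons:
            cat = "utr_only_variant"
            flags[t.transcript_id] = True
        elif can_domain and not hits_by_isoform.get(t.transcript_id):
            cat = "domain_loss"
            flags[t.transcript_id] = False
        else:
            cat = "other"
            flags[t.transcript_id] = False
        categories[t.transcript_id] = cat
    n_domain = sum(1 for t in coding if hits_by_isoform.get(t.transcript_id))
    return SpliceProfile(
        gene_id=gene.gene_id,
        n_isoforms=len(coding),
        categories=categories,
        utr_only_flags=flags,
        n_domain_bearing=n_domain,
        canonical=canonical.transcript_id,
    )


def _neg_id(s: str):
    # invert lexicographic order so max() prefers the smaller ID on ties
    return tuple(-ord(c) for c in s)


def is_family_member(gene: GeneModel, hits_by_isoform: Mapping[str, Sequence]) -> bool:
    """Member iff at least one coding isoform carries a domain hit."""
    return any(hits_by_isoform.get(t.transcript_id) for t in gene.coding_transcripts)


@dataclass
class SpeciesASRecord:
    """Per-species splicing summary (one row of the family table)."""

    species: str
    n_genes: int  # A: family (domain-bearing) genes
    n_tfs: int  # coding isoforms of member genes
    n_genes_as: int  # B: members with >=2 coding isoforms
    n_tfs_as: int  # isoforms belonging to those B genes
    ratio: float = field(init=False)  # 100*B/A
    avg_forms: Optional[float] = field(init=False)  # n_tfs_as / B

    def __post_init__(self):
        if self.n_genes == 0:
            raise ValueError(f"no family members for species {self.species!r}")
        self.ratio = round_half_up(100.0 * self.n_genes_as / self.n_genes)
        self.avg_forms = (
            round_half_up(self.n_tfs_as / self.n_genes_as) if self.n_genes_as else None
        )


def species_as_summary(
    genes: Sequence[GeneModel], hits_by_isoform: Mapping[str, Sequence]
) -> SpeciesASRecord:
    """Summarize alternative splicing over one species' family genes."""
    members = [g for g in genes if is_family_member(g, hits_by_isoform)]
    if not members:
        raise ValueError("no family members")
    species = members[0].species
    n_tfs = sum(len(g.coding_transcripts) for g in members)
    with_as = [g for g in members if len(g.coding_transcripts) >= 2]
    n_tfs_as = sum(len(g.coding_transcripts) for g in with_as)
    return SpeciesASRecord(
        species=species,
        n_genes=len(members),
        n_tfs=n_tfs,
        n_genes_as=len(with_as),
        n_tfs_as=n_tfs_as,
    )


def genus_as_ratio(
    summaries: Iterable[SpeciesASRecord], exclude: Sequence[str] = ()
) -> float:
    """Genus-level AS ratio: 100 * sum(B, all species) / sum(A, non-excluded).

    ``exclude`` removes species from the denominator only, reproducing the
    mixed-denominator convention of the published family table (species
    without any splice forms can be dropped from the gene total).
    """
    summaries = list(summaries)
    num = sum(s.n_genes_as for s in summaries)
    den = sum(s.n_genes for s in summaries if s.species not in set(exclude))
    if den == 0:
        raise ValueError("empty denominator after exclusions")
    return round_half_up(100.0 * num / den)


def profiles_table(profiles: Iterable[SpliceProfile]):
    """Per-isoform classification as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for p in profiles:
        for iso, cat in sorted(p.categories.items()):
            rows.append(
                {
                    "gene_id": p.gene_id,
                    "isoform_id": iso,
                    "category": cat,
                    "utr_only": p.utr_only_flags.get(iso, False),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "isoform_id", "category", "utr_only"])
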