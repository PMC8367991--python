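"""Family-level summary statistics: family table, domain-type census,
cluster evenness, chromosomal distribution, and a species-level PCA."""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .domain_scan import DomainHit, best_hit
from .genome_io import GeneModel, report_chromosome
from .phylo import GeneCluster
from .splice_analysis import SpeciesASRecord

log = logging.getLogger(__name__)


def family_summary(
    records: Sequence[SpeciesASRecord],
    genome_gene_totals: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """The family characteristics table: one row per species.

    Columns mirror the published layout: gene count (A), TF count (coding
    isoforms of members), genes/TFs with alternative splicing (B), the AS
    ratio 100*B/A, and — when whole-genome gene totals are supplied — the
    family proportion 100*A/genome_total.
    """
    rows = []
    for r in records:
        row = {
            "species": r.species,
            "n_genes": r.n_genes,
            "n_tfs": r.n_tfs,
            "n_genes_as": r.n_genes_as,
            "n_tfs_as": r.n_tfs_as,
            "as_ratio": r.ratio,
            "avg_as_forms": r.avg_forms,
        }
        if genome_gene_totals is not None:
            total = genome_gene_totals.get(r.species)
            if total:
                row["family_proportion"] = family_proportion(r.n_genes, total)
        rows.append(row)
    if genome_gene_totals is None:
        log.warning("no genome gene totals supplied; proportion column omitted")
    return pd.DataFrame(rows)


def family_proportion(n_family_genes: int, genome_gene_total: int) -> float:
    """Family share of the annotated gene complement, percent, 2 decimals."""
    if genome_gene_total <= 0:
        raise ValueError("genome gene total must be positive")
    return round_half_up(100.0 * n_family_genes / genome_gene_total)


def census_percentages(counts: Mapping[str, int]) -> pd.DataFrame:
    """Counts and percentages per domain type over all family TFs."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty census")
    df = pd.DataFrame(
        {
            "type": list(counts),
            "count": list(counts.values()),
        }
    )
    df["percentage"] = [round_half_up(100.0 * c / total) for c in df["count"]]
    return df.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)


def domain_type_census(hits_by_isoform: Mapping[str, Sequence[DomainHit]]) -> pd.DataFrame:
    """TF-level census: each TF contributes the type of its best hit."""
    counts: Counter = Counter()
    for hits in hits_by_isoform.values():
        h = best_hit(hits)
        if h is not None:
            counts[h.type] += 1
    return census_percentages(counts)


def pc_evenness(
    clusters: Sequence[GeneCluster], all_species: Sequence[str]
) -> tuple:
    """(n_even, n_total, percentage): a cluster is even iff it covers every
    analysed species with the same member count."""
    if not clusters:
        raise ValueError("no clusters")
    allsp = set(all_species)
    n_even = 0
    for cl in clusters:
        if set(cl.species_counts) == allsp and len(set(cl.species_counts.values())) == 1:
            n_even += 1
    return n_even, len(clusters), round_half_up(100.0 * n_even / len(clusters))


def chromosome_distribution(
    genes: Sequence[GeneModel],
    chromosome_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per-chromosome gene counts and density (genes per Mb).

    Unplaced genes pool under "ChrUn" (no density).  A placed gene on a
    chromosome absent from ``chromosome_lengths`` is an error when lengths
    are supplied.
    """
    counts: Counter = Counter()
    for g in genes:
        counts[report_chromosome(g)] += 1
    if chromosome_lengths is not None:
        for g in genes:
            if g.placed and g.chromosome not in chromosome_lengths:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chromosome!r}")
        for chrom in chromosome_lengths:
            counts.setdefault(chrom, 0)
    rows = []
    for chrom in sorted(counts):
        length = (chromosome_lengths or {}).get(chrom)
        density = counts[chrom] / (length / 1e6) if length else None
        rows.append(
            {"chromosome": chrom, "count": counts[chrom], "length": length, "density": density}
        )
    return pd.DataFrame(rows)


def species_feature_pca(feature_table: pd.DataFrame) -> dict:
    """PCA of species-level gene-family characteristics.

    Features are standardized (zero mean, unit variance) before the
    decomposition; constant features are dropped with a warning.  The sign
    convention makes each component's largest-magnitude loading positive.
    Returns coordinates (first two components), loadings, and variance
    fractions of all components.
    """
    if feature_table.shape[0] < 3:
        raise ValueError("need at least 3 species")
    X = feature_table.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = list(feature_table.columns[~keep])
        log.warning("dropped constant feature(s): %s", dropped)
    X = X[:, keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 non-constant features")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        imax = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, imax] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    coords = U * S
    return {
        "coordinates": pd.DataFrame(
            coords[:, :2], index=feature_table.index, columns=["PC1", "PC2"]
        ),
        "loadings": pd.DataFrame(
            Vt, columns=feature_table.columns[keep],
            index=[f"PC{k+1}" for k in range(Vt.shape[0])],
        ),
        "variance_fractions": frac,
    }


def default_feature_table(
    genes_by_species: Mapping[str, Sequence[GeneModel]],
    hits_by_isoform: Mapping[str, Sequence[DomainHit]],
    subfamily_of_gene: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """A documented default set of 19 species-level characteristics.

    Length/structure summaries, splice statistics, domain-type fractions,
    subfamily fractions, domain placement and basic-region composition —
    a surrogate feature set standing in for unpublished per-gene metrics.
    """
    from .splice_analysis import is_family_member, species_as_summary

    rows = {}
    for sp, genes in genes_by_species.items():
        members = [g for g in genes if is_family_member(g, hits_by_isoform)]
        isoforms = [t for g in members for t in g.coding_transcripts]
        plens = np.array([len(t.protein) for t in isoforms], dtype=float)
        exoncounts = np.array([len(t.exons) for t in isoforms], dtype=float)
        summ = species_as_summary(genes, hits_by_isoform)
        pairs = [
            (best_hit(hits_by_isoform.get(t.transcript_id, [])), t) for t in isoforms
        ]
        pairs = [(b, t) for b, t in pairs if b is not None]
        best = [b for b, _ in pairs]
        typecounts = Counter(b.type if not b.type.startswith("IV_other") else "IV_other" for b in best)
        ntf = max(len(best), 1)
        starts = [b.start / max(len(t.protein), 1) for b, t in pairs]
        basics = [b.basic_fraction for b in best if b.basic_fraction is not None]
        subcounts: Counter = Counter()
        if subfamily_of_gene:
            for g in members:
                subcounts[subfamily_of_gene.get(g.gene_id, "")] += 1
        nmem = max(len(members), 1)
        rows[sp] = {
            "mean_protein_length": plens.mean() if plens.size else 0.0,
            "median_protein_length": float(np.median(plens)) if plens.size else 0.0,
            "mean_exon_count": exoncounts.mean() if exoncounts.size else 0.0,
            "mean_isoform_count": len(isoforms) / nmem,
            "as_ratio": summ.ratio,
            "frac_IV_a": typecounts.get("IV_a", 0) / ntf,
            "frac_IV_b": typecounts.get("IV_b", 0) / ntf,
            "frac_IV_c": typecounts.get("IV_c", 0) / ntf,
            "frac_IV_4": typecounts.get("IV_4", 0) / ntf,
            "frac_IV_p": typecounts.get("IV_p", 0) / ntf,
            "frac_sub_I": subcounts.get("I", 0) / nmem,
            "frac_sub_II": subcounts.get("II", 0) / nmem,
            "frac_sub_III": subcounts.get("III", 0) / nmem,
            "frac_sub_IV": subcounts.get("IV", 0) / nmem,
            "mean_domain_start_frac": float(np.mean(starts)) if starts else 0.0,
            "chrun_fraction": sum(1 for g in members if not g.placed) / nmem,
            "gene_count": len(members),
            "tf_count": len(isoforms),
            "mean_basic_fraction": float(np.mean(basics)) if basics else 0.0,
        }
    return pd.DataFrame(rows).T
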