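"""Published genus-survey count tables, bundled as inputs.

These are the printed per-species characteristics of the seven-genome
*Populus* GATA TF survey (gene/TF/alternative-splicing counts and
whole-genome gene totals), the genus domain-type census, the gene-cluster
(PC) composition and the motif-region variability tally.  They let the
summary-statistics operations be exercised on the real survey's
arithmetic without redistributing any genome data.
"""

from __future__ import annotations

import pandas as pd

from .phylo import GeneCluster
from .splice_analysis import SpeciesASRecord

#: species, family genes (A), family TFs, genes with AS (B), TFs with AS,
#: whole-genome gene total
POPULUS_FAMILY_TABLE = pd.DataFrame(
    [
        ("P. trichocarpa", 39, 67, 13, 41, 42950),
        ("P. pruinosa", 37, 37, 0, 0, 35131),
        ("P. euphratica", 40, 55, 9, 24, 30688),
        ("P. deltoides", 38, 55, 7, 24, 44853),
        ("P. tremuloides", 37, 44, 7, 14, 36830),
        ("P. tremula", 33, 60, 16, 43, 35309),
        ("P. tremula x alba", 38, 71, 16, 49, 41335),
    ],
    columns=["species", "n_genes", "n_tfs", "n_genes_as", "n_tfs_as", "genome_genes"],
)

#: genus-wide TF-level domain-type census (389 TFs)
POPULUS_TYPE_CENSUS = {"IV_b": 272, "IV_c": 102, "IV_4": 8, "IV_p": 7}

#: motif-region variability tally over the per-PC pattern rows
POPULUS_MOTIF_VARIABILITY = {"variable": 23, "total": 556}

_SPECIES = list(POPULUS_FAMILY_TABLE["species"])


def family_records() -> list:
    """The published family table as per-species splicing records."""
    return [
        SpeciesASRecord(
            species=r.species,
            n_genes=r.n_genes,
            n_tfs=r.n_tfs,
            n_genes_as=r.n_genes_as,
            n_tfs_as=r.n_tfs_as,
        )
        for r in POPULUS_FAMILY_TABLE.itertuples()
    ]


def genome_gene_totals() -> dict:
    return dict(zip(POPULUS_FAMILY_TABLE["species"], POPULUS_FAMILY_TABLE["genome_genes"]))


def populus_gene_clusters() -> list:
    """The 21 published gene clusters (PCs) as composition records.

    Eleven PCs hold the same gene count in every species (PC01 with four
    genes per species, the rest with one); PC11 spans five of the seven
    species; PC03/PC05/PC14 each lack one species' gene; PC12/PC20 carry
    one extra gene in one species; the remaining four PCs show mixed
    counts.  Member IDs are synthesized from the composition — only the
    per-species counts matter for evenness statistics.
    """
    comps: list[tuple[str, dict]] = []
    even_counts = [4] + [1] * 10  # PC01 carries four genes per species
    names = iter(f"PC{k:02d}" for k in range(1, 22))
    specs: list[dict] = []
    for c in even_counts:
        specs.append({sp: c for sp in _SPECIES})
    specs.append({sp: 1 for sp in _SPECIES if sp not in ("P. tremuloides", "P. tremula")})
    for missing in ("P. pruinosa", "P. tremula", "P. deltoides"):
        specs.append({sp: 1 for sp in _SPECIES if sp != missing})
    for extra in ("P. deltoides", "P. euphratica"):
        specs.append({sp: (2 if sp == extra else 1) for sp in _SPECIES})
    for k in range(4):  # mixed-count clusters
        d = {sp: 1 for sp in _SPECIES}
        d[_SPECIES[k]] = 2
        d[_SPECIES[(k + 1) % len(_SPECIES)]] = 3
        specs.append(d)
    for spec in specs:
        comps.append((next(names), spec))
    clusters = []
    for pc_id, counts in comps:
        members = [f"{sp}:{pc_id}:{i}" for sp, c in counts.items() for i in range(c)]
        clusters.append(
            GeneCluster(pc_id=pc_id, members=members, species_counts=dict(counts), support=None)
        )
    return clusters


def populus_species() -> list:
    return list(_SPECIES)
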