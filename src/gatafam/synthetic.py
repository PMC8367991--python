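"""Seeded generator of multi-species toy genomes with a planted
zinc-finger TF family, providing ground truth for every pipeline stage.

The generator emulates the data regime of a genus-wide TF-family survey:
~20 orthologous gene clusters across 7 species (a few tens of family
genes per species), planted class-IV zinc-finger domains with a realistic
type mix, alternative-splicing variants confined to UTRs or dropping the
domain exon, occasional transmembrane helices, chromosomal placement with
a small unplaced-scaffold fraction, and a tissue-expression matrix with
per-cluster block correlation.

Simplifications relative to real genomes (documented in the methods
note): background protein sequence is cysteine-free, so planted domains
are the only motif occurrences; exon boundaries are codon-aligned
(phase-0 introns) so exon skipping is frame-preserving; no indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import as_rng
from .genome_io import GeneModel, TranscriptModel, write_fasta, write_gff3

# residues used for non-domain protein sequence: no C (keeps the planted
# tetrad the unique motif occurrence) and none of the strongly
# hydrophobic residues that could mimic a TMH by chance
BACKGROUND_AA = "ADEGHKNPQRSTY"
SUBST_AA = "ADEFGHIKLMNPQRSTVWY"  # mutation targets: everything but C
TMH_AA = "ILVF"
NT = "ACGT"

CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}

# subfamily consensus templates for the domain neighbourhood:
# flank5(7) C s1(<=4) C s2(<=20) C s3(2) C flank3(25)
_BASE = {
    "flank5": "NPSSVLS",
    "s1": "SNAG",
    "s2": "TTTLWRRNAEGGPVSKRARV",
    "s3": "NA",
    "flank3": "KRRSKARRQAGTSLVEPSSAGSGNV",
}
# fixed per-subfamily residues (conserved, mutation-protected); subfamily
# III swaps the diagnostic W/G pair for M/E
SUBFAMILY_EDITS = {
    "I": {("s2", 1): "S", ("flank3", 7): "K", ("s2", 13): "A", ("flank5", 5): "M",
          ("flank3", 18): "T", ("s2", 18): "K", ("flank3", 11): "S", ("flank5", 2): "G",
          ("flank3", 23): "D", ("s2", 10): "N"},
    "II": {("flank5", 1): "T", ("s1", 1): "T", ("s2", 8): "V", ("s2", 11): "D",
           ("s2", 15): "T", ("flank3", 6): "N", ("flank3", 12): "E", ("flank3", 20): "S",
           ("flank5", 4): "E", ("s2", 0): "S"},
    "III": {("s2", 4): "M", ("flank3", 2): "E", ("s2", 2): "P", ("s2", 17): "S",
            ("flank5", 3): "I", ("flank3", 9): "Q", ("flank3", 15): "N", ("s2", 12): "T",
            ("flank3", 21): "E", ("s2", 7): "G"},
    "IV": {("flank5", 0): "T", ("s1", 0): "A", ("s2", 6): "K", ("s2", 9): "S",
           ("s2", 18): "I", ("flank3", 4): "D", ("flank3", 17): "G", ("flank3", 22): "T",
           ("flank5", 6): "A", ("s2", 14): "E"},
}
SUBFAMILIES = ("I", "II", "III", "IV")

TYPE_SPACERS = {"IV_a": (2, 17, 2), "IV_b": (2, 18, 2), "IV_c": (2, 20, 2), "IV_4": (4, 18, 2)}


def subfamily_template(subfamily: str) -> dict:
    tpl = {k: list(v) for k, v in _BASE.items()}
    for (region, idx), aa in SUBFAMILY_EDITS[subfamily].items():
        tpl[region][idx] = aa
    return {k: "".join(v) for k, v in tpl.items()}


def mutate_sequence(
    seq: str,
    rate: float,
    protected: set = frozenset(),
    seed=0,
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
) -> str:
    """Per-site substitution to a uniform random *different* residue with
    probability ``rate``, never at protected positions.  Seeded."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = as_rng(seed)
    out = list(seq)
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        if i in protected:
            continue
        choices = [a for a in alphabet if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


@dataclass
class SimConfig:
    """Study-regime defaults: 7 species, 21 clusters, type mix matching a
    plant GATA family census, 4 tissues."""

    n_species: int = 7
    n_clusters: int = 21
    paralog_prob: float = 0.5  # cluster carries 2 genes per species
    species_dropout: float = 0.03  # a species missing from a cluster
    domain_type_mix: dict = field(
        default_factory=lambda: {"IV_a": 0.0, "IV_b": 0.70, "IV_c": 0.26, "IV_4": 0.04}
    )
    mutation_rate: float = 0.02  # per-site, outside protected positions
    cluster_drift: float = 0.15  # template -> cluster ancestor divergence
    as_spec: dict = field(
        default_factory=lambda: {
            "utr_only": 0.18, "identical_protein": 0.10,
            "domain_loss": 0.08, "other": 0.08,
        }
    )
    degrade_fraction: float = 0.0  # genes given a C4->S partial (IV_p) domain
    anchor_prob: float = 1.0  # cluster has an out-genus anchor ortholog
    anchor_drift: float = 0.08  # cluster ancestor -> anchor divergence
    stem_drift: float = 0.15  # cluster ancestor -> genus ancestor (shared by members)
    tmh_fraction: float = 0.015
    chrom_count: int = 19
    chrom_length: Optional[int] = None  # None: auto-sized; too short -> error
    unplaced_fraction: float = 0.03
    n_conditions: int = 4
    expression_block_corr: tuple = (0.9, 0.0)  # (within, between)
    seed: int = 1

    def __post_init__(self):
        mix = sum(self.domain_type_mix.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError("domain_type_mix must sum to 1")
        for k, v in {**self.as_spec, "tmh": self.tmh_fraction,
                     "dropout": self.species_dropout, "mut": self.mutation_rate}.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"probability {k}={v} outside [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticFamily:
    """Generator output: gene models, sequences and the truth ledger."""

    config: SimConfig
    species: list
    genes_by_species: dict  # species -> list[GeneModel]
    genomes: dict  # species -> {chrom: sequence}
    proteins: dict  # isoform_id -> protein
    expression: pd.DataFrame  # genes x conditions (FPKM)
    truth_genes: pd.DataFrame
    truth_isoforms: pd.DataFrame
    anchors: list  # (anchor_id, protein, subfamily)

    def all_genes(self) -> list:
        return [g for sp in self.species for g in self.genes_by_species[sp]]

    def write(self, outdir) -> dict:
        """Emit FASTA/GFF3/CSV/TSV files; returns the path map."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for sp in self.species:
            fa = os.path.join(outdir, f"{sp}_genome.fasta")
            gff = os.path.join(outdir, f"{sp}_annotation.gff3")
            write_fasta(sorted(self.genomes[sp].items()), fa)
            write_gff3(self.genes_by_species[sp], gff)
            paths[sp] = {"fasta": fa, "gff3": gff}
        prot = os.path.join(outdir, "proteins.fasta")
        write_fasta(sorted(self.proteins.items()), prot)
        expr = os.path.join(outdir, "expression.csv")
        self.expression.to_csv(expr)
        tg = os.path.join(outdir, "truth_genes.tsv")
        ti = os.path.join(outdir, "truth_isoforms.tsv")
        self.truth_genes.to_csv(tg, sep="\t", index=False)
        self.truth_isoforms.to_csv(ti, sep="\t", index=False)
        anc = os.path.join(outdir, "anchors.fasta")
        write_fasta([(f"{a}|{s}", p) for a, p, s in self.anchors], anc)
        paths.update(
            proteins=prot, expression=expr, truth_genes=tg, truth_isoforms=ti, anchors=anc
        )
        return paths


def _protected_positions(subfamily: str, spacers: tuple, nflank_len: int) -> set:
    """Protein positions never mutated: the cysteine tetrad plus the
    subfamily-diagnostic template residues, mapped onto the protein."""
    s1, s2, s3 = spacers
    c1 = nflank_len
    c2 = c1 + 1 + s1
    c3 = c2 + 1 + s2
    c4 = c3 + 1 + s3
    prot = {c1, c2, c3, c4}
    for (region, idx), _ in SUBFAMILY_EDITS[subfamily].items():
        if region == "flank5":
            p = nflank_len - 7 + idx
        elif region == "s1":
            p = c1 + 1 + idx
        elif region == "s2":
            p = c2 + 1 + idx
        elif region == "s3":
            p = c3 + 1 + idx
        else:  # flank3
            p = c4 + 1 + idx
        if region in ("s1", "s2") and idx >= (s1 if region == "s1" else s2):
            continue  # template residue truncated away at this type
        if 0 <= p:
            prot.add(p)
    return prot


def _domain_sequence(tpl: dict, spacers: tuple) -> str:
    s1, s2, s3 = spacers
    return "C" + tpl["s1"][:s1] + "C" + tpl["s2"][:s2] + "C" + tpl["s3"][:s3] + "C"


def _random_aa(rng, n: int) -> str:
    return "".join(BACKGROUND_AA[i] for i in rng.integers(len(BACKGROUND_AA), size=n))


def _random_nt(rng, n: int) -> str:
    return "".join(NT[i] for i in rng.integers(len(NT), size=n))


def _reverse_translate(rng, protein: str) -> str:
    return "".join(CODONS[a][rng.integers(len(CODONS[a]))] for a in protein)


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _subfamily_allocation(n_clusters: int) -> list:
    """Roughly family-like proportions: I largest, IV a single cluster."""
    counts = {
        "III": max(1, round(0.20 * n_clusters)),
        "II": max(1, round(0.24 * n_clusters)),
        "IV": 1,
    }
    counts["I"] = n_clusters - sum(counts.values())
    alloc = []
    for sf in SUBFAMILIES:
        alloc += [sf] * counts.get(sf, 0)
    return alloc[:n_clusters]


def make_anchors(n_per_subfamily: int = 3, seed: int = 7, drift: float = 0.03) -> list:
    """Reference (out-genus) anchor proteins with known subfamily labels,
    one small protein around each subfamily's consensus domain."""
    rng = as_rng(seed)
    anchors = []
    for sf in SUBFAMILIES:
        tpl = subfamily_template(sf)
        spacers = TYPE_SPACERS["IV_c" if sf == "III" else "IV_b"]
        for k in range(n_per_subfamily):
            nflank = _random_aa(rng, 30 if sf == "IV" else 80)[:-7] + tpl["flank5"]
            dom = _domain_sequence(tpl, spacers)
            tail = tpl["flank3"] + _random_aa(rng, 20)
            prot = nflank + dom + tail
            protected = _protected_positions(sf, spacers, len(nflank))
            prot = mutate_sequence(prot, drift, protected, rng, alphabet=SUBST_AA)
            anchors.append((f"anchor_{sf}_{k+1}", prot, sf))
    return anchors


class _GeneBuilder:
    """Assembles one gene region (transcript-forward) with its isoforms."""

    def __init__(self, rng, gene_id: str, protein: str, domain_span: tuple,
                 variants: Sequence[str]):
        self.rng = rng
        self.gene_id = gene_id
        self.protein = protein
        self.ds, self.de = domain_span  # codon-aligned domain exon bounds
        self.variants = list(variants)
        self._build()

    def _build(self):
        rng = self.rng
        L = len(self.protein)
        cds_nt = _reverse_translate(rng, self.protein) + "TAA"
        # coding-exon split points (codon indices); domain kept in one exon
        splits = {self.ds, self.de} if self.de < L else {self.ds}
        extra_candidates = [c for c in range(2, L - 1)
                            if not (self.ds < c < self.de) and c not in splits]
        if extra_candidates and rng.random() < 0.5:
            splits.add(int(rng.choice(extra_candidates)))
        splits = sorted(s for s in splits if 0 < s < L)
        bounds = [0] + splits + [L + 1]  # codon units, stop codon in last exon
        u5 = int(rng.integers(60, 150))
        u3 = int(rng.integers(60, 150))
        margin = 30
        pos = margin
        pieces = [("margin", _random_nt(rng, margin))]
        self.utr5_exon = (pos, pos + u5)
        pieces.append(("utr5", _random_nt(rng, u5)))
        pos += u5
        intron0 = _random_nt(rng, int(rng.integers(80, 200)))
        pieces.append(("intron", intron0))
        pos += len(intron0)
        self.coding_exons = []  # genome-ish (region) coords
        self.introns = []
        for k in range(len(bounds) - 1):
            ntseq = cds_nt[3 * bounds[k]: 3 * bounds[k + 1]]
            self.coding_exons.append((pos, pos + len(ntseq)))
            pieces.append(("cds", ntseq))
            pos += len(ntseq)
            if k < len(bounds) - 2:
                iv = _random_nt(rng, int(rng.integers(80, 200)))
                self.introns.append((pos, pos + len(iv)))
                pieces.append(("intron", iv))
                pos += len(iv)
        self.utr3_exon = (pos, pos + u3)
        pieces.append(("utr3", _random_nt(rng, u3)))
        pos += u3
        pieces.append(("margin", _random_nt(rng, 20)))
        pos += 20
        self.region = "".join(p for _, p in pieces)
        self.length = len(self.region)
        self.codon_bounds = bounds
        # frame-preserving intron slide needs the first intron between
        # coding exons to start with the next exon's first 3 nt
        if "identical_protein" in self.variants and self.introns:
            i0, _ = self.introns[0]
            nxt = self.coding_exons[1][0]
            self.region = (
                self.region[:i0] + self.region[nxt: nxt + 3] + self.region[i0 + 3:]
            )

    def isoforms(self) -> list:
        """(suffix, planted_kind, exons, cds, protein) in region coords."""
        ce = self.coding_exons
        exons = [self.utr5_exon, *ce[:-1], (ce[-1][0], self.utr3_exon[1])]
        cds = list(ce)
        out = [("a", "canonical", exons, cds, self.protein)]
        suffix = "b"
        L = len(self.protein)
        for kind in self.variants:
            if kind == "utr_only":
                ex2 = [(self.utr5_exon[0] - 15, self.utr5_exon[1]), *exons[1:]]
                out.append((suffix, kind, ex2, list(cds), self.protein))
            elif kind == "identical_protein":
                if len(ce) < 2:
                    continue
                ex2 = list(exons)
                cd2 = list(cds)
                k = 1 if self.utr5_exon in exons else 0
                # slide the first internal intron 3 nt downstream
                a0, a1 = cd2[0]
                b0, b1 = cd2[1]
                cd2[0] = (a0, a1 + 3)
                cd2[1] = (b0 + 3, b1)
                ex2[1] = (ex2[1][0], ex2[1][1] + 3)
                ex2[2] = (ex2[2][0] + 3, ex2[2][1])
                out.append((suffix, kind, ex2, cd2, self.protein))
            elif kind == "domain_loss":
                dk = next(
                    k for k, (b0, b1) in enumerate(zip(self.codon_bounds, self.codon_bounds[1:]))
                    if b0 <= self.ds < b1
                )
                if dk == len(self.coding_exons) - 1:
                    continue  # never drop the stop-bearing exon
                ex2 = [e for e in exons if e != ce[dk]]
                cd2 = [c for c in cds if c != ce[dk]]
                lo, hi = self.codon_bounds[dk], self.codon_bounds[dk + 1]
                prot2 = self.protein[:lo] + self.protein[hi:]
                out.append((suffix, kind, ex2, cd2, prot2))
            elif kind == "other":
                k_codons = 6
                cd2 = list(cds)
                s, e = cd2[-1]
                cd2[-1] = (s, e - 3 * k_codons)
                prot2 = self.protein[: L - (k_codons - 1)]
                out.append((suffix, kind, list(exons), cd2, prot2))
            else:
                raise ValueError(f"unknown variant kind {kind!r}")
            suffix = chr(ord(suffix) + 1)
        return out


def make_family(config: SimConfig) -> SyntheticFamily:
    """Generate the full multi-species family; reproducible from the seed."""
    rng = as_rng(config.seed)
    species = [f"sp{k+1:02d}" for k in range(config.n_species)]
    alloc = _subfamily_allocation(config.n_clusters)
    type_names = list(config.domain_type_mix)
    type_p = np.array([config.domain_type_mix[t] for t in type_names])

    clusters = []
    for c in range(config.n_clusters):
        sf = alloc[c]
        tpl = subfamily_template(sf)
        ctype = type_names[rng.choice(len(type_names), p=type_p)]
        spacers = TYPE_SPACERS[ctype]
        if sf == "IV":
            nflank = _random_aa(rng, int(rng.integers(12, 30)))
            tail_extra = int(rng.integers(120, 200))
        else:
            nflank = _random_aa(rng, int(rng.integers(120, 200)))
            tail_extra = int(rng.integers(20, 45))
        nflank = "M" + nflank[1:-7] + tpl["flank5"]
        ancestor = (
            nflank + _domain_sequence(tpl, spacers) + tpl["flank3"] + _random_aa(rng, tail_extra)
        )
        protected = _protected_positions(sf, spacers, len(nflank))
        ancestor = mutate_sequence(ancestor, config.cluster_drift, protected, rng,
                                   alphabet=SUBST_AA)
        n_copies = 2 if rng.random() < config.paralog_prob else 1
        present = [sp for sp in species if rng.random() >= config.species_dropout]
        if len(present) < 2:
            present = species[:2]
        has_anchor = rng.random() < config.anchor_prob
        # genus ancestor: substitutions shared by every in-genus member but
        # absent from the anchor ortholog, making the cluster monophyletic
        # with the anchor as its sister lineage
        genus_ancestor = mutate_sequence(ancestor, config.stem_drift, protected, rng,
                                         alphabet=SUBST_AA)
        clusters.append(
            dict(cluster_id=f"K{c+1:02d}", subfamily=sf, type=ctype, spacers=spacers,
                 ancestor=ancestor, genus_ancestor=genus_ancestor, protected=protected,
                 nflank_len=len(nflank), n_copies=n_copies, present=present,
                 has_anchor=has_anchor)
        )

    # out-genus anchor set: one deep anchor per subfamily (from the
    # template) plus an ortholog anchor for most clusters, mirroring how a
    # reference species' members scatter through the family tree
    anchors = []
    for sf in SUBFAMILIES:
        tpl = subfamily_template(sf)
        spacers = TYPE_SPACERS["IV_c" if sf == "III" else "IV_b"]
        nflank = "M" + _random_aa(rng, 60)[:-7] + tpl["flank5"]
        prot = nflank + _domain_sequence(tpl, spacers) + tpl["flank3"] + _random_aa(rng, 25)
        prot = mutate_sequence(prot, config.cluster_drift,
                               _protected_positions(sf, spacers, len(nflank)), rng,
                               alphabet=SUBST_AA)
        anchors.append((f"anchor_{sf}_base", prot, sf))
    for cl in clusters:
        if cl["has_anchor"]:
            prot = mutate_sequence(cl["ancestor"], config.anchor_drift,
                                   cl["protected"], rng, alphabet=SUBST_AA)
            anchors.append((f"anchor_{cl['cluster_id']}", prot, cl["subfamily"]))

    as_kinds = list(config.as_spec)
    genes_by_species: dict = {sp: [] for sp in species}
    genomes: dict = {sp: {} for sp in species}
    proteins: dict = {}
    gene_rows = []
    iso_rows = []
    offsets = {sp: {} for sp in species}
    counters = {sp: 0 for sp in species}
    scafs = {sp: 0 for sp in species}

    for cl in clusters:
        ds = cl["nflank_len"]
        de = ds + len(_domain_sequence(subfamily_template(cl["subfamily"]), cl["spacers"]))
        for sp in cl["present"]:
            for copy in range(cl["n_copies"]):
                counters[sp] += 1
                gid = f"{sp}G{counters[sp]:03d}"
                prot = mutate_sequence(
                    cl["genus_ancestor"], config.mutation_rate, cl["protected"], rng,
                    alphabet=SUBST_AA,
                )
                # optional planted features
                tmh_span = None
                if rng.random() < config.tmh_fraction:
                    tlen = 23
                    if ds >= tlen + 12:  # room in the N-flank
                        t0 = int(rng.integers(5, ds - tlen - 5))
                    else:
                        t0 = de + 30
                    if t0 + tlen <= len(prot):
                        stretch = "".join(TMH_AA[i] for i in rng.integers(len(TMH_AA), size=tlen))
                        prot = prot[:t0] + stretch + prot[t0 + tlen:]
                        tmh_span = (t0, t0 + tlen)
                degraded = False
                if rng.random() < config.degrade_fraction:
                    c4 = de - 1
                    prot = prot[:c4] + "S" + prot[c4 + 1:]
                    degraded = True
                variants = [k for k in as_kinds if rng.random() < config.as_spec[k]]
                builder = _GeneBuilder(rng, gid, prot, (ds, de), variants)
                strand = "+" if rng.random() < 0.5 else "-"
                unplaced = rng.random() < config.unplaced_fraction
                if unplaced:
                    scafs[sp] += 1
                    chrom = f"scaffold_{700 + scafs[sp]}"
                    base = int(rng.integers(50, 300))
                    genomes[sp][chrom] = _random_nt(rng, base)
                    offsets[sp][chrom] = base
                else:
                    chrom = f"chr{(counters[sp] - 1) % config.chrom_count + 1:02d}"
                    if chrom not in genomes[sp]:
                        genomes[sp][chrom] = _random_nt(rng, int(rng.integers(200, 500)))
                        offsets[sp][chrom] = len(genomes[sp][chrom])
                off = offsets[sp][chrom]
                region = builder.region if strand == "+" else _revcomp(builder.region)
                gap = _random_nt(rng, int(rng.integers(200, 800)))
                genomes[sp][chrom] = genomes[sp][chrom] + region + gap
                offsets[sp][chrom] = off + builder.length + len(gap)

                def to_genome(iv):
                    s, e = iv
                    if strand == "+":
                        return (off + s, off + e)
                    return (off + builder.length - e, off + builder.length - s)

                gm = GeneModel(gene_id=gid, species=sp, chromosome=chrom,
                               strand=strand, placed=not unplaced)
                for suffix, kind, exons, cds, p in builder.isoforms():
                    tid = gid + suffix
                    t = TranscriptModel(
                        transcript_id=tid,
                        exons=sorted(to_genome(iv) for iv in exons),
                        cds=sorted(to_genome(iv) for iv in cds),
                        protein=p,
                    )
                    gm.transcripts.append(t)
                    proteins[tid] = p
                    expected = {
                        "canonical": "canonical",
                        "utr_only": "identical_protein",
                        "identical_protein": "identical_protein",
                        "domain_loss": "domain_loss",
                        "other": "other",
                    }[kind]
                    iso_rows.append(
                        {
                            "isoform_id": tid, "gene_id": gid, "planted_kind": kind,
                            "expected_category": expected,
                            "expected_utr_only_flag": kind == "utr_only",
                            "has_domain": kind != "domain_loss" and not degraded,
                        }
                    )
                genes_by_species[sp].append(gm)
                gene_rows.append(
                    {
                        "gene_id": gid, "species": sp, "cluster_id": cl["cluster_id"],
                        "subfamily": cl["subfamily"],
                        "domain_type": "IV_p" if degraded else cl["type"],
                        "domain_start": ds, "domain_end": de,
                        "tmh_start": tmh_span[0] if tmh_span else -1,
                        "tmh_end": tmh_span[1] if tmh_span else -1,
                        "chromosome": chrom, "strand": strand, "placed": not unplaced,
                        "n_isoforms": 1 + len(variants),
                    }
                )

    if config.chrom_length is not None:
        for sp in species:
            for chrom, seq in genomes[sp].items():
                if chrom.startswith("chr") and len(seq) > config.chrom_length:
                    raise ValueError(
                        f"chromosome {chrom} of {sp} needs {len(seq)} bp > "
                        f"configured length {config.chrom_length}"
                    )

    truth_genes = pd.DataFrame(gene_rows)
    truth_isoforms = pd.DataFrame(iso_rows)
    expression = _make_expression(rng, truth_genes, config)
    return SyntheticFamily(
        config=config,
        species=species,
        genes_by_species=genes_by_species,
        genomes=genomes,
        proteins=proteins,
        expression=expression,
        truth_genes=truth_genes,
        truth_isoforms=truth_isoforms,
        anchors=anchors,
    )


def _make_expression(rng, truth_genes: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Gaussian-copula block-correlated FPKM matrix: one block per cluster,
    exponential marginals scaled per cluster."""
    within, between = config.expression_block_corr
    conditions = [f"tissue_{k+1}" for k in range(config.n_conditions)]
    cluster_ids = list(dict.fromkeys(truth_genes["cluster_id"]))
    global_f = rng.standard_normal(config.n_conditions)
    factors = {}
    scales = {}
    for cid in cluster_ids:
        f = rng.standard_normal(config.n_conditions)
        if between > 0:
            f = np.sqrt(between) * global_f + np.sqrt(1 - between) * f
        factors[cid] = f
        scales[cid] = float(rng.uniform(5.0, 50.0))
    rows = {}
    for _, g in truth_genes.iterrows():
        f = factors[g["cluster_id"]]
        z = np.sqrt(within) * f + np.sqrt(1 - within) * rng.standard_normal(config.n_conditions)
        u = stats.norm.cdf(z)
        rows[g["gene_id"]] = stats.expon.ppf(u) * scales[g["cluster_id"]]
    df = pd.DataFrame(rows, index=conditions).T
    df.index.name = "gene_id"
    return df
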