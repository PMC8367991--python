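"""Genome annotation I/O: GFF3 + FASTA -> gene models with protein isoforms.

Internal coordinates are 0-based half-open throughout; GFF3's 1-based
inclusive convention is converted on the way in and restored on the way
out.  Transcripts without CDS are retained as non-coding isoforms but
never counted as family members (TFs).
"""

from __future__ import annotations

import fnmatch
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

DEFAULT_UNPLACED_PATTERN = "scaffold_*"


@dataclass
class TranscriptModel:
    """One transcript: exon/CDS intervals (genome coords) and its protein."""

    transcript_id: str
    exons: list = field(default_factory=list)  # [start, end) tuples
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    protein: str = ""
    malformed: bool = False

    @property
    def coding(self) -> bool:
        return bool(self.cds) and not self.malformed

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GeneModel:
    """A gene with its transcripts and chromosomal placement."""

    gene_id: str
    species: str = ""
    chromosome: str = ""
    strand: str = "+"
    transcripts: list = field(default_factory=list)
    placed: bool = True

    @property
    def coding_transcripts(self) -> list:
        return [t for t in self.transcripts if t.coding]

    def span(self) -> tuple:
        starts = [s for t in self.transcripts for s, _ in t.exons]
        ends = [e for t in self.transcripts for _, e in t.exons]
        return (min(starts), max(ends)) if starts else (0, 0)


def _derive_utrs(t: TranscriptModel, strand: str) -> None:
    """UTR intervals = exon coverage outside the CDS extent."""
    if not t.cds:
        t.utr5, t.utr3 = [], []
        return
    cds_lo = min(s for s, _ in t.cds)
    cds_hi = max(e for _, e in t.cds)
    left, right = [], []
    for s, e in t.exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    if strand == "+":
        t.utr5, t.utr3 = left, right
    else:
        t.utr5, t.utr3 = right, left


def translate_cds(
    cds_intervals: Sequence[tuple], chrom_seq: str, strand: str
) -> str:
    """Strand-aware translation of concatenated CDS intervals.

    The stop codon is removed.  Raises ValueError on a length not
    divisible by 3 or an internal stop.
    """
    parts = [chrom_seq[s:e] for s, e in sorted(cds_intervals)]
    nt = "".join(parts)
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon in translation")
    return aa


def parse_annotation(
    gff3_path: str,
    fasta_path: str,
    species: str = "",
    unplaced_pattern: str = DEFAULT_UNPLACED_PATTERN,
) -> list[GeneModel]:
    """Parse a GFF3 + genome FASTA pair into gene models.

    Genes on sequences matching ``unplaced_pattern`` (shell glob) get
    ``placed=False`` and are pooled under "ChrUn" in reports.  Transcripts
    whose CDS length is not a multiple of 3 are flagged malformed and
    excluded from coding analyses with a logged warning; a CDS referencing
    a chromosome absent from the FASTA is a hard error.
    """
    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        gm = GeneModel(
            gene_id=g.id,
            species=species,
            chromosome=g.seqid,
            strand=g.strand,
            placed=not fnmatch.fnmatch(g.seqid, unplaced_pattern),
        )
        for mrna in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            t = TranscriptModel(transcript_id=mrna.id)
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                t.exons.append((ex.start - 1, ex.end))
            for c in db.children(mrna, featuretype="CDS", order_by="start"):
                t.cds.append((c.start - 1, c.end))
            t.exons.sort()
            t.cds.sort()
            if not t.exons and t.cds:
                t.exons = list(t.cds)
            if t.cds:
                if g.seqid not in seqs:
                    raise ValueError(
                        f"CDS of {mrna.id} references missing chromosome {g.seqid!r}"
                    )
                try:
                    t.protein = translate_cds(t.cds, seqs[g.seqid], g.strand)
                except ValueError as err:
                    log.warning("transcript %s flagged malformed: %s", mrna.id, err)
                    t.malformed = True
            _derive_utrs(t, g.strand)
            gm.transcripts.append(t)
        genes.append(gm)
    return genes


def load_proteome(
    fasta_path: str, id_scheme: str = "suffix_letter", species: str = ""
) -> list[GeneModel]:
    """Load a pre-translated proteome keyed by gene + isoform IDs.

    ``id_scheme`` currently supports ``suffix_letter`` (gene id plus a
    trailing lowercase letter naming the isoform, "g1a"/"g1b") and a
    regex with named groups ``gene`` and ``isoform``.  The resulting
    models have no coordinates, so coordinate-dependent analyses (UTR
    variants, chromosome maps) are unavailable.
    """
    if id_scheme == "suffix_letter":
        rx = re.compile(r"^(?P<gene>.+?)(?P<isoform>[a-z])$")
    else:
        rx = re.compile(id_scheme)
    genes: dict[str, GeneModel] = {}
    seen: set[str] = set()
    skipped = []
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if not records:
        log.warning("empty proteome FASTA %s", fasta_path)
    for rec in records:
        m = rx.match(rec.id)
        if not m:
            skipped.append(rec.id)
            continue
        if rec.id in seen:
            raise ValueError(f"duplicate transcript ID {rec.id!r}")
        seen.add(rec.id)
        gid = m.group("gene")
        gm = genes.setdefault(gid, GeneModel(gene_id=gid, species=species))
        gm.transcripts.append(
            TranscriptModel(
                transcript_id=rec.id,
                cds=[(0, 3 * len(rec.seq))],  # synthetic extent: marks it coding
                protein=str(rec.seq).upper(),
            )
        )
    if skipped:
        log.warning("skipped %d header(s) not matching the ID rule: %s",
                    len(skipped), ", ".join(skipped[:5]))
    return list(genes.values())


# ---------------------------------------------------------------------------
# writers


def write_fasta(records: Iterable[tuple], path: str, width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_gff3(genes: Iterable[GeneModel], path: str, source: str = "gatafam") -> None:
    """Emit gene models back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span()
            fh.write(
                "\t".join(
                    [g.chromosome, source, "gene", str(lo + 1), str(hi),
                     ".", g.strand, ".", f"ID={g.gene_id}"]
                ) + "\n"
            )
            for t in g.transcripts:
                ts = min(s for s, _ in t.exons)
                te = max(e for _, e in t.exons)
                fh.write(
                    "\t".join(
                        [g.chromosome, source, "mRNA", str(ts + 1), str(te),
                         ".", g.strand, ".",
                         f"ID={t.transcript_id};Parent={g.gene_id}"]
                    ) + "\n"
                )
                for kind, ivals in (("exon", t.exons), ("CDS", t.cds)):
                    phase = 0
                    ordered = sorted(ivals, reverse=(g.strand == "-")) if kind == "CDS" else sorted(ivals)
                    for s, e in ordered:
                        ph = str(phase) if kind == "CDS" else "."
                        fh.write(
                            "\t".join(
                                [g.chromosome, source, kind, str(s + 1), str(e),
                                 ".", g.strand, ph,
                                 f"Parent={t.transcript_id}"]
                            ) + "\n"
                        )
                        if kind == "CDS":
                            phase = (3 - ((e - s) - phase) % 3) % 3
    return None


def report_chromosome(g: GeneModel) -> str:
    """User-facing chromosome label; unplaced genes pool under ChrUn."""
    return g.chromosome if g.placed else "ChrUn"
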