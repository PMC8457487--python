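"""Sequence, annotation and variant I/O with fixed coordinate conventions.

Every coordinate held in memory is 0-based half-open; every coordinate in a
file we read (GFF3, VCF) or write for humans is 1-based inclusive, per those
formats' standards.  The conversion happens exactly once, at the I/O boundary,
so downstream modules never reason about off-by-ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from cyvcf2 import VCF

__all__ = [
    "FormatError",
    "GenomicInterval",
    "GeneModel",
    "VariantSite",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "read_vcf",
]

# Full IUPAC nucleotide alphabet (uppercase); '-' tolerated nowhere on read.
IUPAC_CODES = set("ACGTRYSWKMBDHVN")

#: ambiguity code -> the set of bases it covers
IUPAC_TO_BASES = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

#: base set (frozenset) -> ambiguity code
BASES_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_TO_BASES.items()}


class FormatError(ValueError):
    """A file violated its format contract; the message names the record."""


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval: 0-based start (inclusive), end (exclusive)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def to_1based(self) -> str:
        """Render as the 1-based inclusive string used in reports."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


@dataclass
class GeneModel:
    """An annotated gene: genomic span, ordered exons and coding sequence.

    ``exons`` are sorted 5'->3' in transcription order (reversed genomic order
    for minus-strand genes).  ``cds`` is the spliced coding sequence on the
    coding strand; ``genomic_seq`` is the gene-span sequence, also oriented to
    the coding strand.  ``cds_exon_spans`` gives, per coding exon in
    transcription order, the half-open CDS-offset range it contributes,
    together with its genomic interval — the lookup table used to lift
    CDS-frame guide coordinates onto the genome.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    cds: str
    genomic_seq: str
    cds_exon_spans: list[tuple[int, int, GenomicInterval]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        if not self.cds:
            raise ValueError(f"gene {self.gene_id}: empty CDS")
        genomic_sorted = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic_sorted, genomic_sorted[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    def cds_offset_to_genomic(self, off: int) -> tuple[str, int]:
        """Map a CDS offset to (chrom, 0-based genomic position)."""
        for c0, c1, ivl in self.cds_exon_spans:
            if c0 <= off < c1:
                if self.interval.strand == "+":
                    return ivl.chrom, ivl.start + (off - c0)
                return ivl.chrom, ivl.end - 1 - (off - c0)
        raise IndexError(f"CDS offset {off} outside gene {self.gene_id}")

    def genomic_to_gene_offset(self, pos: int) -> int:
        """Map a genomic position inside the gene span to a gene-relative
        offset on the coding strand (0 = 5' end of the gene span)."""
        if not (self.interval.start <= pos < self.interval.end):
            raise IndexError(
                f"position {pos} outside gene {self.gene_id} span"
            )
        if self.interval.strand == "+":
            return pos - self.interval.start
        return self.interval.end - 1 - pos


@dataclass(frozen=True)
class VariantSite:
    """A population variant: 0-based position, reference and alternates."""

    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValueError("variant with no alt alleles")
        for a in (self.ref_allele, *self.alt_alleles):
            if not a or set(a) - set("ACGT"):
                raise ValueError(f"invalid allele {a!r} at {self.chrom}:{self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and all(
            len(a) == 1 for a in self.alt_alleles
        )

    @property
    def is_indel(self) -> bool:
        return not self.is_snp


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into {id: uppercase sequence}.

    Ids are the first whitespace-delimited header token.  U is converted to T;
    IUPAC ambiguity codes are kept.  Empty files, duplicate ids and
    non-IUPAC characters raise :class:`FormatError`.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise FormatError(
                f"record {rec.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | os.PathLike, records: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _exon_list(db: gffutils.FeatureDB, parent, genome: dict[str, str]):
    feats = list(db.children(parent, featuretype="exon"))
    if not feats:  # exon-less annotations: treat CDS features as exons
        feats = list(db.children(parent, featuretype="CDS"))
    return feats


def read_gff3(path: str | os.PathLike, genome: dict[str, str]) -> list[GeneModel]:
    """Read gene models from GFF3, converting to 0-based half-open coordinates.

    Expects gene -> mRNA -> exon/CDS feature hierarchies.  Minus-strand exon
    lists are reversed into transcription order and the CDS is
    reverse-complemented onto the coding strand.
    """
    db = gffutils.create_db(
        os.fspath(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise FormatError(
                f"gene {gene.id}: unknown sequence {gene.seqid!r}"
            )
        chrom_seq = genome[gene.seqid]
        g_ivl = GenomicInterval(gene.seqid, gene.start - 1, gene.end, gene.strand)
        mrnas = list(db.children(gene, featuretype="mRNA")) or [gene]
        mrna = mrnas[0]  # first isoform only
        exon_feats = _exon_list(db, mrna, genome)
        cds_feats = list(db.children(mrna, featuretype="CDS")) or exon_feats
        for f in exon_feats + cds_feats:
            if f.start - 1 < g_ivl.start or f.end > g_ivl.end:
                raise FormatError(
                    f"feature at {f.seqid}:{f.start}-{f.end} outside gene {gene.id}"
                )
        exons = sorted(
            (
                GenomicInterval(f.seqid, f.start - 1, f.end, gene.strand)
                for f in exon_feats
            ),
            key=lambda e: e.start,
        )
        cds_ivls = sorted(
            (
                GenomicInterval(f.seqid, f.start - 1, f.end, gene.strand)
                for f in cds_feats
            ),
            key=lambda e: e.start,
        )
        # CDS on the coding strand, plus per-exon CDS-offset spans
        parts = [chrom_seq[i.start : i.end] for i in cds_ivls]
        if gene.strand == "+":
            ordered = list(zip(parts, cds_ivls))
        else:
            exons = exons[::-1]
            ordered = [(revcomp(p), i) for p, i in zip(parts, cds_ivls)][::-1]
        cds = "".join(p for p, _ in ordered)
        spans, off = [], 0
        for p, ivl in ordered:
            spans.append((off, off + len(p), ivl))
            off += len(p)
        gseq = chrom_seq[g_ivl.start : g_ivl.end]
        if gene.strand == "-":
            gseq = revcomp(gseq)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                interval=g_ivl,
                exons=exons,
                cds=cds,
                genomic_seq=gseq,
                cds_exon_spans=spans,
            )
        )
    return genes


def read_vcf(path: str | os.PathLike) -> list[VariantSite]:
    """Read variant sites from a VCF, dropping records that fail FILTER.

    Positions become 0-based.  Multi-allelic records stay one site with all
    alternates.  Indels are kept (``VariantSite.is_indel``); the consensus
    module decides their treatment.
    """
    sites: list[VariantSite] = []
    for var in VCF(os.fspath(path)):
        if var.FILTER is not None:  # None == PASS or '.'
            continue
        alts = tuple(a for a in var.ALT if a and a != "<NON_REF>")
        if not alts:
            continue
        sites.append(
            VariantSite(
                chrom=var.CHROM,
                pos=var.POS - 1,
                ref_allele=var.REF.upper(),
                alt_alleles=tuple(a.upper() for a in alts),
            )
        )
    return sites
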