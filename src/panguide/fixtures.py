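"""Synthetic genomes, gene families and variant sets with known ground truth.

The generator emulates the structures the pipeline must resolve in a real
plant genome: a multi-copy gene family implanted into random background
sequence, with an allele pair (synonymous-only divergence, so translated
proteins stay identical), additional diverged copies (protein-altering
substitutions, never nonsense), optional truncated pseudogene copies (one
injected internal stop), and per-member population SNPs.  Everything is
driven by one integer seed and is byte-reproducible.

Also provided are two deterministic synthetic analogues of published worked
examples from the cannabinoid-synthase literature: a CBCAS-like pair of
1635-bp genes identical except one synonymous C>T at base pair 662, and an
OAC-like family (allele pair plus an extra copy) whose coding sequences
carry exactly 14 polymorphic positions.  These are constructed stand-ins —
the real supplementary sequences are not redistributed here — with the same
structure and summary numbers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .seqio import GeneModel, GenomicInterval, VariantSite, write_fasta

__all__ = [
    "FamilySpec",
    "FamilyTruth",
    "simulate_genome",
    "simulate_family",
    "implant_family",
    "emit_truth",
    "cbcas_analogue",
    "oac_analogue",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
# codon families whose third position is fully degenerate
_FOURFOLD_PREFIXES = {"TC", "CT", "CC", "CG", "AC", "GT", "GC", "GG"}


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint for one implanted gene family.

    member_divergence[i] is the per-site substitution rate of member i from
    the common ancestor (member ids are m1..mN).  allele_of maps a member to
    the member it is an allele of; such members receive synonymous-biased
    mutations so their translated proteins match.  truncate names members
    that get one internal stop codon.  snp_rate is the per-site density of
    population SNPs simulated over each member's gene span.
    """

    n_members: int
    member_divergence: tuple[float, ...]
    allele_of: dict[str, str] = field(default_factory=dict)
    truncate: frozenset[str] = frozenset()
    gene_len: int = 1500  # CDS length, nt
    n_exons: int = 2
    intron_len: int = 300
    snp_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.member_divergence) != self.n_members:
            raise ValueError("one divergence rate per member required")
        if any(not (0 <= r <= 0.2) for r in self.member_divergence):
            raise ValueError("divergence rates must lie in [0, 0.2]")
        if self.gene_len < 300:
            raise ValueError("gene_len must be >= 300")
        if self.n_exons < 1:
            raise ValueError("n_exons must be >= 1")

    def member_ids(self) -> list[str]:
        return [f"m{i + 1}" for i in range(self.n_members)]


@dataclass
class MemberTruth:
    member_id: str
    interval: GenomicInterval
    label: str  # intended classification
    gene: GeneModel
    snp_offsets: set[int] = field(default_factory=set)  # gene frame
    variants: list[VariantSite] = field(default_factory=list)


@dataclass
class FamilyTruth:
    spec: FamilySpec
    members: dict[str, MemberTruth] = field(default_factory=dict)

    @property
    def genes(self) -> list[GeneModel]:
        return [m.gene for m in self.members.values()]


def simulate_genome(length: int, gc: float = 0.5, seed: int = 0) -> dict[str, str]:
    """One random chromosome of i.i.d. bases with the given GC content."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0 < gc < 1):
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return {"chr1": seq}


def _random_orf(rng: np.random.Generator, cds_len: int) -> str:
    """ATG + random non-stop codons + TAA, total length cds_len (mult. of 3)."""
    cds_len -= cds_len % 3
    n_mid = cds_len // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_mid + 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _synonymous_sites(cds: str) -> list[int]:
    """CDS offsets whose base can be swapped without changing the protein
    (third positions of four-fold degenerate codons, stop codon excluded)."""
    sites = []
    for i in range(0, len(cds) - 3, 3):  # skip the terminal stop codon
        if cds[i : i + 2] in _FOURFOLD_PREFIXES:
            sites.append(i + 2)
    return sites


def _mutate(
    rng: np.random.Generator,
    gene_seq: str,
    rate: float,
    exon_spans: list[tuple[int, int]],
    synonymous_only: bool,
) -> str:
    """Substitute bases at roughly `rate` per site over the whole gene span.

    exon_spans are gene-frame CDS windows (in order).  synonymous_only
    restricts coding changes to four-fold degenerate third positions (intron
    changes are always free).  Non-synonymous mode resamples any substitution
    that would create an in-frame stop codon, so diverged copies stay
    protein-coding unless truncation is requested explicitly.
    """
    seq = list(gene_seq)
    length = len(seq)
    n_mut = rng.binomial(length, rate)
    if n_mut == 0:
        return gene_seq

    exonic = set()
    cds_offset_of = {}
    off = 0
    for lo, hi in exon_spans:
        for p in range(lo, hi):
            exonic.add(p)
            cds_offset_of[p] = off
            off += 1
    cds = "".join(gene_seq[lo:hi] for lo, hi in exon_spans)

    if synonymous_only:
        syn = set(_synonymous_sites(cds))
        allowed = [
            p
            for p in range(length)
            if p not in exonic or cds_offset_of[p] in syn
        ]
    else:
        allowed = list(range(length))
    n_mut = min(n_mut, len(allowed))
    positions = rng.choice(len(allowed), size=n_mut, replace=False)
    for pi in positions:
        p = allowed[pi]
        old = seq[p]
        choices = [b for b in "ACGT" if b != old]
        rng.shuffle(choices)
        for new in choices:
            seq[p] = new
            if p not in exonic:
                break
            co = cds_offset_of[p]
            codon_start = co - co % 3
            codon = "".join(
                seq[_gene_pos(exon_spans, c)]
                for c in range(codon_start, codon_start + 3)
            )
            if codon not in _STOPS:
                break
            seq[p] = old  # try another base
    return "".join(seq)


def _gene_pos(exon_spans: list[tuple[int, int]], cds_off: int) -> int:
    for lo, hi in exon_spans:
        if cds_off < hi - lo:
            return lo + cds_off
        cds_off -= hi - lo
    raise IndexError("CDS offset outside exons")


def _inject_stop(gene_seq: str, exon_spans: list[tuple[int, int]]) -> str:
    """Replace one mid-CDS codon with TAA."""
    cds_len = sum(hi - lo for lo, hi in exon_spans)
    codon_idx = (cds_len // 3) // 2
    seq = list(gene_seq)
    for k in range(3):
        seq[_gene_pos(exon_spans, codon_idx * 3 + k)] = "TAA"[k]
    return "".join(seq)


def simulate_family(
    spec: FamilySpec,
) -> tuple[dict[str, str], list[tuple[int, int]], dict[str, str]]:
    """Generate family member gene sequences without touching a genome.

    Returns (member_id -> gene-span sequence, gene-frame exon spans,
    member_id -> intended label).  The exon spans are shared by all members
    (substitution-only divergence preserves coordinates).
    """
    rng = np.random.default_rng(spec.seed)
    cds_len = spec.gene_len - spec.gene_len % 3
    ancestor_cds = _random_orf(rng, cds_len)

    # split CDS across exons; introns start GT, end AG
    bounds = np.linspace(0, cds_len, spec.n_exons + 1).astype(int)
    exon_cds = [(int(a), int(b)) for a, b in zip(bounds, bounds[1:])]
    intron_seqs = []
    for _ in range(spec.n_exons - 1):
        mid = "".join(rng.choice(_BASES, size=spec.intron_len - 4))
        intron_seqs.append("GT" + mid + "AG")

    def assemble(cds: str) -> tuple[str, list[tuple[int, int]]]:
        parts, spans, pos = [], [], 0
        for k, (a, b) in enumerate(exon_cds):
            parts.append(cds[a:b])
            spans.append((pos, pos + (b - a)))
            pos += b - a
            if k < len(intron_seqs):
                parts.append(intron_seqs[k])
                pos += len(intron_seqs[k])
        return "".join(parts), spans

    ancestor_gene, gene_exon_spans = assemble(ancestor_cds)

    ids = spec.member_ids()
    member_seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for i, mid in enumerate(ids):
        synonymous = mid in spec.allele_of or mid in spec.allele_of.values()
        seq = _mutate(
            rng,
            ancestor_gene,
            spec.member_divergence[i],
            gene_exon_spans,
            synonymous_only=synonymous,
        )
        if mid in spec.truncate:
            seq = _inject_stop(seq, gene_exon_spans)
        member_seqs[mid] = seq
        if mid in spec.truncate:
            labels[mid] = "TRUNCATED_HOMOLOG"
        elif synonymous:
            labels[mid] = "ALLELE_PAIR"
        elif i == 0:
            labels[mid] = "REFERENCE"
        else:
            labels[mid] = "GENE_COPY"
    return member_seqs, gene_exon_spans, labels


def implant_family(
    genome: dict[str, str], spec: FamilySpec
) -> tuple[dict[str, str], FamilyTruth]:
    """Implant the family into the genome, >=10 kb apart, with ground truth.

    Returns the modified genome and a FamilyTruth carrying, per member, the
    genomic interval, the intended classification label, the gene model, the
    simulated SNP mask (gene frame) and the corresponding VCF-ready
    variants.
    """
    rng = np.random.default_rng(spec.seed + 1)  # SNP/placement stream
    member_seqs, gene_exon_spans, labels = simulate_family(spec)
    span_len = len(next(iter(member_seqs.values())))

    chrom = next(iter(genome))
    glen = len(genome[chrom])
    gap = 10_000
    needed = spec.n_members * (span_len + gap) + gap
    if glen < needed:
        raise ValueError(
            f"genome of {glen} bp too short for {spec.n_members} implants "
            f"({needed} bp needed)"
        )

    ids = spec.member_ids()
    # evenly spaced implant anchors, all plus strand
    stride = (glen - gap) // spec.n_members
    seq_list = list(genome[chrom])
    truth = FamilyTruth(spec=spec)
    for i, mid in enumerate(ids):
        start = gap // 2 + i * stride
        seq_list[start : start + span_len] = member_seqs[mid]
        ivl = GenomicInterval(chrom, start, start + span_len, "+")
        exons = [
            GenomicInterval(chrom, start + lo, start + hi, "+")
            for lo, hi in gene_exon_spans
        ]
        cds = "".join(
            member_seqs[mid][lo:hi] for lo, hi in gene_exon_spans
        )
        spans = []
        off = 0
        for e, (lo, hi) in zip(exons, gene_exon_spans):
            spans.append((off, off + (hi - lo), e))
            off += hi - lo
        gene = GeneModel(
            gene_id=mid,
            interval=ivl,
            exons=exons,
            cds=cds,
            genomic_seq=member_seqs[mid],
            cds_exon_spans=spans,
        )
        label = labels[mid]
        n_snp = rng.binomial(span_len, spec.snp_rate)
        offs = sorted(
            int(x) for x in rng.choice(span_len, size=n_snp, replace=False)
        )
        variants = []
        for o in offs:
            ref_base = member_seqs[mid][o]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            variants.append(
                VariantSite(
                    chrom=chrom,
                    pos=start + o,
                    ref_allele=ref_base,
                    alt_alleles=(alt,),
                )
            )
        truth.members[mid] = MemberTruth(
            member_id=mid,
            interval=ivl,
            label=label,
            gene=gene,
            snp_offsets=set(offs),
            variants=variants,
        )
    new_genome = {chrom: "".join(seq_list)}
    return new_genome, truth


def emit_truth(truth: FamilyTruth, genome: dict[str, str], outdir: str | os.PathLike) -> dict[str, str]:
    """Write genome FASTA, gene GFF3, SNP VCF, mask BED and a JSON manifest.

    Returns a map of logical name -> written path.  All files follow their
    format's coordinate convention (GFF3/VCF 1-based, BED 0-based half-open)
    and re-read cleanly through seqio.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "gff3": os.path.join(outdir, "genes.gff3"),
        "vcf": os.path.join(outdir, "snps.vcf"),
        "bed": os.path.join(outdir, "mask.bed"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    write_fasta(paths["genome"], genome)

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for m in truth.members.values():
            g = m.gene
            ivl = g.interval
            base = f"{ivl.chrom}\tpanguide\t"
            fh.write(
                base + f"gene\t{ivl.start + 1}\t{ivl.end}\t.\t{ivl.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                base + f"mRNA\t{ivl.start + 1}\t{ivl.end}\t.\t{ivl.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for k, e in enumerate(g.exons, 1):
                fh.write(
                    base + f"exon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                    f"ID={g.gene_id}.e{k};Parent={g.gene_id}.t1\n"
                )
                fh.write(
                    base + f"CDS\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t0\t"
                    f"ID={g.gene_id}.c{k};Parent={g.gene_id}.t1\n"
                )

    chrom = next(iter(genome))
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        all_vars = sorted(
            (v for m in truth.members.values() for v in m.variants),
            key=lambda v: v.pos,
        )
        for v in all_vars:
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t"
                f"{','.join(v.alt_alleles)}\t.\tPASS\t.\n"
            )

    with open(paths["bed"], "w") as fh:
        for m in truth.members.values():
            for v in m.variants:
                fh.write(f"{v.chrom}\t{v.pos}\t{v.pos + 1}\t{m.member_id}\n")

    manifest = {
        "seed": truth.spec.seed,
        "members": {
            mid: {
                "interval": [
                    m.interval.chrom,
                    m.interval.start,
                    m.interval.end,
                    m.interval.strand,
                ],
                "label": m.label,
                "snp_offsets": sorted(m.snp_offsets),
            }
            for mid, m in truth.members.items()
        },
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Synthetic analogues of published worked examples (constructed stand-ins;
# the originals live in a supplementary table not redistributed here).
# ---------------------------------------------------------------------------

def cbcas_analogue() -> dict[str, dict[str, object]]:
    """Two synthetic CBCAS-like genes, 1635 bp, one synonymous C>T at bp 662.

    Structure mirrors the published CBCAS#1/#2 pair: identical genomic
    sequences except a single C-to-T substitution at base pair 662 (1-based)
    that leaves the predicted proteins identical (third codon position of a
    glycine codon).  Layout: 50-nt 5' UTR, 1536-nt single-exon CDS, 49-nt
    3' UTR.
    """
    rng = np.random.default_rng(20257413)
    utr5 = "".join(rng.choice(_BASES, size=50))
    cds = _random_orf(rng, 1536)
    utr3 = "".join(rng.choice(_BASES, size=49))
    # bp 662 (1-based) = index 661 = CDS index 611 = codon 203, position 3
    codon_start = 609
    cds = cds[:codon_start] + "GGC" + cds[codon_start + 3 :]
    seq1 = utr5 + cds + utr3
    assert len(seq1) == 1635 and seq1[661] == "C"
    seq2 = seq1[:661] + "T" + seq1[662:]
    cds2 = seq2[50 : 50 + 1536]
    return {
        "CBCAS_like_1": {"genomic": seq1, "cds": cds, "cds_start": 50},
        "CBCAS_like_2": {"genomic": seq2, "cds": cds2, "cds_start": 50},
    }


def oac_analogue() -> dict[str, str]:
    """Synthetic OAC-like CDS family: allele pair + extra copy, 14 SNPs total.

    Mirrors the published OAC narrative: three coding sequences (two alleles
    and one additional gene copy) whose multiple alignment carries exactly 14
    polymorphic positions — 5 synonymous differences between the alleles and
    9 further differences private to the extra copy.
    """
    rng = np.random.default_rng(5793422)
    cds = _random_orf(rng, 306)
    syn = _synonymous_sites(cds)
    allele_sites = [syn[i] for i in np.linspace(2, len(syn) - 3, 5).astype(int)]
    allele2 = list(cds)
    for p in allele_sites:
        allele2[p] = {"A": "G", "G": "A", "C": "T", "T": "C"}[allele2[p]]
    # 9 copy-private sites, disjoint from the allele sites, none creating stops
    copy = list(cds)
    taken = set(allele_sites)
    candidates = [p for p in range(3, len(cds) - 3) if p not in taken]
    rng.shuffle(candidates)
    placed = 0
    for p in candidates:
        if placed == 9:
            break
        old = copy[p]
        for new in "ACGT":
            if new == old:
                continue
            copy[p] = new
            codon_start = p - p % 3
            if "".join(copy[codon_start : codon_start + 3]) not in _STOPS:
                placed += 1
                taken.add(p)
                break
            copy[p] = old
    assert placed == 9
    return {
        "OAC_allele1": cds,
        "OAC_allele2": "".join(allele2),
        "OAC_copy": "".join(copy),
    }
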