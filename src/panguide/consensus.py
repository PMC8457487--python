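"""Population-variant overlay: IUPAC consensus sequences and SNP masks.

A gene's consensus sequence is its reference sequence with every
population-variable site re-encoded as the IUPAC code covering the reference
plus all alternate alleles.  The SNP mask — the set of gene-relative offsets
with any variation — is what guide design must avoid for a guide to work on
every genotype.  Indels are recorded as masked positions but never shift
coordinates: the consensus stays length-matched to the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqio import (
    BASES_TO_IUPAC,
    IUPAC_TO_BASES,
    GeneModel,
    VariantSite,
)

__all__ = [
    "ConsensusRecord",
    "apply_variants",
    "mask_from_consensus_pair",
    "snp_density_table",
    "project_mask_to_cds",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass
class ConsensusRecord:
    """Reference gene sequence plus its population SNP mask, gene frame.

    Offsets are 0-based on the coding strand of the gene span (offset 0 =
    5' end of the gene).  ``consensus_seq[i] != ref_seq[i]`` exactly when
    ``i`` is a SNP position.
    """

    gene_id: str
    ref_seq: str
    consensus_seq: str
    snp_positions: set[int] = field(default_factory=set)
    indel_positions: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.consensus_seq):
            raise ValueError(
                f"{self.gene_id}: consensus/reference length mismatch"
            )

    @property
    def mask(self) -> set[int]:
        """All positions a genotype-independent guide must avoid."""
        return self.snp_positions | self.indel_positions


def _iupac_union(bases: set[str]) -> str:
    try:
        return BASES_TO_IUPAC[frozenset(bases)]
    except KeyError:
        raise ValueError(f"cannot encode base set {sorted(bases)}") from None


def apply_variants(gene: GeneModel, variants: list[VariantSite]) -> ConsensusRecord:
    """Overlay variants (genomic coordinates) onto one gene.

    SNP alleles are unioned with the reference into an IUPAC code at the
    gene-relative offset; minus-strand genes get positions mirrored and
    alleles complemented.  Indels only mark ``indel_positions`` (at every
    reference base their REF allele spans).  Duplicate records at one site
    merge by allele union.  A variant whose REF disagrees with the gene
    sequence is an input error and raises.
    """
    ivl = gene.interval
    ref = gene.genomic_seq
    snp_alleles: dict[int, set[str]] = {}
    indels: set[int] = set()
    for v in variants:
        if v.chrom != ivl.chrom or not (ivl.start <= v.pos < ivl.end):
            raise ValueError(
                f"variant {v.chrom}:{v.pos + 1} outside gene {gene.gene_id}"
            )
        if v.is_indel:
            for p in range(v.pos, min(v.pos + len(v.ref_allele), ivl.end)):
                indels.add(gene.genomic_to_gene_offset(p))
            continue
        off = gene.genomic_to_gene_offset(v.pos)
        ref_base, alt_bases = v.ref_allele, set(v.alt_alleles)
        if ivl.strand == "-":
            ref_base = ref_base.translate(_COMPLEMENT)
            alt_bases = {a.translate(_COMPLEMENT) for a in alt_bases}
        observed = ref[off]
        if observed != ref_base:
            raise ValueError(
                f"gene {gene.gene_id} position {v.pos + 1} ({v.chrom}): "
                f"expected ref {ref_base}, reference has {observed}"
            )
        snp_alleles.setdefault(off, {ref_base}).update(alt_bases)

    cons = list(ref)
    snp_positions: set[int] = set()
    for off, bases in snp_alleles.items():
        code = _iupac_union(bases)
        if code != ref[off]:
            cons[off] = code
            snp_positions.add(off)
    return ConsensusRecord(
        gene_id=gene.gene_id,
        ref_seq=ref,
        consensus_seq="".join(cons),
        snp_positions=snp_positions,
        indel_positions=indels,
    )


def mask_from_consensus_pair(ref_seq: str, consensus_seq: str) -> set[int]:
    """Mask from a pre-built consensus: every position whose consensus
    character is not exactly the reference base (ambiguity or difference)."""
    if len(ref_seq) != len(consensus_seq):
        raise ValueError("reference and consensus lengths differ")
    return {
        i
        for i, (r, c) in enumerate(zip(ref_seq.upper(), consensus_seq.upper()))
        if c != r
    }


def snp_density_table(records: list[ConsensusRecord]) -> pd.DataFrame:
    """Per-gene SNP density: gene id, gene length, SNP count."""
    rows = [
        {
            "gene_id": r.gene_id,
            "gene_length": len(r.ref_seq),
            "snp_count": len(r.snp_positions),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["gene_id", "gene_length", "snp_count"])


def project_mask_to_cds(gene: GeneModel, mask_gene_frame: set[int]) -> set[int]:
    """Project gene-frame mask offsets into CDS offsets (drops intronic/UTR).

    Gene-frame offset g (coding strand, 0 = gene 5' end) corresponds to a
    genomic position; positions falling inside a coding exon map into the CDS
    through the exon lookup table.
    """
    out: set[int] = set()
    for c0, c1, ivl in gene.cds_exon_spans:
        for off in range(c0, c1):
            chrom, gpos = gene.cds_offset_to_genomic(off)
            g_off = gene.genomic_to_gene_offset(gpos)
            if g_off in mask_gene_frame:
                out.add(off)
    return out


def decode_iupac(code: str) -> set[str]:
    """Bases covered by one IUPAC character."""
    return set(IUPAC_TO_BASES[code.upper()])
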