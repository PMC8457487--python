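"""SNP-avoiding SpCas9 sgRNA enumeration, filtering, scoping and ranking.

Guides are 20-nt protospacers adjacent to an NGG PAM, enumerated over the
CDS of each gene on both strands.  Filtering enforces genotype independence
(no overlap with the population SNP mask), basic composition rules (GC
bounds, no TTTT Pol-III terminator, no ambiguous bases) and contiguity on
the genome (windows spanning exon junctions are discarded — Cas9 cuts DNA,
not mRNA).  Scope classification labels each survivor UNIVERSAL (perfect in
every family member), SPECIFIC (perfect in exactly the target) or SINGLE
(no family context); ranking puts the earliest exon first to maximise the
chance that NHEJ indels frameshift the protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .seqio import GeneModel, GenomicInterval, revcomp

__all__ = [
    "GuideParams",
    "GuideCandidate",
    "Scope",
    "enumerate_protospacers",
    "filter_guides",
    "classify_scope",
    "rank_guides",
    "design_for_family",
    "FamilyGuideReport",
]

_IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def pam_regex(pam: str) -> re.Pattern:
    return re.compile("".join(_IUPAC_RE[c] for c in pam.upper()))


class Scope(str, Enum):
    UNIVERSAL = "UNIVERSAL"
    SPECIFIC = "SPECIFIC"
    SINGLE = "SINGLE"
    #: perfect in more than one but not all members; emitted in no pool
    PARTIAL = "PARTIAL"


@dataclass(frozen=True)
class GuideParams:
    protospacer_len: int = 20
    pam: str = "NGG"
    gc_min: float = 0.40
    gc_max: float = 0.70
    forbid_tttt: bool = True
    max_snp_overlap: int = 0
    require_unambiguous: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.gc_min < self.gc_max <= 1):
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if self.protospacer_len < 16:
            raise ValueError("protospacer_len must be >= 16")


@dataclass
class GuideCandidate:
    guide_id: str
    protospacer: str
    pam_seq: str
    target_gene: str
    genomic_pos: GenomicInterval | None
    exon_index: int  # 1 = first coding exon
    cds_offset: int  # CDS offset of the 5'-most footprint base
    strand: str  # relative to the gene's coding strand
    gc_fraction: float
    snp_overlap: int = 0
    scope: Scope | None = None
    family_matches: dict[str, int] = field(default_factory=dict)
    filters_passed: list[str] = field(default_factory=list)
    offtarget_summary: str = ""

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open CDS-offset range covered by protospacer + PAM."""
        length = len(self.protospacer) + len(self.pam_seq)
        return self.cds_offset, self.cds_offset + length


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def _exon_of_cds_offset(gene: GeneModel, off: int) -> int:
    for idx, (c0, c1, _ivl) in enumerate(gene.cds_exon_spans, 1):
        if c0 <= off < c1:
            return idx
    return len(gene.cds_exon_spans)


def _genomic_footprint(
    gene: GeneModel, cds_start: int, length: int
) -> GenomicInterval | None:
    """Lift a CDS window to the genome; None if it spans an exon junction."""
    if not gene.cds_exon_spans:
        return None
    for c0, c1, ivl in gene.cds_exon_spans:
        if c0 <= cds_start and cds_start + length <= c1:
            if gene.interval.strand == "+":
                start = ivl.start + (cds_start - c0)
                return GenomicInterval(ivl.chrom, start, start + length, "+")
            end = ivl.end - (cds_start - c0)
            return GenomicInterval(ivl.chrom, end - length, end, "-")
    return None


def enumerate_protospacers(
    gene: GeneModel, params: GuideParams = GuideParams()
) -> list[GuideCandidate]:
    """Every PAM-adjacent protospacer window in the CDS, both strands.

    Unfiltered: composition and SNP filters come later so that attrition can
    be reported per reason.  Windows whose genomic footprint is split across
    an exon junction are excluded here (no contiguous genomic target exists).
    """
    cds = gene.cds.upper()
    plen, pam = params.protospacer_len, params.pam.upper()
    pamlen = len(pam)
    pat = pam_regex(pam)
    rc_pat = pam_regex(revcomp(pam))
    out: list[GuideCandidate] = []
    n = 0
    # + strand: [protospacer][PAM]
    for i in range(plen, len(cds) - pamlen + 1):
        if pat.fullmatch(cds[i : i + pamlen]):
            spacer = cds[i - plen : i]
            foot_start = i - plen
            gpos = _genomic_footprint(gene, foot_start, plen + pamlen)
            if gene.cds_exon_spans and gpos is None:
                continue
            if gpos is not None:
                gpos = GenomicInterval(
                    gpos.chrom, gpos.start, gpos.end, gene.interval.strand
                )
            n += 1
            out.append(
                GuideCandidate(
                    guide_id=f"{gene.gene_id}_g{n:04d}+",
                    protospacer=spacer,
                    pam_seq=cds[i : i + pamlen],
                    target_gene=gene.gene_id,
                    genomic_pos=gpos,
                    exon_index=_exon_of_cds_offset(gene, foot_start),
                    cds_offset=foot_start,
                    strand="+",
                    gc_fraction=_gc(spacer),
                )
            )
    # - strand: genomic [PAMrc][protospacer rc]; spacer read 5'->3' off the
    # reverse complement
    for i in range(0, len(cds) - pamlen - plen + 1):
        if rc_pat.fullmatch(cds[i : i + pamlen]):
            window = cds[i + pamlen : i + pamlen + plen]
            spacer = revcomp(window)
            gpos = _genomic_footprint(gene, i, plen + pamlen)
            if gene.cds_exon_spans and gpos is None:
                continue
            if gpos is not None:
                flipped = "-" if gene.interval.strand == "+" else "+"
                gpos = GenomicInterval(gpos.chrom, gpos.start, gpos.end, flipped)
            n += 1
            out.append(
                GuideCandidate(
                    guide_id=f"{gene.gene_id}_g{n:04d}-",
                    protospacer=spacer,
                    pam_seq=revcomp(cds[i : i + pamlen]),
                    target_gene=gene.gene_id,
                    genomic_pos=gpos,
                    exon_index=_exon_of_cds_offset(gene, i),
                    cds_offset=i,
                    strand="-",
                    gc_fraction=_gc(spacer),
                )
            )
    return out


def filter_guides(
    candidates: list[GuideCandidate],
    mask: set[int],
    params: GuideParams = GuideParams(),
) -> tuple[list[GuideCandidate], dict[str, int]]:
    """Apply SNP-avoidance and composition filters.

    Returns (survivors, attrition counts by reason).  Survivors carry the
    list of filters they passed; ``snp_overlap`` is annotated on every
    candidate before filtering.
    """
    kept: list[GuideCandidate] = []
    drops: dict[str, int] = {}

    def drop(reason: str) -> None:
        drops[reason] = drops.get(reason, 0) + 1

    for c in candidates:
        lo, hi = c.footprint
        c.snp_overlap = sum(1 for p in mask if lo <= p < hi)
        if c.snp_overlap > params.max_snp_overlap:
            drop("snp_overlap")
            continue
        if params.require_unambiguous and (
            set(c.protospacer) - set("ACGT") or set(c.pam_seq) - set("ACGT")
        ):
            drop("ambiguous")
            continue
        if not (params.gc_min <= c.gc_fraction <= params.gc_max):
            drop("gc")
            continue
        if params.forbid_tttt and "TTTT" in c.protospacer:
            drop("tttt")
            continue
        c.filters_passed = ["snp_overlap", "ambiguous", "gc", "tttt"]
        kept.append(c)
    return kept, drops


def _occurrences(pattern: str, seq: str) -> int:
    """Exact occurrences of pattern in seq on both strands."""
    count = start = 0
    while (idx := seq.find(pattern, start)) != -1:
        count += 1
        start = idx + 1
    rc = revcomp(pattern)
    start = 0
    while (idx := seq.find(rc, start)) != -1:
        count += 1
        start = idx + 1
    return count


def _best_hamming(pattern: str, seq: str) -> int:
    """Fewest mismatches of pattern against seq at any ungapped offset,
    either strand; gapped matches count as non-matches."""
    best = len(pattern)
    for s in (seq, revcomp(seq)):
        for i in range(len(s) - len(pattern) + 1):
            mm = sum(1 for a, b in zip(pattern, s[i : i + len(pattern)]) if a != b)
            if mm < best:
                best = mm
                if best == 0:
                    return 0
    return best


def classify_scope(
    candidate: GuideCandidate, family: dict[str, str]
) -> GuideCandidate:
    """Label a guide UNIVERSAL / SPECIFIC / SINGLE / PARTIAL within a family.

    ``family`` maps member id -> CDS sequence and must include the target.
    Matching is exact occurrence of protospacer+PAM on either strand;
    ``family_matches`` records the best ungapped Hamming distance per member.
    """
    if candidate.target_gene not in family:
        raise ValueError(
            f"family lacks target gene {candidate.target_gene!r}"
        )
    if len(family) == 1:
        candidate.scope = Scope.SINGLE
        candidate.family_matches = {candidate.target_gene: 0}
        return candidate
    word = candidate.protospacer + candidate.pam_seq
    matches: dict[str, int] = {}
    for member_id, cds in family.items():
        if _occurrences(word, cds.upper()) > 0:
            matches[member_id] = 0
        else:
            matches[member_id] = _best_hamming(word, cds.upper())
    candidate.family_matches = matches
    perfect = [m for m, mm in matches.items() if mm == 0]
    if len(perfect) == len(family):
        candidate.scope = Scope.UNIVERSAL
    elif perfect == [candidate.target_gene]:
        candidate.scope = Scope.SPECIFIC
    else:
        candidate.scope = Scope.PARTIAL
    return candidate


def rank_guides(candidates: list[GuideCandidate]) -> list[GuideCandidate]:
    """Earliest-exon-first stable ordering; drops nothing.

    Sort key: exon index, then CDS offset, then GC distance from 0.5, then
    guide id — an early-exon cut maximises the odds a repair indel
    frameshifts the whole protein.
    """
    return sorted(
        candidates,
        key=lambda c: (
            c.exon_index,
            c.cds_offset,
            abs(c.gc_fraction - 0.5),
            c.guide_id,
        ),
    )


@dataclass
class FamilyGuideReport:
    universal: list[GuideCandidate] = field(default_factory=list)
    specific: dict[str, list[GuideCandidate]] = field(default_factory=dict)
    single: list[GuideCandidate] = field(default_factory=list)
    attrition: dict[str, int] = field(default_factory=dict)

    @property
    def emitted(self) -> list[GuideCandidate]:
        out = list(self.universal) + list(self.single)
        for pool in self.specific.values():
            out.extend(pool)
        return out

    def to_table(self):
        import pandas as pd

        rows = []
        for c in rank_guides(self.emitted):
            g = c.genomic_pos
            rows.append(
                {
                    "guide_id": c.guide_id,
                    "target_gene": c.target_gene,
                    "scope": c.scope.value if c.scope else "",
                    "protospacer": c.protospacer,
                    "pam": c.pam_seq,
                    "chrom": g.chrom if g else "",
                    "start": g.start + 1 if g else "",
                    "end": g.end if g else "",
                    "strand": g.strand if g else c.strand,
                    "exon_index": c.exon_index,
                    "gc_pct": round(100 * c.gc_fraction, 1),
                    "snp_overlap": c.snp_overlap,
                    "offtarget_summary": c.offtarget_summary,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "guide_id", "target_gene", "scope", "protospacer", "pam",
                "chrom", "start", "end", "strand", "exon_index", "gc_pct",
                "snp_overlap", "offtarget_summary",
            ],
        )


def design_for_family(
    family: list[GeneModel],
    masks: dict[str, set[int]],
    genome: dict[str, str],
    params: GuideParams = GuideParams(),
    max_mm: int = 1,
    target_loci: list[GenomicInterval] | None = None,
) -> FamilyGuideReport:
    """Full design pass for one homolog family.

    enumerate -> SNP/composition filter -> scope classification ->
    genome-wide off-target screen -> rank.  Guides rejected at any stage are
    tallied in ``attrition`` so an empty report is always accountable.
    ``masks`` maps gene id -> CDS-frame SNP offsets.
    """
    from .offtarget import screen_guides

    if not family:
        raise ValueError("empty family")
    cds_by_id = {g.gene_id: g.cds for g in family}
    if target_loci is None:
        target_loci = [g.interval for g in family]

    report = FamilyGuideReport()
    survivors: list[GuideCandidate] = []
    for gene in family:
        cands = enumerate_protospacers(gene, params)
        report.attrition["enumerated"] = (
            report.attrition.get("enumerated", 0) + len(cands)
        )
        kept, drops = filter_guides(cands, masks.get(gene.gene_id, set()), params)
        for reason, cnt in drops.items():
            report.attrition[reason] = report.attrition.get(reason, 0) + cnt
        for c in kept:
            classify_scope(c, cds_by_id)
        partial = [c for c in kept if c.scope is Scope.PARTIAL]
        report.attrition["partial_family_match"] = (
            report.attrition.get("partial_family_match", 0) + len(partial)
        )
        survivors.extend(c for c in kept if c.scope is not Scope.PARTIAL)

    decisions, _hit_table = screen_guides(
        survivors, genome, target_loci, max_mm=max_mm
    )
    for c in survivors:
        accepted, summary = decisions[c.guide_id]
        c.offtarget_summary = summary
        if not accepted:
            report.attrition["offtarget"] = (
                report.attrition.get("offtarget", 0) + 1
            )
            continue
        if c.scope is Scope.UNIVERSAL:
            report.universal.append(c)
        elif c.scope is Scope.SPECIFIC:
            report.specific.setdefault(c.target_gene, []).append(c)
        else:
            report.single.append(c)

    report.universal = rank_guides(report.universal)
    report.single = rank_guides(report.single)
    for k in report.specific:
        report.specific[k] = rank_guides(report.specific[k])
    return report
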