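"""Allele / gene-copy / truncated-homolog classification.

Candidate loci recovered for one gene are sorted into biological categories
by nucleotide identity bands, translated-protein comparison and premature
stop codons:

* identity > 98%                          -> allele pair
* identity 80-98%, similar length and identical translated proteins
                                          -> allele pair
* identity 90-98% otherwise (and any member beyond the first two haplotypes)
                                          -> additional gene copy
* internal stop codon in the CDS          -> truncated homolog (pseudogene),
                                             regardless of identity
* anything else                           -> ambiguous, evidence retained

Genomic sequences are compared by default; when a member is shorter than
1 kb, or the pair's lengths diverge badly, the comparison falls back to the
CDS/mRNA sequences (a short or rearranged genomic region makes genomic
identity meaningless).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from Bio import Align, BiopythonWarning
from Bio.Seq import Seq

__all__ = [
    "PairwiseAlignment",
    "ClassifierParams",
    "CandidateRecord",
    "CopyClassification",
    "Label",
    "Basis",
    "global_align",
    "translate",
    "classify_pair",
    "classify_family",
]


class Label(str, Enum):
    ALLELE_PAIR = "ALLELE_PAIR"
    GENE_COPY = "GENE_COPY"
    TRUNCATED_HOMOLOG = "TRUNCATED_HOMOLOG"
    AMBIGUOUS = "AMBIGUOUS"


class Basis(str, Enum):
    GENOMIC = "GENOMIC"
    CDS = "CDS"


@dataclass
class PairwiseAlignment:
    """A global alignment with identity over informative columns.

    ``columns`` excludes terminal-overhang columns (free end gaps) and
    all-gap columns; identity = matches / columns.
    """

    aligned_a: str
    aligned_b: str
    matches: int
    columns: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


@dataclass(frozen=True)
class ClassifierParams:
    allele_identity_min: float = 0.98
    copy_identity_min: float = 0.90
    allele_band_low: float = 0.80
    short_seq_cutoff: int = 1000
    length_ratio_similar: float = 0.80
    #: amino-acid identity treated as "identical proteins"; set to 1.0 for
    #: strict equality
    protein_identity_min: float = 0.99

    def __post_init__(self) -> None:
        if not (
            0
            < self.allele_band_low
            < self.copy_identity_min
            < self.allele_identity_min
            < 1
        ):
            raise ValueError("identity thresholds out of order")


@dataclass
class CandidateRecord:
    """One candidate locus/gene: genomic sequence and (if known) its CDS."""

    member_id: str
    genomic_seq: str
    cds: str | None = None


@dataclass
class CopyClassification:
    member_ids: list[str]
    label: Label
    basis: Basis
    evidence: list[tuple] = field(default_factory=list)
    note: str = ""


_GLOBAL = Align.PairwiseAligner()
_GLOBAL.mode = "global"
_GLOBAL.match_score = 1
_GLOBAL.mismatch_score = -1
_GLOBAL.open_gap_score = -2
_GLOBAL.extend_gap_score = -2
try:  # free terminal gaps (attribute renamed across biopython versions)
    _GLOBAL.end_insertion_score = 0
    _GLOBAL.end_deletion_score = 0
except AttributeError:  # pragma: no cover
    _GLOBAL.target_end_gap_score = 0
    _GLOBAL.query_end_gap_score = 0


def _alignment_strings(aln) -> tuple[str, str]:
    a_blocks, b_blocks = aln.aligned
    target, query = str(aln.target), str(aln.query)
    out_a, out_b = [], []
    # leading overhang
    t0 = a_blocks[0][0] if len(a_blocks) else len(target)
    q0 = b_blocks[0][0] if len(b_blocks) else len(query)
    out_a.append(target[:t0] + "-" * q0)
    out_b.append("-" * t0 + query[:q0])
    tprev, qprev = t0, q0
    for (ta, tb), (qa, qb) in zip(a_blocks, b_blocks):
        out_a.append(target[tprev:ta] + "-" * (qa - qprev))
        out_b.append("-" * (ta - tprev) + query[qprev:qa])
        out_a.append(target[ta:tb])
        out_b.append(query[qa:qb])
        tprev, qprev = tb, qb
    # trailing overhang
    out_a.append(target[tprev:] + "-" * (len(query) - qprev))
    out_b.append("-" * (len(target) - tprev) + query[qprev:])
    return "".join(out_a), "".join(out_b)


def global_align(a: str, b: str) -> PairwiseAlignment:
    """Optimal global alignment (match +1, mismatch -1, gap -2, free ends).

    Identity is matches over columns, where terminal-overhang columns are
    excluded so that a short sequence aligned inside a long one is judged on
    the aligned core only.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _GLOBAL.align(a.upper(), b.upper())[0]
    sa, sb = _alignment_strings(aln)
    # trim terminal overhangs: columns where one string has a terminal gap
    lo = 0
    hi = len(sa)
    while lo < hi and (sa[lo] == "-" or sb[lo] == "-"):
        lo += 1
    while hi > lo and (sa[hi - 1] == "-" or sb[hi - 1] == "-"):
        hi -= 1
    matches = columns = 0
    for ca, cb in zip(sa[lo:hi], sb[lo:hi]):
        if ca == "-" and cb == "-":
            continue
        columns += 1
        if ca == cb:
            matches += 1
    return PairwiseAlignment(sa, sb, matches, columns)


def translate(cds: str) -> tuple[str, bool]:
    """Translate frame 1 with the standard code; report premature stops.

    Returns (protein up to the first stop, premature_stop).  Ambiguous codons
    that resolve to a unique amino acid are translated; others become 'X'.
    A trailing incomplete codon is ignored.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    trimmed = cds[: len(cds) - len(cds) % 3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        try:
            full = str(Seq(trimmed).translate())
        except Exception:
            # codon-by-codon fallback for undecodable ambiguity
            parts = []
            for i in range(0, len(trimmed), 3):
                try:
                    parts.append(str(Seq(trimmed[i : i + 3]).translate()))
                except Exception:
                    parts.append("X")
            full = "".join(parts)
    stop = full.find("*")
    if stop == -1:
        return full, False
    premature = stop < len(full) - 1
    return full[:stop], premature


def polymorphic_columns(seqs: list[str]) -> set[int]:
    """Positions (0-based, frame of the first sequence) where any sequence
    disagrees with the first.

    Center-star style: each sequence is globally aligned to the first;
    mismatch and gap columns are projected onto first-sequence coordinates
    and unioned.  For equal-length, high-identity families (allele sets)
    this equals the variable columns of a full MSA.
    """
    if not seqs:
        return set()
    ref = seqs[0].upper()
    poly: set[int] = set()
    for other in seqs[1:]:
        aln = global_align(ref, other)
        sa, sb = aln.aligned_a, aln.aligned_b
        # core = columns between the first and last where both are aligned
        both = [i for i, (x, y) in enumerate(zip(sa, sb)) if x != "-" and y != "-"]
        if not both:
            continue
        lo, hi = both[0], both[-1] + 1
        ref_pos = sa[:lo].replace("-", "").__len__()
        for ca, cb in zip(sa[lo:hi], sb[lo:hi]):
            if ca == "-":
                continue  # insertion in other; no reference column
            if cb != ca:  # mismatch or internal deletion
                poly.add(ref_pos)
            ref_pos += 1
    return poly


def _proteins_identical(cds_a: str, cds_b: str, params: ClassifierParams) -> bool:
    prot_a, _ = translate(cds_a)
    prot_b, _ = translate(cds_b)
    if not prot_a or not prot_b:
        return False
    if params.protein_identity_min >= 1.0:
        return prot_a == prot_b
    return global_align(prot_a, prot_b).identity >= params.protein_identity_min


def classify_pair(
    a: CandidateRecord,
    b: CandidateRecord,
    params: ClassifierParams = ClassifierParams(),
) -> CopyClassification:
    """Classify one candidate pair; symmetric in its arguments."""
    # basis: genomic unless a member is short or the lengths are dissimilar
    la, lb = len(a.genomic_seq), len(b.genomic_seq)
    ratio = min(la, lb) / max(la, lb)
    use_cds = (
        min(la, lb) < params.short_seq_cutoff
        or ratio < params.length_ratio_similar
    )
    if use_cds:
        basis = Basis.CDS
        if a.cds is None or b.cds is None:
            return CopyClassification(
                member_ids=sorted([a.member_id, b.member_id]),
                label=Label.AMBIGUOUS,
                basis=basis,
                note="CDS comparison required but CDS missing",
            )
        seq_a, seq_b = a.cds, b.cds
    else:
        basis = Basis.GENOMIC
        seq_a, seq_b = a.genomic_seq, b.genomic_seq

    aln = global_align(seq_a, seq_b)
    identity = aln.identity
    have_cds = a.cds is not None and b.cds is not None
    prot_same = _proteins_identical(a.cds, b.cds, params) if have_cds else False
    stops = {}
    for rec in (a, b):
        stops[rec.member_id] = (
            translate(rec.cds)[1] if rec.cds is not None else False
        )
    evidence = [
        (
            tuple(sorted([a.member_id, b.member_id])),
            identity,
            prot_same,
            any(stops.values()),
        )
    ]
    ids = sorted([a.member_id, b.member_id])

    if identity > params.allele_identity_min:
        label = Label.ALLELE_PAIR
    elif (
        params.allele_band_low <= identity <= params.allele_identity_min
        and ratio >= params.length_ratio_similar
        and prot_same
    ):
        label = Label.ALLELE_PAIR
    elif params.copy_identity_min < identity < params.allele_identity_min:
        label = Label.GENE_COPY
    elif any(stops.values()):
        label = Label.TRUNCATED_HOMOLOG
    else:
        label = Label.AMBIGUOUS
    return CopyClassification(
        member_ids=ids, label=label, basis=basis, evidence=evidence
    )


def classify_family(
    members: list[CandidateRecord],
    params: ClassifierParams = ClassifierParams(),
) -> list[CopyClassification]:
    """Classify a whole candidate family; each member appears exactly once.

    Premature-stop members become truncated homologs outright.  The
    remaining members are greedily paired into allele pairs, highest pairwise
    identity first; members beyond the first two haplotypes land as gene
    copies when their identity to the family sits in the copy band.
    """
    if not members:
        raise ValueError("empty family")
    out: list[CopyClassification] = []
    active: list[CandidateRecord] = []
    for rec in members:
        if rec.cds is not None and translate(rec.cds)[1]:
            out.append(
                CopyClassification(
                    member_ids=[rec.member_id],
                    label=Label.TRUNCATED_HOMOLOG,
                    basis=Basis.CDS,
                    note="internal stop codon in CDS",
                )
            )
        else:
            active.append(rec)

    if len(active) == 1 and not out:
        return [
            CopyClassification(
                member_ids=[active[0].member_id],
                label=Label.AMBIGUOUS,
                basis=Basis.GENOMIC,
                note="single member, no comparator",
            )
        ]

    # all-pairs classification among non-truncated members
    pair_results: dict[frozenset, CopyClassification] = {}
    for i in range(len(active)):
        for j in range(i + 1, len(active)):
            res = classify_pair(active[i], active[j], params)
            pair_results[
                frozenset((active[i].member_id, active[j].member_id))
            ] = res

    def pair_identity(res: CopyClassification) -> float:
        return res.evidence[0][1] if res.evidence else 0.0

    unassigned = {rec.member_id: rec for rec in active}
    paired_once = False
    # greedy allele pairing, highest identity first, ids lexicographic on tie
    candidates = sorted(
        (
            (res, key)
            for key, res in pair_results.items()
            if res.label == Label.ALLELE_PAIR
        ),
        key=lambda t: (-pair_identity(t[0]), sorted(t[1])),
    )
    for res, key in candidates:
        ids = sorted(key)
        if all(m in unassigned for m in ids) and not paired_once:
            out.append(res)
            for m in ids:
                del unassigned[m]
            paired_once = True  # >2 haplotypes => further members are copies

    # leftovers: copy-band identity to anything in the family => gene copy
    for mid in sorted(unassigned):
        rec = unassigned[mid]
        best_res, best_id = None, -1.0
        for key, res in pair_results.items():
            if mid in key and pair_identity(res) > best_id:
                best_res, best_id = res, pair_identity(res)
        if best_res is not None and (
            best_res.label == Label.GENE_COPY
            or (paired_once and best_id > params.allele_band_low)
        ):
            out.append(
                CopyClassification(
                    member_ids=[mid],
                    label=Label.GENE_COPY,
                    basis=best_res.basis,
                    evidence=best_res.evidence,
                )
            )
        else:
            out.append(
                CopyClassification(
                    member_ids=[mid],
                    label=Label.AMBIGUOUS,
                    basis=best_res.basis if best_res else Basis.GENOMIC,
                    evidence=best_res.evidence if best_res else [],
                )
            )
    return out


def classification_table(results: list[CopyClassification]):
    """Tab-ready report: ids, label, basis, identity %, protein/stop flags."""
    import pandas as pd

    rows = []
    for res in results:
        ident = res.evidence[0][1] if res.evidence else None
        prot = res.evidence[0][2] if res.evidence else None
        stop = res.evidence[0][3] if res.evidence else (
            res.label == Label.TRUNCATED_HOMOLOG
        )
        rows.append(
            {
                "members": ",".join(res.member_ids),
                "label": res.label.value,
                "basis": res.basis.value,
                "identity_pct": round(100 * ident, 2) if ident is not None else "",
                "proteins_identical": prot,
                "premature_stop": stop,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "members", "label", "basis", "identity_pct",
            "proteins_identical", "premature_stop",
        ],
    )
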