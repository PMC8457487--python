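"""Seed-and-extend local homology search with Karlin-Altschul E-value screening.

Discovery of candidate gene copies works BLASTN-style at desk scale: exact
word seeds anchor candidate regions, a cheap ungapped X-drop extension
discards noise seeds, surviving regions get a full banded-window gapped local
alignment, and hits are screened by the Karlin-Altschul expectation

    E = K * m * n * exp(-lambda * S)

with m the query length and n the total searched sequence length.  The
default threshold E < 1e-10 is deliberately stringent: it is the screen used
for calling gene copies, where a missed borderline hit is preferable to a
spurious extra copy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align

from .seqio import GenomicInterval, revcomp

__all__ = [
    "SearchParams",
    "LocalHit",
    "Locus",
    "build_seed_index",
    "search",
    "merge_hits_to_loci",
    "estimate_evalue",
    "rescore_alignment",
]

_ACGT = set("ACGT")


@dataclass(frozen=True)
class SearchParams:
    """Scoring and screening parameters for the local search.

    lambda_ka and k_ka are the ungapped nucleotide Karlin-Altschul constants
    applied as an approximation for this (mildly gapped) scoring scheme.
    """

    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    evalue_max: float = 1e-10
    lambda_ka: float = 1.28
    k_ka: float = 0.46
    # extension control
    xdrop: int = 20
    band: int = 50
    min_ungapped_score: int = 15

    def __post_init__(self) -> None:
        if self.word_size < 7:
            raise ValueError("word_size must be >= 7")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.evalue_max <= 0 or self.lambda_ka <= 0 or self.k_ka <= 0:
            raise ValueError("evalue_max, lambda_ka, k_ka must be positive")


@dataclass
class LocalHit:
    query_id: str
    subject: GenomicInterval
    score: int
    identity: float
    evalue: float
    query_span: tuple[int, int]
    aligned: tuple[str, str] = ("", "")  # gapped query / subject strings

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0, 1]")


@dataclass
class Locus:
    locus_id: str
    interval: GenomicInterval
    supporting_hits: list[LocalHit] = field(default_factory=list)
    best_query: str = ""


def estimate_evalue(score: int, m: int, n: int, params: SearchParams) -> float:
    """Karlin-Altschul expected number of chance hits at raw score >= score."""
    if m <= 0 or n <= 0:
        raise ValueError("m and n must be positive")
    return params.k_ka * m * n * math.exp(-params.lambda_ka * score)


def build_seed_index(
    genome: dict[str, str], word_size: int
) -> dict[str, list[tuple[str, int, str]]]:
    """Index every exact word on both strands as kmer -> [(chrom, offset, strand)].

    A '-' entry at offset o means the word occurs as the reverse complement of
    genome[o:o+word_size].  Words containing ambiguity codes are skipped.
    """
    index: dict[str, list[tuple[str, int, str]]] = {}
    for chrom, seq in genome.items():
        for off in range(len(seq) - word_size + 1):
            kmer = seq[off : off + word_size]
            if set(kmer) - _ACGT:
                continue
            index.setdefault(kmer, []).append((chrom, off, "+"))
            index.setdefault(revcomp(kmer), []).append((chrom, off, "-"))
    return index


def rescore_alignment(
    aligned_a: str, aligned_b: str, params: SearchParams
) -> int:
    """Score a gapped alignment from its aligned strings (affine gaps)."""
    score = 0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-":
            score += params.gap_extend if in_gap_a else params.gap_open
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score += params.gap_extend if in_gap_b else params.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += params.match if ca == cb else params.mismatch
            in_gap_a = in_gap_b = False
    return score


def _ungapped_xdrop(query: str, subject: str, qpos: int, spos: int, params: SearchParams) -> int:
    """Two-sided ungapped X-drop extension score from a seed match."""
    w = params.word_size
    score = best = params.match * w
    # right
    i, j = qpos + w, spos + w
    run, run_best = 0, 0
    while i < len(query) and j < len(subject):
        run += params.match if query[i] == subject[j] else params.mismatch
        if run > run_best:
            run_best = run
        if run_best - run > params.xdrop:
            break
        i += 1
        j += 1
    score += run_best
    # left
    i, j = qpos - 1, spos - 1
    run, run_best = 0, 0
    while i >= 0 and j >= 0:
        run += params.match if query[i] == subject[j] else params.mismatch
        if run > run_best:
            run_best = run
        if run_best - run > params.xdrop:
            break
        i -= 1
        j -= 1
    return score + run_best


def _aligner(params: SearchParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = params.match
    a.mismatch_score = params.mismatch
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    return a


def _alignment_strings(aln) -> tuple[str, str]:
    # rebuild gapped strings from the aligned block coordinates
    qa, sa = [], []
    (tblocks, qblocks) = aln.aligned
    tprev = qprev = None
    target, query = aln.target, aln.query
    for (t0, t1), (q0, q1) in zip(tblocks, qblocks):
        if tprev is not None:
            qa.append(query[qprev:q0])
            qa.append("-" * (t0 - tprev))
            sa.append("-" * (q0 - qprev))
            sa.append(target[tprev:t0])
        qa.append(query[q0:q1])
        sa.append(target[t0:t1])
        tprev, qprev = t1, q1
    return "".join(qa), "".join(sa)


def search(
    query: str,
    genome: dict[str, str],
    params: SearchParams = SearchParams(),
    query_id: str = "query",
    index: dict[str, list[tuple[str, int, str]]] | None = None,
) -> list[LocalHit]:
    """Find local alignments of query against genome with E < evalue_max.

    Seeds from the word index are clustered by (chrom, strand, diagonal
    band); each cluster is pre-screened by ungapped X-drop extension and, if
    it survives, realigned with a gapped local alignment of the query against
    a subject window around the cluster.  Overlapping hits are deduplicated
    to the highest-scoring.  Results are sorted by ascending E-value.
    """
    query = query.upper()
    w = params.word_size
    if len(query) < w:
        raise ValueError("query shorter than word size")
    amb = sum(1 for c in query if c not in _ACGT)
    if amb > len(query) / 2:
        raise ValueError(
            f"query {query_id!r}: {amb}/{len(query)} ambiguous bases (>50%)"
        )
    if index is None:
        index = build_seed_index(genome, w)
    n_total = sum(len(s) for s in genome.values())
    m = len(query)

    # gather seeds keyed by (chrom, strand, diagonal)
    seeds: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for qpos in range(m - w + 1):
        kmer = query[qpos : qpos + w]
        for chrom, off, strand in index.get(kmer, ()):  # noqa: B905
            if strand == "+":
                diag = off - qpos
            else:
                # on '-' the query kmer matches revcomp(subject word); in
                # reversed-window coordinates the diagonal is off + qpos
                diag = off + qpos
            seeds.setdefault((chrom, strand), []).append((diag, qpos, off))

    aligner = _aligner(params)
    hits: list[LocalHit] = []
    for (chrom, strand), lst in seeds.items():
        seq = genome[chrom]
        lst.sort()
        # cluster seeds whose diagonals are within the band and whose subject
        # positions are within a query length of each other
        clusters: list[list[tuple[int, int, int]]] = []
        for d, qp, sp in lst:
            if (
                clusters
                and d - clusters[-1][-1][0] <= params.band
                and abs(sp - clusters[-1][-1][2]) <= m
            ):
                clusters[-1].append((d, qp, sp))
            else:
                clusters.append([(d, qp, sp)])
        for cl in clusters:
            if strand == "+":
                best_seed = max(
                    cl, key=lambda t: _ungapped_xdrop(query, seq, t[1], t[2], params)
                )
                ung = _ungapped_xdrop(query, seq, best_seed[1], best_seed[2], params)
            else:
                rc_query = revcomp(query)
                # seed at query qpos corresponds to rc_query position m-w-qpos
                def _rc_ext(t):
                    return _ungapped_xdrop(
                        rc_query, seq, m - w - t[1], t[2], params
                    )

                best_seed = max(cl, key=_rc_ext)
                ung = _rc_ext(best_seed)
            if ung < params.min_ungapped_score:
                continue
            _, qp, sp = best_seed
            win_lo = max(0, sp - m - 2 * params.band)
            win_hi = min(len(seq), sp + m + 2 * params.band)
            window = seq[win_lo:win_hi]
            q_aln = query if strand == "+" else revcomp(query)
            alns = aligner.align(window, q_aln)
            aln = alns[0]
            score = int(aln.score)
            qa, sa = _alignment_strings(aln)
            matches = sum(
                1 for a, b in zip(qa, sa) if a == b and a != "-"
            )
            columns = len(qa)
            identity = matches / columns if columns else 0.0
            t0 = int(aln.aligned[0][0][0])
            t1 = int(aln.aligned[0][-1][1])
            q0 = int(aln.aligned[1][0][0])
            q1 = int(aln.aligned[1][-1][1])
            s_start, s_end = win_lo + t0, win_lo + t1
            if strand == "+":
                q_span = (q0, q1)
            else:
                q_span = (m - q1, m - q0)
            ev = estimate_evalue(score, m, n_total, params)
            hits.append(
                LocalHit(
                    query_id=query_id,
                    subject=GenomicInterval(chrom, s_start, s_end, strand),
                    score=score,
                    identity=identity,
                    evalue=ev,
                    query_span=q_span,
                    aligned=(qa, sa),
                )
            )

    hits = _dedup_hits(hits)
    hits = [h for h in hits if h.evalue < params.evalue_max]
    hits.sort(key=lambda h: (h.evalue, h.subject.start, h.subject.strand))
    return hits


def _dedup_hits(hits: list[LocalHit]) -> list[LocalHit]:
    """Drop hits whose subject interval overlaps a better hit by >50%."""
    kept: list[LocalHit] = []
    for h in sorted(
        hits, key=lambda h: (-h.score, h.subject.start, h.subject.strand != "+")
    ):
        redundant = False
        for k in kept:
            if k.subject.chrom != h.subject.chrom:
                continue
            ov = min(k.subject.end, h.subject.end) - max(
                k.subject.start, h.subject.start
            )
            if ov > 0.5 * min(len(k.subject), len(h.subject)):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def merge_hits_to_loci(hits: list[LocalHit], merge_gap: int = 5000) -> list[Locus]:
    """Merge same-chrom, same-strand hits within merge_gap into candidate loci.

    The locus count for one query is its reported copy number.  Output order
    and content are invariant to the order of the input hit list.
    """
    by_key: dict[tuple[str, str], list[LocalHit]] = {}
    for h in hits:
        by_key.setdefault((h.subject.chrom, h.subject.strand), []).append(h)
    loci: list[Locus] = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda h: (h.subject.start, h.subject.end))
        current: list[LocalHit] = []
        for h in group:
            if current and h.subject.start - current[-1].subject.end <= merge_gap:
                current.append(h)
            else:
                if current:
                    loci.append(_make_locus(chrom, strand, current))
                current = [h]
        if current:
            loci.append(_make_locus(chrom, strand, current))
    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start, l.interval.strand))
    for i, locus in enumerate(loci, 1):
        locus.locus_id = f"locus_{i}"
    return loci


def _make_locus(chrom: str, strand: str, group: list[LocalHit]) -> Locus:
    start = min(h.subject.start for h in group)
    end = max(h.subject.end for h in group)
    best = max(group, key=lambda h: h.score)
    return Locus(
        locus_id="",
        interval=GenomicInterval(chrom, start, end, strand),
        supporting_hits=list(group),
        best_query=best.query_id,
    )


def hits_table(hits: list[LocalHit]):
    """Hit table in BLAST outfmt-6-like column order (1-based coordinates)."""
    import pandas as pd

    rows = [
        {
            "query_id": h.query_id,
            "chrom": h.subject.chrom,
            "start": h.subject.start + 1,
            "end": h.subject.end,
            "strand": h.subject.strand,
            "score": h.score,
            "identity_pct": round(100 * h.identity, 2),
            "evalue": h.evalue,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query_id", "chrom", "start", "end",
            "strand", "score", "identity_pct", "evalue",
        ],
    )
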