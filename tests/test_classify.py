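"""Allele / copy / truncated-homolog decision procedure."""

import numpy as np
import pytest

from panguide.classify import (
    Basis,
    CandidateRecord,
    ClassifierParams,
    Label,
    classify_family,
    classify_pair,
    global_align,
    polymorphic_columns,
    translate,
)
from panguide.fixtures import FamilySpec, simulate_family

PARAMS = ClassifierParams()


def _nw_score_oracle(a, b, match=1, mismatch=-1, gap=-2):
    """Independent quadratic DP: global score with free terminal gaps."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = 0  # free left end gaps
    for j in range(1, m + 1):
        H[0][j] = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
    # free right end gaps: best over last row/column
    return max(max(H[n]), max(H[i][m] for i in range(n + 1)))


def _score_from_alignment(aln):
    score = 0
    sa, sb = aln.aligned_a, aln.aligned_b
    lo, hi = 0, len(sa)
    while lo < hi and (sa[lo] == "-" or sb[lo] == "-"):
        lo += 1
    while hi > lo and (sa[hi - 1] == "-" or sb[hi - 1] == "-"):
        hi -= 1
    for ca, cb in zip(sa[lo:hi], sb[lo:hi]):
        if ca == "-" or cb == "-":
            score -= 2
        elif ca == cb:
            score += 1
        else:
            score -= 1
    return score


class TestGlobalAlign:
    def test_identity_case(self):
        assert global_align("ACGT", "ACGT").identity == 1.0

    def test_single_substitution(self):
        aln = global_align("ACGTACGT", "ACGTTCGT")
        assert (aln.matches, aln.columns) == (7, 8)
        assert aln.identity == pytest.approx(0.875)

    def test_terminal_overhangs_excluded_from_identity(self):
        # short sequence inside a long one: identity judged on the core
        assert global_align("AAAACGTACGTAAAA", "CGTACGT").identity == 1.0

    def test_substitution_pairs_match_dp_oracle(self):
        """On indel-free pairs the optimal alignment is the diagonal, so
        identity and score are both uniquely determined."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=150))
            b = list(a)
            k = rng.integers(1, 12)
            for pos in rng.choice(len(a), size=k, replace=False):
                b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
            b = "".join(b)
            aln = global_align(a, b)
            assert _score_from_alignment(aln) == _nw_score_oracle(a, b)
            # the optimal alignment can only improve on the diagonal one
            assert (len(a) - k) / len(a) - 1e-9 <= aln.identity <= 1.0

    def test_gapped_pairs_score_matches_dp_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=120))
            cut = int(rng.integers(20, 100))
            b = a[:cut] + a[cut + 3 :]  # 3-nt deletion
            aln = global_align(a, b)
            assert _score_from_alignment(aln) == _nw_score_oracle(a, b)


class TestTranslate:
    @pytest.mark.parametrize(
        "cds,protein,premature",
        [
            ("ATGGCTTAA", "MA", False),
            ("ATGTAAGCT", "M", True),
            ("ATGGCNGCT", "MAA", False),
        ],
    )
    def test_examples(self, cds, protein, premature):
        assert translate(cds) == (protein, premature)

    def test_unresolvable_codon_becomes_x(self):
        prot, _ = translate("ATGNNN")
        assert prot == "MX"

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate("AT")


def _mutated(seq, k, seed, transversion=False):
    rng = np.random.default_rng(seed)
    out = list(seq)
    table = (
        {"A": "T", "T": "A", "C": "G", "G": "C"}
        if transversion
        else {"A": "G", "G": "A", "C": "T", "T": "C"}
    )
    for pos in rng.choice(len(seq), size=k, replace=False):
        out[pos] = table[out[pos]]
    return "".join(out)


class TestClassifyPair:
    @pytest.fixture()
    def base(self):
        seqs, _, _ = simulate_family(
            FamilySpec(n_members=1, member_divergence=(0.0,), gene_len=1200,
                       n_exons=1, seed=77)
        )
        return seqs["m1"]

    def test_high_identity_is_allele_pair(self, base):
        b = _mutated(base, 6, 1)  # 0.5% divergence
        res = classify_pair(
            CandidateRecord("a", base, base), CandidateRecord("b", b, b), PARAMS
        )
        assert res.label is Label.ALLELE_PAIR

    def test_mid_identity_differing_proteins_is_gene_copy(self, base):
        b = _mutated(base, 60, 2, transversion=True)  # ~5%, protein-altering
        res = classify_pair(
            CandidateRecord("a", base, base), CandidateRecord("b", b, b), PARAMS
        )
        assert res.label is Label.GENE_COPY

    def test_mid_identity_identical_proteins_is_allele_pair(self, base):
        # synonymous-only divergence of ~3% via the generator
        seqs, _, _ = simulate_family(
            FamilySpec(n_members=2, member_divergence=(0.0, 0.03),
                       allele_of={"m2": "m1"}, gene_len=1200, n_exons=1, seed=78)
        )
        a, b = seqs["m1"], seqs["m2"]
        ident = global_align(a, b).identity
        assert ident < 0.98  # genuinely in the protein-evidence band
        res = classify_pair(
            CandidateRecord("a", a, a), CandidateRecord("b", b, b), PARAMS
        )
        assert res.label is Label.ALLELE_PAIR

    def test_symmetric_in_arguments(self, base):
        b = _mutated(base, 40, 3)
        ra = classify_pair(
            CandidateRecord("a", base, base), CandidateRecord("b", b, b), PARAMS
        )
        rb = classify_pair(
            CandidateRecord("b", b, b), CandidateRecord("a", base, base), PARAMS
        )
        assert (ra.label, ra.member_ids) == (rb.label, rb.member_ids)

    def test_short_sequences_fall_back_to_cds(self, base):
        short = base[:600]
        res = classify_pair(
            CandidateRecord("a", short, short),
            CandidateRecord("b", short, short),
            PARAMS,
        )
        assert res.basis is Basis.CDS

    def test_missing_cds_when_required_is_ambiguous(self, base):
        res = classify_pair(
            CandidateRecord("a", base[:500], None),
            CandidateRecord("b", base[:500], None),
            PARAMS,
        )
        assert res.label is Label.AMBIGUOUS
        assert "CDS" in res.note


class TestClassifyFamily:
    def test_allele_plus_paralog_family(self):
        seqs, spans, labels = simulate_family(
            FamilySpec(n_members=3, member_divergence=(0.0, 0.005, 0.06),
                       allele_of={"m2": "m1"}, gene_len=1500, n_exons=1, seed=9)
        )
        recs = [CandidateRecord(m, s, s) for m, s in seqs.items()]
        results = classify_family(recs, PARAMS)
        got = {}
        for r in results:
            for m in r.member_ids:
                got[m] = r.label
        assert got["m1"] is Label.ALLELE_PAIR
        assert got["m2"] is Label.ALLELE_PAIR
        assert got["m3"] is Label.GENE_COPY

    def test_truncated_member_flagged_regardless_of_identity(self):
        seqs, spans, labels = simulate_family(
            FamilySpec(n_members=3, member_divergence=(0.0, 0.0, 0.0),
                       truncate=frozenset({"m3"}), gene_len=1500, n_exons=1,
                       seed=10)
        )
        recs = [CandidateRecord(m, s, s) for m, s in seqs.items()]
        results = classify_family(recs, PARAMS)
        by_member = {m: r.label for r in results for m in r.member_ids}
        assert by_member["m3"] is Label.TRUNCATED_HOMOLOG
        assert by_member["m1"] is Label.ALLELE_PAIR
        assert by_member["m2"] is Label.ALLELE_PAIR

    def test_single_member_is_ambiguous(self):
        res = classify_family([CandidateRecord("x", "ATG" + "ACG" * 200 + "TAA")])
        assert len(res) == 1
        assert res[0].label is Label.AMBIGUOUS

    def test_every_member_covered_exactly_once(self):
        seqs, _, _ = simulate_family(
            FamilySpec(n_members=4, member_divergence=(0.0, 0.005, 0.05, 0.05),
                       allele_of={"m2": "m1"}, truncate=frozenset({"m4"}),
                       gene_len=1200, n_exons=1, seed=12)
        )
        recs = [CandidateRecord(m, s, s) for m, s in seqs.items()]
        results = classify_family(recs, PARAMS)
        covered = sorted(m for r in results for m in r.member_ids)
        assert covered == sorted(seqs)


class TestPolymorphicColumns:
    def test_counts_union_of_differences(self):
        ref = "ATGGCTGCTGCTGCTTAA"
        s2 = ref[:4] + "G" + ref[5:]
        s3 = ref[:10] + "T" + ref[11:]
        assert polymorphic_columns([ref, s2, s3]) == {4, 10}

    def test_no_variation(self):
        assert polymorphic_columns(["ACGT" * 10] * 3) == set()
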