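"""sgRNA enumeration, filtering, scoping and ranking."""

import random
import re

import numpy as np
from panguide.fixtures import FamilySpec, implant_family, simulate_genome
from panguide.guides import (
    GuideParams,
    Scope,
    classify_scope,
    design_for_family,
    enumerate_protospacers,
    filter_guides,
    rank_guides,
)
from panguide.seqio import GeneModel, GenomicInterval, revcomp

PARAMS = GuideParams()


def _single_exon_gene(cds, gene_id="g", start=0):
    ivl = GenomicInterval("chr1", start, start + len(cds), "+")
    return GeneModel(
        gene_id=gene_id,
        interval=ivl,
        exons=[ivl],
        cds=cds,
        genomic_seq=cds,
        cds_exon_spans=[(0, len(cds), ivl)],
    )


def _brute_force_windows(cds, plen=20):
    """Oracle: every NGG-adjacent window on both strands via regex."""
    out = set()
    for m in re.finditer(r"(?=([ACGT])GG)", cds):
        i = m.start()
        if i >= plen:
            out.add(("+", i - plen, cds[i - plen : i]))
    rc = revcomp(cds)
    for m in re.finditer(r"(?=([ACGT])GG)", rc):
        i = m.start()
        if i >= plen:
            # map back to forward coordinates of the footprint start
            fwd_start = len(cds) - (i + 3)
            out.add(("-", fwd_start, rc[i - plen : i]))
    return out


class TestEnumerate:
    def test_single_plus_strand_pam(self):
        cds = "GTTTAACCTTAACCGGTTAAAGG"  # AGG at the very end
        cands = enumerate_protospacers(_single_exon_gene(cds), PARAMS)
        plus = [c for c in cands if c.strand == "+"]
        assert any(c.pam_seq == "AGG" and c.cds_offset == 0 for c in plus)

    def test_minus_strand_pam_from_ccn_prefix(self):
        rng = np.random.default_rng(0)
        cds = "CCT" + "".join(rng.choice(list("ACGT"), size=20))
        cands = enumerate_protospacers(_single_exon_gene(cds), PARAMS)
        minus = [c for c in cands if c.strand == "-"]
        assert len(minus) >= 1
        c = minus[0]
        assert c.pam_seq == revcomp(cds[:3])
        assert c.protospacer == revcomp(cds[3:23])

    def test_matches_regex_scan_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            cds = "".join(rng.choice(list("ACGT"), size=2000))
            cands = enumerate_protospacers(_single_exon_gene(cds), PARAMS)
            got = {(c.strand, c.cds_offset, c.protospacer) for c in cands}
            assert got == _brute_force_windows(cds)

    def test_no_pam_empty(self):
        assert enumerate_protospacers(_single_exon_gene("AT" * 30), PARAMS) == []

    def test_junction_spanning_windows_excluded(self, family_genome):
        genome, truth = family_genome
        gene = truth.members["m1"].gene
        chrom = genome[gene.interval.chrom]
        for c in enumerate_protospacers(gene, PARAMS):
            g = c.genomic_pos
            word = chrom[g.start : g.end]
            if g.strand == "-":
                word = revcomp(word)
            assert word == c.protospacer + c.pam_seq  # contiguous on genome


class TestFilter:
    def _cand(self, spacer, pam="AGG", off=0):
        gene = _single_exon_gene(spacer + pam + "A" * 30)
        cands = enumerate_protospacers(gene, PARAMS)
        return [c for c in cands if c.cds_offset == off and c.strand == "+"]

    def test_snp_overlap_dropped(self):
        spacer = "ACGT" * 5
        cands = self._cand(spacer)
        kept, drops = filter_guides(cands, mask={10}, params=PARAMS)
        assert kept == []
        assert drops.get("snp_overlap", 0) >= 1

    def test_gc_bound_dropped(self):
        cands = self._cand("ATATATATATATATATATAT")
        kept, drops = filter_guides(cands, mask=set(), params=PARAMS)
        assert kept == []
        assert drops.get("gc", 0) >= 1

    def test_tttt_dropped(self):
        cands = self._cand("GCGCGCGCGCGATTTTACAG")  # GC 0.6, has TTTT
        kept, drops = filter_guides(cands, mask=set(), params=PARAMS)
        assert kept == []
        assert drops.get("tttt", 0) >= 1

    def test_noop_filter_passes_everything(self):
        rng = np.random.default_rng(4)
        cds = "".join(rng.choice(list("ACGT"), size=500))
        gene = _single_exon_gene(cds)
        cands = enumerate_protospacers(gene, PARAMS)
        lax = GuideParams(gc_min=0.0, gc_max=1.0, forbid_tttt=False)
        kept, drops = filter_guides(cands, mask=set(), params=lax)
        assert len(kept) == len(cands)
        assert drops == {}


class TestScope:
    def test_universal_and_specific(self):
        rng = np.random.default_rng(6)
        shared = "".join(rng.choice(list("ACGT"), size=23))
        core = "".join(rng.choice(list("ACGT"), size=200))
        m1 = shared + core + "TGCAGTACGATCGATTACAGCGG"
        m2 = shared + core[:100] + "T" + core[101:] + "A" * 23
        m3 = shared + core[:50] + "G" + core[51:] + "C" * 23
        gene = _single_exon_gene(m1, "m1")
        family = {"m1": m1, "m2": m2, "m3": m3}
        cands = enumerate_protospacers(gene, GuideParams(gc_min=0, gc_max=1,
                                                         forbid_tttt=False))
        scoped = [classify_scope(c, family) for c in cands]
        by_word = {c.protospacer + c.pam_seq: c for c in scoped}
        for word, c in by_word.items():
            n_present = sum(
                word in s or revcomp(word) in s for s in family.values()
            )
            if n_present == 3:
                assert c.scope is Scope.UNIVERSAL
            elif n_present == 1 and word in m1:
                assert c.scope is Scope.SPECIFIC
        assert any(c.scope is Scope.UNIVERSAL for c in scoped)
        assert any(c.scope is Scope.SPECIFIC for c in scoped)

    def test_specific_mismatch_counts_recorded(self):
        rng = np.random.default_rng(7)
        m1 = "".join(rng.choice(list("ACGT"), size=120))
        m2 = m1[:60] + ("A" if m1[60] != "A" else "C") + m1[61:]
        gene = _single_exon_gene(m1, "m1")
        fam = {"m1": m1, "m2": m2}
        for c in enumerate_protospacers(gene, GuideParams(gc_min=0, gc_max=1)):
            classify_scope(c, fam)
            if c.scope is Scope.SPECIFIC:
                assert c.family_matches["m1"] == 0
                assert c.family_matches["m2"] >= 1

    def test_single_member_family(self):
        rng = np.random.default_rng(8)
        m1 = "".join(rng.choice(list("ACGT"), size=100))
        gene = _single_exon_gene(m1, "m1")
        cands = enumerate_protospacers(gene, GuideParams(gc_min=0, gc_max=1))
        if cands:
            c = classify_scope(cands[0], {"m1": m1})
            assert c.scope is Scope.SINGLE


class TestRank:
    def _mk(self, gid, exon, off, gc):
        from panguide.guides import GuideCandidate

        return GuideCandidate(
            guide_id=gid, protospacer="A" * 20, pam_seq="AGG",
            target_gene="g", genomic_pos=None, exon_index=exon,
            cds_offset=off, strand="+", gc_fraction=gc,
        )

    def test_earliest_exon_wins_regardless_of_gc(self):
        g1 = self._mk("a", 2, 0, 0.5)
        g2 = self._mk("b", 1, 500, 0.9)
        assert rank_guides([g1, g2])[0].guide_id == "b"

    def test_gc_tiebreak_closest_to_half(self):
        g1 = self._mk("a", 1, 10, 0.7)
        g2 = self._mk("b", 1, 10, 0.55)
        assert rank_guides([g1, g2])[0].guide_id == "b"

    def test_ranking_is_permutation(self):
        guides = [self._mk(f"g{i}", i % 3 + 1, i * 7 % 50, 0.4 + i * 0.01)
                  for i in range(20)]
        shuffled = guides[:]
        random.Random(0).shuffle(shuffled)
        assert sorted(c.guide_id for c in rank_guides(shuffled)) == sorted(
            c.guide_id for c in guides
        )
        assert [c.guide_id for c in rank_guides(shuffled)] == [
            c.guide_id for c in rank_guides(guides)
        ]


class TestDesignForFamily:
    def test_two_member_family_yields_universal_and_specific(self):
        genome = simulate_genome(60_000, seed=21)
        spec = FamilySpec(
            n_members=2, member_divergence=(0.0, 0.05), gene_len=900,
            n_exons=2, snp_rate=0.02, seed=8,
        )
        genome, truth = implant_family(genome, spec)
        genes = [m.gene for m in truth.members.values()]
        from panguide.consensus import apply_variants, project_mask_to_cds

        masks = {
            mid: project_mask_to_cds(m.gene, apply_variants(m.gene, m.variants).mask)
            for mid, m in truth.members.items()
        }
        report = design_for_family(genes, masks, genome, PARAMS, max_mm=0)
        assert len(report.universal) >= 1
        for mid in truth.members:
            assert len(report.specific.get(mid, [])) >= 1
        # guarantee: no emitted footprint touches the mask
        for c in report.emitted:
            lo, hi = c.footprint
            assert not any(lo <= p < hi for p in masks[c.target_gene])

    def test_single_gene_all_single_scope(self):
        genome = simulate_genome(30_000, seed=22)
        spec = FamilySpec(n_members=1, member_divergence=(0.0,), gene_len=600,
                          n_exons=1, snp_rate=0.0, seed=5)
        genome, truth = implant_family(genome, spec)
        gene = truth.members["m1"].gene
        report = design_for_family([gene], {"m1": set()}, genome, PARAMS, max_mm=0)
        assert report.universal == [] and report.specific == {}
        assert all(c.scope is Scope.SINGLE for c in report.single)
        assert len(report.single) > 0

    def test_full_mask_exhausts_candidates_with_attrition(self):
        genome = simulate_genome(30_000, seed=23)
        spec = FamilySpec(n_members=1, member_divergence=(0.0,), gene_len=600,
                          n_exons=1, snp_rate=0.0, seed=6)
        genome, truth = implant_family(genome, spec)
        gene = truth.members["m1"].gene
        full_mask = set(range(len(gene.cds)))
        report = design_for_family([gene], {"m1": full_mask}, genome, PARAMS, max_mm=0)
        assert report.emitted == []
        assert report.attrition["snp_overlap"] == report.attrition["enumerated"]
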