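# Methods

`panguide` implements a genotype-independent genome-editing design workflow
for plant gene families: find every copy of a gene in an assembly, decide
which candidates are alleles, extra copies or pseudogenes, overlay
population variation, and design Cas9 guides that work on any genotype.
This note records the models, parameters and design choices behind each
stage, and what the synthetic test data does and does not establish.

## Homology search (`panguide.homology`)

Candidate gene copies are found by seed-and-extend local alignment.  Exact
`word_size`-mers (default 11) shared between query and genome anchor
candidate regions; seeds on one diagonal band (half-width 50) within a query
length of each other are clustered and extended once.  A cheap two-sided
ungapped X-drop extension (drop 20) discards noise seeds below a minimum
ungapped score of 15; survivors are realigned with a gapped local alignment
(match +1, mismatch −2, gap open −5, gap extend −2; the affine DP is
Biopython's `PairwiseAligner`) against a window of ±(query length + 100)
around the anchor.  Hits overlapping a better hit by more than 50% of the
shorter interval are dropped.

Hits are screened by the Karlin–Altschul expectation
`E = K·m·n·exp(−λ·S)` with `m` the query length, `n` the total genome
length, and the ungapped nucleotide constants λ = 1.28, K = 0.46 used as an
approximation for this scoring scheme.  The default acceptance threshold
`E < 1e−10` is deliberately stringent because the locus count downstream is
reported as a copy number: a missed borderline hit is preferable to a
spurious extra copy.  Hits on one chromosome and strand within `merge_gap`
(default 5000 nt, comfortably larger than typical plant introns) merge into
one locus, so an intron-split alignment still counts as a single copy.

Caveats: the ungapped prefilter can, in principle, suppress a true hit whose
every seed neighbourhood is interrupted by indels; at the divergences the
tool targets (≤ 20%) some seed always sits in a clean stretch.  The
Karlin–Altschul constants are not re-estimated for the gapped scheme, so
E-values are approximate — which is why the screen is used as a threshold,
not as a reported statistic.

## Allele / copy / pseudogene classification (`panguide.classify`)

Candidates for one gene are compared by optimal global alignment with free
terminal gaps (match +1, mismatch −1, gap −2).  Identity is matches over
aligned core columns: terminal-overhang columns are excluded so a fragment
aligned inside a longer sequence is judged on the shared region.  The
decision bands are:

* identity > 98% → allele pair;
* identity 80–98% with similar lengths (ratio ≥ 0.80) and identical
  translated proteins → allele pair;
* identity 90–98% otherwise → additional gene copy;
* internal stop codon → truncated homolog, regardless of identity;
* otherwise → ambiguous, with the evidence retained.

Comparisons use genomic sequence unless a member is shorter than 1000 nt or
the length ratio falls below 0.80, in which case the CDS/mRNA is compared
instead (basis recorded in the output).  "Identical proteins" defaults to
≥ 99% amino-acid identity — a single conservative substitution should not
demote an allele — and can be tightened to strict equality
(`protein_identity_min=1.0`).

At family level, members with premature stops are set aside first as
truncated homologs; the rest are greedily paired into at most one allele
pair (highest identity first, ties by id).  Once two haplotypes are
assigned, every further member with ≥ 80% identity to the family is an
additional copy: a diploid locus has two haplotypes, so a third
high-identity sequence must be another copy.  Where the 80–98%+protein rule
and the 90–98% copy rule overlap, protein evidence wins for the first pair
and loses thereafter — this keeps both rules consistent for the
two-alleles-plus-extra-copy families the workflow is built for.

The boundary values themselves (98.0%, 90.0%) use strict inequalities for
the allele band and open interval for the copy band; behaviour exactly at a
boundary is documented by the code rather than biologically meaningful.

## Consensus and SNP masks (`panguide.consensus`)

Population variants (VCF) are overlaid onto each gene: at a SNP the
consensus character becomes the IUPAC code covering reference plus all
alternate alleles; the SNP mask is the set of changed positions.
Minus-strand genes have positions mirrored and alleles complemented so the
mask lives on the coding strand.  Indels are masked (a guide must avoid
them too) but never shift coordinates: guide design operates in the
reference frame, and a length-altering consensus would desynchronise mask
and sequence.  Duplicate records at one site merge by allele union.  Depth
and quality filtering are upstream concerns; any VCF row passing FILTER is
trusted.  SNP density is reported per gene span; CDS-restricted masks are
obtained by projection (`project_mask_to_cds`), since intronic SNPs are
irrelevant to CDS-frame guides.

## Guide design (`panguide.guides`)

Protospacers are all 20-nt windows 5′ of an NGG PAM, enumerated on both
strands of each CDS.  Windows whose genomic footprint crosses an exon
junction are excluded — Cas9 cuts genomic DNA, and a junction-spanning CDS
window has no contiguous genomic target — trading yield for correctness.
Filters: zero SNP-mask overlap over protospacer+PAM (the genotype-
independence guarantee; configurable), GC fraction within [0.40, 0.70], no
TTTT run (Pol-III terminator), no ambiguous bases.  These composition
bounds are ordinary guide-design practice, exposed in `GuideParams`.

Scope within a homolog family is decided by exact occurrence of
protospacer+PAM in each member's CDS (either strand): present in all →
UNIVERSAL, present in exactly the target → SPECIFIC, family of one →
SINGLE.  A guide perfect in more than one but not all members gets the
fourth label PARTIAL and is emitted in no pool — it is neither universally
usable nor discriminating, and silently binning it as either would be
wrong.  Recorded per-member mismatch counts use the best ungapped Hamming
match; gapped matches count as non-matches.

Ranking is a stable sort by (exon index, CDS offset, |GC − 0.5|, id):
the earliest possible exon first, because an NHEJ indel there frameshifts
the largest fraction of the protein.

## Off-target screening (`panguide.offtarget`)

Every genomic site within `max_mm` mismatches of a protospacer is found by
pigeonhole seed partitioning: the spacer is split into `max_mm + 1`
contiguous seeds, every exact seed occurrence (string scan, both strands)
is extended to a full-window Hamming comparison.  This is complete — no
heuristic sensitivity loss — for `max_mm ≤ 4`, which is where the method is
capped.  A guide is rejected iff a 0-mismatch, PAM-adjacent, full-length
site exists outside the target family's loci; mismatched sites are reported
for review but do not reject, since in-planta tolerance of single
mismatches is unresolved.  Whether reported (non-rejecting) sites must be
PAM-adjacent is a flag; rejection always requires the PAM.

## Synthetic data (`panguide.fixtures`)

The generator emulates the structures the pipeline must resolve: i.i.d.
background sequence at a chosen GC; an ancestral gene with a valid ORF and
GT…AG introns; members mutated from it at specified per-site rates
(binomially sampled counts, uniform placement); allele members restricted
to intron positions and four-fold-degenerate third codon positions so their
proteins are identical by construction; copy members with unrestricted
substitutions, except that nonsense changes are resampled so copies remain
protein-coding unless truncation is requested; truncated members get one
mid-CDS TAA.  Per-member SNPs are placed uniformly at `snp_rate` per site
(default 1%, the order of diversity seen in outbreeding crop panels).
Implants are spaced ≥ 10 kb so locus merging can never fuse distinct
copies.  Everything derives from one integer seed and is byte-reproducible.

Default study conditions used by the test suite and the acceptance script:
allele divergence 0.5% per site, copy divergence 5%, SNP density 1–2%,
families of 1–5 members in 40–100 kb genomes, 200 replicates for the
statistical recovery rates, 50 families for the guide guarantees.  Genome
and family sizes are desk-scale on purpose: every guarantee checked is
either exact (oracle equivalence, direct rescans) or statistical with
binomial error bars, and neither changes qualitatively with sequence
length.

What the generator does *not* emulate: repeat families, nested or
pericentromeric gene clusters, segmental duplications, hemizygosity,
sequencing or assembly error, and realistic linkage between SNPs.  Passing
tests therefore demonstrate algorithmic correctness on clean signals, not
robustness to assembly artefacts — on a real genome, repeat-induced spurious
loci and collapsed copies remain the user's responsibility to inspect.

Two deterministic analogues of published worked examples are included
(`cbcas_analogue`, `oac_analogue`): a pair of 1635-bp synthase-like genes
identical except one synonymous C>T at base pair 662, and a three-member
family (allele pair + copy) whose CDS alignment carries exactly 14
polymorphic columns.  They are constructed stand-ins with the same
structure and summary numbers as the published sequences, which are not
redistributed here.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally, 1-based inclusive in every
  human-facing report; the conversion happens only at I/O boundaries.
* Alignment identity of an empty core is defined as 0.
* A single-member family classifies as AMBIGUOUS (no comparator), never as
  an allele of itself.
* Ambiguous codons translate to their unique amino acid when one exists,
  otherwise 'X'; a trailing incomplete codon is ignored.
* Queries with > 50% ambiguous bases are refused by the homology search;
  guides containing any ambiguity are refused by the off-target search and
  dropped by the composition filter.
* Tie-breaks everywhere are lexicographic on ids after the scientific keys,
  making every ordering deterministic for fixed inputs.

## Known limitations

* E-values use ungapped Karlin–Altschul constants; they are screening
  thresholds, not publishable statistics.
* Off-target counting is ungapped; DNA/RNA-bulge off-targets are out of
  scope, as are efficiency scores (Doench-style) and chromatin
  accessibility.
* The classifier assumes a diploid reference; polyploid haplotype counts
  would need a generalised pairing rule.
* Scope classification matches against CDS sequences of the family, not
  whole gene spans; a guide overlapping intron-adjacent CDS in one member
  but intronic sequence in another is conservatively non-matching.
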