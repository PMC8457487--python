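# panguide

**Genotype-independent CRISPR sgRNA design for plant gene families.**

Knocking out a gene with Cas9 in an outbreeding crop runs into three
problems at once: the gene usually exists as several highly similar copies
(alleles, paralogs, truncated pseudogenes), the population carries SNPs that
can silently break a guide on some genotypes, and near-identical family
members invite off-target cutting.  `panguide` is a toolkit for the whole
design workflow:

1. **Find every copy** — seed-and-extend local homology search of a query
   gene against a genome assembly, with Karlin–Altschul screening
   (`E = K·m·n·e^{−λS}`, accepted at `E < 10⁻¹⁰`) and merging of nearby
   hits into candidate loci, whose count is the copy number.
2. **Classify the copies** — allele pair (global-alignment identity > 98%,
   or 80–98% with identical translated proteins), additional gene copy
   (90–98% beyond the first two haplotypes), or truncated homolog
   (premature stop codon), on genomic or CDS basis as lengths dictate.
3. **Mask population variation** — overlay VCF variants (or a pre-built
   IUPAC consensus FASTA) onto each gene, producing a consensus sequence
   and the SNP mask a genotype-independent guide must avoid.
4. **Design guides** — enumerate all 20-nt NGG protospacers in each CDS,
   drop any touching the SNP mask (plus GC / TTTT / ambiguity filters),
   label each guide **universal** (perfect in every family member) or
   **specific** (perfect in exactly one), and rank earliest-exon-first for
   maximal frameshift likelihood.
5. **Confirm off-targets** — complete mismatch-tolerant genome search
   (pigeonhole seeds, exact for ≤ 4 mismatches); a guide is rejected iff a
   perfect, PAM-adjacent, full-length match exists outside its own family's
   loci.

A synthetic-data module generates genomes with implanted gene families,
alleles, pseudogenes and SNPs with known ground truth, so the entire
pipeline is testable offline.

## Worked example

```python
from panguide.fixtures import FamilySpec, implant_family, simulate_genome
from panguide.homology import SearchParams, search, merge_hits_to_loci
from panguide.classify import CandidateRecord, classify_family, classification_table
from panguide.consensus import apply_variants, project_mask_to_cds
from panguide.guides import GuideParams, design_for_family

genome = simulate_genome(60_000, gc=0.5, seed=42)
spec = FamilySpec(n_members=3, member_divergence=(0.0, 0.005, 0.05),
                  allele_of={"m2": "m1"}, gene_len=900, n_exons=2,
                  snp_rate=0.01, seed=42)
genome, truth = implant_family(genome, spec)

hits = search(truth.members["m1"].gene.genomic_seq, genome,
              SearchParams(), query_id="m1")
loci = merge_hits_to_loci(hits, merge_gap=5000)
```

The search recovers all three implanted copies:

```
3 loci found for query m1:
  locus_1  chr1:5001-6200    identity 1.000  E 0.00e+00
  locus_2  chr1:21667-22866  identity 0.998  E 0.00e+00
  locus_3  chr1:38333-39532  identity 0.949  E 0.00e+00
```

Classification separates the allele pair from the diverged extra copy —
m1/m2 align at 99.8% with identical proteins (alleles), m3 at 94.9% with a
changed protein (gene copy):

```
members       label   basis  identity_pct  proteins_identical  premature_stop
  m1,m2 ALLELE_PAIR GENOMIC         99.83                True           False
     m3   GENE_COPY GENOMIC         94.92               False           False
```

Guide design on the SNP-masked family then yields pools of both kinds:

```
universal guides: 66, specific: {'m3': 37}
top universal guide: TCCATGACCTGGCTGTAGTG PAM AGG exon 1 at chr1:5065-5087
```

Every universal guide occurs perfectly in all three members and avoids
every masked SNP; the specific guides exploit m3's private differences.
(m1 and m2, being alleles at 99.8% identity, offer almost no discriminating
windows — exactly why their pool is empty here.)

The same pipeline runs from the shell on FASTA + GFF3 + VCF inputs:

```bash
panguide run --config pipeline.yaml     # search → classify → consensus → design
panguide search --genome g.fa --queries q.fa --out hits.tsv
panguide design --genome g.fa --gff3 genes.gff3 --vcf snps.vcf --out guides.tsv
```

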