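# Methods

## Screening model

The screen consumes a joint-genotyped cohort VCF (the product of per-sample
haplotype calling and joint genotyping on a small resequenced panel; read
alignment and variant calling are upstream of this package) and applies six
stages in a fixed order:

1. **Annotation hard filter.** Inclusive bounds on site quality and the
   standard GATK annotations: QD >= 2.0, QUAL >= 30.0, FS <= 60.0,
   MQ >= 40.0, MQRankSum >= −12.5, ReadPosRankSum >= −8.0. A boundary value
   passes. An annotation absent from a record (rank-sum statistics are
   undefined at sites lacking both homozygote classes) skips its criterion
   and is reported as `missing-annotation` rather than failing the site —
   the behaviour of GATK's VariantFiltration.
2. **Isolated biallelic SNPs.** A candidate must be a single-base
   substitution with exactly one ALT and no *other variant of any type* at
   distance <= 100 bp on the same chromosome ("within 100 bp" is read
   inclusively: 100 bp separation excludes, 101 bp retains). Isolation is
   evaluated against all records present at this stage.
3. **High-confidence tag.** Records meeting the same bounds with
   QUAL >= 1000.0 are tagged `FIRSTOK`; the tag is required for candidacy
   (tagging itself never deletes records, so the tagged VCF can be kept).
4. **Population filters.** Minor allele frequency >= 0.05 over non-missing
   genotypes, missing-call fraction <= 0 (every sample typed), and a
   Hardy–Weinberg p-value >= 0.001. The default HWE test is the exact test
   (the behaviour of the VCFtools `--hwe` filter); chi-square is available.
5. **Isolation re-check** against the surviving loci. Because stage-2
   survivors are already pairwise separated, this re-check removes nothing
   on clean data; it is retained as a structural guarantee when the screen
   is entered mid-pipeline.
6. **Informativeness band.** 0.2 <= PIC <= 0.5 (inclusive), with PIC
   computed from cohort allele frequencies over non-missing genotypes.

One caveat on monotonicity: relaxing any per-record threshold (MAF, HWE,
missingness, PIC band, the FIRSTOK quality bar) or shrinking the isolation
window can only grow the surviving set, and the test suite asserts this.
Relaxing a *stage-1 hard-filter* bound can in principle shrink it, because a
reintroduced record may crowd a previously isolated neighbour out of stage 2;
this is inherent to the stage ordering, not an implementation artifact.

## Exact Hardy–Weinberg test

Conditional on the typed sample count n and minor allele count m, the null
distribution of the heterozygote count h (parity of m) is

P(h) ∝ n! · 2^h / (n_hommaj! · n_hommin! · h!) · m!(2n−m)!/(2n)!

computed in log space. The two-sided p-value sums P(h′) over all h′ with
P(h′) <= P(h_obs), with a 1 + 1e−12 relative guard so symmetric
configurations of equal probability count as ties. The test suite verifies
this against an independent oracle that enumerates all C(2n, m) placements
of minor-allele copies into 2n ordered allele slots for every configuration
with n <= 10. Monomorphic loci return p = 1 by convention.

## Diversity report

Per locus: Na (observed alleles), Ne = 1/Σp², Shannon–Wiener I = −Σp ln p
in natural-log units, Ho (heterozygotes/typed), He = 1 − Σp² *without* the
small-sample 2n/(2n−1) correction (this convention is what reproduces the
published validation table exactly), F_IS = (He − Ho)/He (0 when He = 0),
MAF as the **major** allele frequency (the convention of the
GenAlEx-style report; the screening filter's `maf_min`, like the VCFtools
flag, thresholds the minor allele), Botstein PIC, and the HWE p-value. The
report's default HWE method is chi-square with one degree of freedom
against (p², 2pq, q²); the exact test is a switch. The NS/* conformity
flags at α = 0.05 are method-sensitive at heterozygote-deficit loci —
chi-square flags more loci than the exact test — so flag columns from
different tools should not be compared directly. Means are unweighted
arithmetic means over loci. All values are carried at full precision;
half-up rounding to 3 decimals happens only at serialization.

`counts_from_summary(Ho, MAF, n)` inverts a printed report row back to
integer genotype counts (het = round(Ho·n), minor alleles =
round((1−MAF)·2n), homozygote split by parity), raising when no
non-negative configuration reconciles the inputs. `infer_typed_n` picks the
sample count (30, 29, 28) that makes Ho·n closest to an integer —
published panels typically have a locus or two typed in n−1 individuals.

## Synthetic-data generator

The generator emulates the *products* of a resequencing study, not the
reads: a reference genome (i.i.d. bases at a target GC fraction, default
0.41), a 12-sample cohort VCF at ~1 variant per 2 kb, and population
genotype matrices for ~30 individuals.

* **Cohort sites.** Per chromosome the variant count is
  Binomial(length, density) and positions are drawn without replacement,
  so coordinates are unique and strictly increasing; a density implying
  more sites than bases is an error. REF is read from the reference, ALT
  drawn from the other three bases.
* **Annotations** are uniform draws from configurable ranges whose defaults
  (QD 15–35, FS 0–10, MQ 50–60, rank sums ±2, QUAL 1200–3000) sit well
  inside the pass region including the QUAL >= 1000 tag, because the
  screening thresholds are bounds, not distributions — the generator's job
  is a controlled baseline.
* **Genotypes** are multinomial Hardy–Weinberg draws at a per-site minor
  allele frequency from Uniform(0.2, 0.5). At 12 samples, sampling noise
  alone would occasionally push a clean site below the MAF floor, the PIC
  band or the HWE threshold; such draws are redrawn (up to 20 times, then
  replaced by the rounded HWE expectation). This makes the unmodified
  cohort a guaranteed-pass baseline so that planted violations are the
  *only* marginal causes of rejection — the property the truth-table
  oracle needs. The redraw slightly truncates the genotype-count
  distribution of the cohort VCF; the population-matrix generator used for
  parameter recovery does no such filtering.
* **Planted violations.** `plant_violations` picks victims only among
  records that survive the default screen on the clean cohort, then
  overwrites one property per victim: QD 1.0, QUAL 20.0 (or 500.0 for a
  tag-only failure), FS 80.0, MQ 30.0, rank sums −15/−10, an added third
  allele, a companion SNP 50 bp away (planted in pairs, at sites whose
  existing neighbours are > 260 bp away so only the pair is affected), a
  single-heterozygote genotype vector (MAF 1/24), one knocked-out call, a
  zero-heterozygote 50:50 vector (extreme HWE departure with in-band MAF
  and PIC), or a two-heterozygote vector (PIC ≈ 0.14, below the band, with
  MAF above the floor). The truth table maps criterion → locus IDs, and
  by construction the screened survivor set of the planted cohort equals
  the clean survivor set minus the truth table (recall = precision = 1).
* **Population matrices.** Genotype frequencies p² + fpq, 2pq(1−f),
  q² + fpq (clipped and renormalized) allow negative-f heterozygote excess;
  calls are multinomial per locus, coded 0/1/2 copies of the minor allele,
  with i.i.d. missingness. What the generator does **not** model: linkage
  between loci, genotyping error, allele dropout, null alleles, or
  population structure — so passing recovery tests show estimator
  correctness under the stated law, not robustness to real-data artifacts.

## Panel selection

"Evenly distributed" is operationalized as: largest-remainder quotas per
chromosome (proportional to chromosome length by default, since candidate
density varies; equal-per-chromosome as the alternative), then equal-width
positional bins over each chromosome's candidate span with one seeded
uniform draw per bin. Empty-bin slots are backfilled from the nearest bins
with unused candidates, so the panel size equals the target whenever
feasible. The seed is mandatory in the spec object so published panels are
reproducible. No optimal-spacing or linkage-aware pruning is attempted.

## KASP assay geometry

Forward bodies are the last `body_length − 1` reference bases left of the
SNP plus the allele base (3′ terminus), tails prepended verbatim (FAM to
the first allele listed, by convention the reference allele; the
assignment is recorded on the sheet). The common reverse primer is the
reverse complement of the plus-strand window starting `reverse_offset`
bases right of the SNP. Defaults (body 22, offset 30, length 22) are
placeholders of realistic magnitude: commercial assay design optimizes
primer thermodynamics, which this package deliberately does not replicate
— its contribution is the bookkeeping from screened locus to orderable
sheet, with the tail constants and 1:1:3 premix metadata exact.

## Problem sizes and numerical choices

The test suite runs on two-chromosome references of 200 + 150 kb
(~175-record cohorts), a 1 Mb single-chromosome instance (~500 records)
for the screening oracle, exhaustive HWE enumeration up to n = 10, and
parameter recovery at n = 10,000 individuals with 3-SD tolerances derived
from binomial/delta-method variances (plus 0.01 slack on F_IS for the
neglected He variance). Reports round half-up at 3 decimals; all internal
comparisons use full precision. Genotypes are unphased throughout; the
simulated VCF dialect is minimal v4.2 (contig, INFO, FORMAT/GT headers),
written via pysam and read via cyvcf2.

## Known limitations

Whole-genome scale streaming is out of scope (records are held in memory);
multi-population statistics (F_ST, AMOVA), kinship and linkage
disequilibrium are not computed; indels are not simulated realistically
(isolation crowding uses position only); the published study's discovery
counts depend on its real accessions and wet-lab outcomes and are not
targets of the synthetic pipeline, which validates behaviour by
planted-truth and oracle equivalence instead.
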