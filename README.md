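# kaspanel

Genome-wide SNP screening, KASP assay construction, and population-genetic
validation for conservation marker panels.

`kaspanel` implements, as a tested and reusable pipeline, the workflow used
to develop KASP-genotyped SNP marker panels for the Yangtze finless porpoise
(*Neophocaena asiaeorientalis asiaeorientalis*): starting from a
joint-genotyped multi-sample VCF and a chromosome-level reference genome, it
screens candidate SNPs, subsamples an evenly distributed panel, builds
allele-specific primer sets, and computes the per-locus diversity report
used to validate the panel on a population sample. A synthetic-data module
generates reference sequences, annotated cohort VCFs with planted filter
violations, and genotype matrices with known parameters, so every stage is
testable end to end without any sequencing data.

## The method

**Screening.** Sites from a cohort VCF pass, in order:

1. GATK-style hard filter (inclusive bounds):
   `QD >= 2.0 && QUAL >= 30.0 && FS <= 60.0 && MQ >= 40.0 && MQRankSum >= -12.5 && ReadPosRankSum >= -8.0`
2. biallelic SNPs with no other variant within 100 bp either side
   (protects primer-binding context),
3. a high-confidence tag (`FIRSTOK`) requiring `QUAL >= 1000.0` with the
   same annotation bounds, required for candidacy,
4. VCFtools-style population filters: minor allele frequency >= 0.05, no
   missing genotypes (`--max-missing 1`), Hardy–Weinberg exact-test
   p >= 0.001,
5. an isolation re-check, and an informativeness band
   0.2 <= PIC <= 0.5 on Botstein's polymorphism information content,

   PIC = 1 − Σᵢ pᵢ² − Σᵢ<ⱼ 2 pᵢ² pⱼ²  (for two alleles: 1 − (p²+q²) − 2p²q²).

**Panel selection.** Per-chromosome quotas by largest-remainder
apportionment (proportional to chromosome length, or equal per chromosome),
then one seeded uniform draw per equal-width positional bin within each
chromosome.

**KASP design.** For each panel SNP, ±150 bp flanks are extracted from the
reference; two allele-specific forward primers share a body ending at the
SNP (the allele at the 3′ terminus) and carry the universal fluorescent
tails FAM `GAAGGTGACCAAGTTCATGCT` and VIC `GAAGGTCGGAGTCAACGGATT`; a common
reverse primer is the reverse complement of a downstream window. Primer
premix ratio F1:F2:R = 1:1:3 is recorded on the order sheet.

**Validation statistics.** From a loci × samples genotype matrix, per locus:
Na, Ne = 1/Σp², Shannon–Wiener I = −Σp ln p (nats), Ho, He = 1 − Σp²,
F_IS = (He − Ho)/He, major allele frequency (MAF), PIC, and a
Hardy–Weinberg test (chi-square, or exact by enumeration conditional on
allele counts), with an unweighted means row.

## Worked example

Reproduce one row of the published 19-marker validation report from its
genotype counts (13 major homozygotes, 9 heterozygotes, 8 minor
homozygotes in 30 individuals):

```python
from kaspanel.popgen import locus_summary, round3

s = locus_summary([0]*13 + [1]*9 + [2]*8)
print(round3(s.ne), round3(s.shannon), round3(s.ho), round3(s.he),
      round3(s.fis), round3(s.maf), round3(s.pic))
```

prints

```
1.946 0.679 0.3 0.486 0.383 0.583 0.368
```

i.e. the marker segregates at major-allele frequency 0.583, carries an
effective 1.946 alleles and Shannon diversity 0.679 nats, shows a
heterozygote deficit (Ho 0.300 vs He 0.486, F_IS 0.383), and its PIC of
0.368 sits in the moderately-polymorphic band. The full pipeline runs from
a shell:

```sh
kaspanel run --out-dir run1 --seed 5
```

which simulates a reference and a 12-sample cohort, screens candidates,
selects a 50-SNP panel, designs KASP primer sets, and writes the diversity
report, a per-stage count log and a manifest into `run1/`. Each stage is
also available as its own subcommand (`simulate`, `screen`, `select-panel`,
`design-kasp`, `stats`) operating on plain VCF/TSV/CSV files.

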