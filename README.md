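# sitpipe

Rare-variant inheritance-model prioritization and brain-asymmetry group
statistics for *situs inversus totalis* (SIT) cohorts.

SIT — complete mirror reversal of the thoracic and abdominal organs — is
genetically heterogeneous: roughly half of cases carry disruptive biallelic
variants in motile-cilia genes (often shared with primary ciliary
dyskinesia, PCD), while the rest have no identifiable monogenic cause.
`sitpipe` implements the analysis that splits such a cohort into
genetically **solved** and **unsolved** cases from annotated genome
sequencing calls, and then asks whether that causal heterogeneity is
reflected in functional and structural brain asymmetry. It is written for
researchers in laterality genetics who have per-individual annotated
variant calls, a candidate-gene panel and image-derived asymmetry
phenotypes, and want the full pipeline — filtering, inheritance models,
enrichment, relatedness QC and the statistics battery — reproducible from
one seed.

## What it computes

**Variant retention cascade.** Per called variant: caller hard filters
(SNVs: QD < 2, FS > 60, MQ < 40, HaplotypeScore > 13, MQRankSum < −12.5,
ReadPosRankSum < −8; indels: QD < 2, FS > 200, ReadPosRankSum < −20),
consequence class (exonic or splicing within 2 bp of a boundary;
synonymous/unknown excluded), deleteriousness (CADD phred ≥ 20, or an
AlphaMissense-pathogenic rescue for missense SNVs below it), genotype
quality (SNV DP ≥ 7, indel DP ≥ 10, GQ ≥ 20, heterozygous allelic balance
no more extreme than 3:1), and a model-specific gnomAD allele-frequency
cutoff (recessive ≤ 0.005, dominant ≤ 5 × 10⁻⁵; absent frequency = novel,
retained).

**Inheritance models.** Per individual and gene, retained variants form a
genotype configuration; a gene qualifies under the recessive/X-linked
model with a homozygous variant, an unphased pair of heterozygous variants
(potential compound heterozygote — a cis-phased pair is vetoed), or any
variant on chromosome X in a male; under the dominant model with one
retained variant at the stricter frequency cutoff. Genes qualifying in
controls are subtracted (recessive: ≥ 1 control; dominant: > 1 control),
surviving genes are matched to a candidate panel with confirmed
inheritance modes (recessive first, dominant only for cases left
unsolved), and each case is called solved/unsolved, with
unconfirmed-candidate hits recorded as notable.

**Around the core.** Hypergeometric gene-set over-representation with
set-size bounds 15–500 and minimum intersection 2 (Bonferroni default, BH
option); genotype QC (MAF ≥ 0.05, variant missingness ≤ 2%, sample
missingness ≤ 10%), greedy LD pruning (window 200, step 50, r² ≤ 0.2) and
KING-robust kinship φ̂ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i) + N_Aa(j)) with the
0.354 / 0.0884 classification bands and 2^k sensitivity exclusion sets;
and per-outcome ANCOVA (`outcome ~ group + age + sex`, Type II SS, partial
η²) with Holm families, Tukey-corrected estimated-marginal-mean contrasts
and Hedges' g, a median-centered Levene test on the atypical-laterality
count, and Fisher's exact test on left-handedness.

A synthetic-cohort generator (`sitpipe.cohort_sim`) emulates the full
study design — 38 cases and 38 controls, 19 planted causal genotypes in a
configurable recessive/compound-het/X-linked/dominant mix, shared rare
background variation, two sibling pairs in the kinship matrix, and
phenotypes with case–control torque effects but null functional-laterality
effects — with known ground truth, so every stage runs and is testable
without any data access.

## Worked example

```sh
sitpipe simulate --seed 1 --out study
sitpipe prioritize --vcf study/cohort.vcf --individuals study/individuals.tsv \
    --candidates study/candidates.tsv --out report
sitpipe kinship --genotypes study/genotypes.tsv --out kinship.tsv
sitpipe stats --phenotypes study/phenotypes.tsv --individuals study/individuals.tsv \
    --calls report/calls.tsv --out stats.json
```

prints

```
INFO sitpipe: wrote synthetic study to study
INFO sitpipe: solved 19 of 38 cases
INFO sitpipe: 4905 variants after QC, 4841 after pruning, 2 related pairs
INFO sitpipe: wrote statistics to stats.json
```

The prioritizer recovered all 19 planted causal genotypes and no false
positives (`report/calls.tsv` lists each case's status, assigned gene,
model and notable genes); the kinship stage found exactly the two planted
sibling pairs (φ ≈ 0.25) among 2 850 sample pairs; and in `stats.json` the
planted occipital-bending reversal is detected (Holm-adjusted p = 0.0004)
while frontal bending, with no planted effect, is not. The same library
calls are available in Python via `sitpipe.simulate_cohort`,
`sitpipe.run_prioritization` and `sitpipe.run_stat_battery`.

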