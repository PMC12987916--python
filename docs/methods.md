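# Methods

This note documents the models and procedures `sitpipe` implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Inputs and file dialects

Annotation is consumed, never computed. The annotated VCF uses a fixed
INFO dialect (`GENE`, `CSQ_CLASS`, `SPLICE_DIST`, `CADD`, `AM_CLASS`,
`GNOMAD_AF`, site metrics `QD/FS/MQ/HAPSCORE/MQRS/RPRS`, flags `LEGACY`
and `PHASED_CIS`) with per-sample `GT/DP/GQ/AD`. Numeric INFO values are
written as VCF Strings so a write/read cycle is lossless at full float
precision. Multiallelic records are rejected rather than silently split:
zygosity derivation from GT is only well defined on pre-split records.
Coordinates are 1-based VCF positions; no liftover. Phenotypes,
candidate genes, the cohort table and the kinship genotype matrix
(samples × variants, dosages 0/1/2/NA) are plain TSV; reports are TSV +
JSON with sorted keys, byte-stable for fixed inputs.

Phase is an input attribute (`PHASED_CIS`), not something the package
infers from reads: short-read phasing evidence, where available, is
produced upstream. A gene whose heterozygous pair is marked cis is vetoed
as a compound-heterozygote candidate.

## Variant filter semantics

All inequalities are implemented exactly as the rules are stated:
"DP below 7" fails 6 and passes 7; CADD "≥ 20" retains 20.0; allelic
balance "more extreme than 3:1 or 1:3" is strict, so an exact 1:3 read
ratio is retained (0.25 ≤ alt fraction ≤ 0.75). Absent site metrics never
fail a site filter; the AB rule applies only to heterozygous calls, and a
het call with zero informative reads fails with `AB_UNDEFINED`.

Three deliberate choices:

- **Absent allele frequency = novel = retained** under both models. A
  variant unobserved in the reference population is exactly the kind of
  rare allele the cascade is meant to keep.
- **The AlphaMissense-benign exclusion acts only on the CADD < 20 rescue
  path.** A missense variant at CADD ≥ 20 is retained even when classed
  benign; the rescue (CADD < 20 but pathogenic) is restricted to missense,
  the only class AlphaMissense scores.
- **`legacy_retained` bypasses the deleteriousness rule only.** Cohorts
  assembled in stages may carry calls scored by an earlier pipeline
  version (here: inframe indels at CADD 16/17); they are flagged in the
  input rather than loosening the threshold for everything else.
- **Splicing calls lacking a distance annotation count as within-boundary**:
  the annotator already classed them as splicing.

## Gene models and solved assignment

Configurations per (individual, gene): `hom`, `chet_unphased`,
`chet_phased_cis`, `x_hemi` (male, all variants on chromosome X),
`single_het`, with precedence hom → chet → x_hemi. Recessive/X-linked
qualification: `hom`, `chet_unphased` or `x_hemi`. Dominant
qualification: at least one retained variant of any zygosity.

Control subtraction mirrors the qualification criteria: a gene qualifying
in ≥ 1 control (recessive) or > 1 control (dominant) is removed from every
case. The dominant rule's control scope is configurable (`pooled` default,
`stage_II`): the published analysis phrases the dominant subtraction for
stage II controls, but summarizes the pooled cohort, and the pooled run is
what the per-individual table reflects. Controls are scored with the
identical case criteria when counting controls that meet them; a control
is flagged when a qualifying recessive gene matches the candidate panel
regardless of confirmation status.

Assignment is recessive-first: a case solved under the recessive/X-linked
model is never evaluated dominantly. A solved call requires the candidate
panel to confirm the matching mode (`recessive` for hom/chet
configurations, `x_linked` for hemizygous, `dominant` otherwise);
qualifying candidates with unconfirmed mode are recorded as notable and
leave the case unsolved. When two or more confirmed candidates qualify in
one individual — a situation the source cohort never presents — the call
picks the gene with the most deleterious supporting variant (maximum
CADD), then the lexicographically first symbol, and sets a tie flag. This
tie rule is a documented convention of this package, not an observed
practice.

## Enrichment

Over-representation is the upper-tail hypergeometric probability of the
observed overlap, with term-size bounds 15–500 and minimum intersection 2;
sets outside the bounds are skipped before correction. The background is
the collection's explicit gene universe (configurable), and gene identity
is plain symbol matching — collections must be pre-mapped. The
hierarchy-aware g:SCS-style correction is not implemented; Bonferroni
(default) or Benjamini–Hochberg is applied per query list, so adjusted
p-values are conservative relative to analyses using hierarchy-aware
corrections. The reciprocal exclusion removes case-qualifying genes from
the control list (case lists already exclude control genes via
subtraction), making the control list a size-comparable negative control.

## Relatedness

QC order is fixed: variant filters first (MAF ≥ 0.05 computed from
observed calls, missingness ≤ 2%), then sample missingness ≤ 10% on the
surviving variants. LD pruning is greedy within sliding windows of 200
variants advanced by 50: while any retained pair in the window exceeds
r² = 0.2 (Pearson correlation of dosages, pairwise deletion of missing
calls), the lower-MAF member is dropped, the later position on an exact
tie. The tie-break is unspecified in the field's common tooling, so the
*identity* of the retained set may differ from other implementations; the
within-window r² audit is the invariant contract, and re-pruning a pruned
matrix is a fixed point. KING-robust uses the between-family estimator
throughout (appropriate for cohort screening), with classification bands
φ > 0.354 (duplicate/MZ) and φ > 0.0884 (second-degree or closer); the
published sibling estimates 0.232 and 0.293 fall in the second band.
Sensitivity exclusion sets are the Cartesian product of one member per
related pair (k pairs → 2^k re-runs of the statistics battery).

## Statistics battery

Each outcome is fit as `outcome ~ group + age + sex` by OLS; the group
test uses Type II sums of squares (the default of the R routine this
emulates; Type III is available via `ss_type`), and partial η² is
SS_group/(SS_group + SS_resid). Holm correction is applied within the
three outcome families (4 laterality indexes, 4 torque metrics, 2 sinus
volumes). Post-hoc contrasts run only for outcomes with Holm-adjusted
p < 0.05: the adjusted mean difference is the difference of fitted group
coefficients (equal to the estimated-marginal-mean difference under the
additive model), with familywise p from the studentized range on the
model's residual degrees of freedom. Hedges' g uses the pooled-SD
standardized difference with small-sample correction J = 1 − 3/(4·df − 1),
computed from the **raw** group data by default; whether the original
analysis standardized raw or covariate-adjusted differences is not
stated, so an adjusted variant is provided (`adjusted_g=True`).

The atypical-laterality count is the number of tasks (0–4) whose
laterality index has the opposite sign to the control mean for that task;
an index of exactly zero counts as typical (the sign convention for this
measure-zero case is otherwise undefined), and a zero control mean is an
error. Variance homogeneity of the count uses the median-centered Levene
(Brown–Forsythe) form. Handedness is dichotomized left vs non-left
(ambidextrous → non-left) for the solved-vs-unsolved Fisher test.

Degenerate inputs are flagged rather than fabricated: a constant outcome
yields F = 0/η² = 0 with a degenerate flag, all-zero Levene deviations a
degenerate flag, and a singular design matrix an error.

## Synthetic generator

The generator's defaults are the study conditions: 38 cases (15 stage I,
23 stage II) and 38 controls; 19 solved cases in a
0.35/0.45/0.05/0.15 mixture of homozygous-recessive, compound-het,
X-linked and dominant configurations (largest-remainder apportionment:
7/8/1/3); X-linked cases forced male. Planted variants are constructed to
pass every filter rule (about one in five via the AlphaMissense rescue
path), with allele frequencies log-uniform below the model cutoff
(recessive < 5 × 10⁻³, dominant < 5 × 10⁻⁵) and one in five novel.
Background singles land only in non-candidate genes, so planted solved
status is exactly recoverable; dedicated constructs exercise the
subtraction step (a chet gene shared by one case and one control) and the
notable path (chet in unconfirmed candidates). Two sibling pairs are
planted among the cases by Mendelian transmission from simulated parental
haplotypes over 5 000 independent loci with frequencies Uniform(0.05, 0.5).

Phenotype effects default to standardized case-vs-control differences of
0.70 (frontal petalia), 0.90 (occipital petalia), 1.05 (occipital
bending), 0 (frontal bending), 0.5 SD on both sinus volumes — identical
for solved and unsolved groups — and 0 on all four laterality indexes.
Torque noise is Gaussian with unit within-group SD: no distributional
model is reported for the real measures, and Gaussian is the minimal
assumption consistent with ANCOVA. Laterality indexes are drawn as a
positive magnitude around a task-typical signed mean (word −1.5, praxis
−1.2, spatial +1.0, face +0.8, SD 0.5) whose sign flips with probability
0.08 (controls) / 0.15 (cases) per task; these flip rates are loosely
anchored to the ~30% vs ~48% atypicality figures reported for controls
and SIT cases in earlier functional-imaging work and are config-exposed,
not asserted. The atypical count is always computed from the *emitted*
indexes against the *emitted* control means. Age and sex carry no
phenotype effects by default.

What the generator does **not** emulate: linkage disequilibrium beyond
independent loci, realistic per-gene variant density or annotation error,
sequencing reads, population stratification, and covariate effects on
phenotypes. Passing tests therefore demonstrate the correctness of the
pipeline's logic and the calibration of its statistics under the study's
effect structure — not robustness to those real-data complications.

## Problem sizes

The test suite and acceptance script use: 20 generator seeds for
end-to-end recovery; 1 000 random variants for filter-oracle equivalence;
2 000 null replicates for ANCOVA and Levene type-I calibration at the
study's 19/19/38 group sizes; 500 replicates for Hedges'-g recovery of
the planted occipital-bending effect (1.01); 200 replicate sibling pairs
at 5 000 loci for the kinship oracle. These sizes give Monte-Carlo
standard errors well inside the asserted bands (e.g. SE ≈ 0.005 on a 0.05
rejection rate at 2 000 replicates; SE ≈ 0.013 on the mean recovered g).

## Known limitations

- No read-backed or trio phasing; phase is consumed, not inferred.
- No CNV or non-coding variant handling; the cascade is exonic/splicing.
- Symbol-level gene identity throughout (no ID mapping).
- Bonferroni/BH instead of hierarchy-aware gene-set correction.
- The dominant-model gene lists are typically too large relative to the
  number of contributing individuals for meaningful enrichment; dominant
  enrichment is exposed but not run by default.
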