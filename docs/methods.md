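# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish.

## Data model

Cohorts are held as a variant table (pandas), dense genotype matrices
(variants × samples, int8 dosage with −1 for missing; males on chrX carry
hemizygous dosage {0,1}), parallel DP/GQ/AD matrices, and a sample table.
Multi-allelic VCF rows are split into biallelic records before analysis;
the pre-split ALT count is retained so the "more than four alternate
alleles" site filter remains well defined. Variant identity is
(chrom, pos, ref, alt) after shared-suffix/prefix trimming; full
left-alignment against a reference FASTA is not attempted, as the
pipeline both writes and consumes parsimony-normalized records. Male
heterozygous calls on non-PAR X are biologically inconsistent; they are
set missing and counted in a QC anomaly log rather than allowed to create
hemizygous carriers. Pseudo-autosomal regions are out of model: the only
X-linked panel gene is non-PAR.

## QC and candidate selection

Genotype-level: a call is set missing when DP < 8, GQ < 20, or — for
heterozygous calls only — the minor-read ratio
min(ref, alt)/(ref+alt) < 0.20. Homozygous and hemizygous calls are
exempt from the ratio rule, which would otherwise reject nearly all good
homozygotes; a heterozygote with no usable AD is set missing under a
distinct log reason. Site-level (after recomputing missingness): drop
sites in the user-supplied low-complexity/decoy BED mask (BED [s, e)
masks 1-based positions s+1..e), sites with > 4 ALT alleles, > 10%
missing genotypes, or spanning > 15 nt. All thresholds live in
`FilterConfig` and are overridable.

Candidate sets over the gene panel: the primary set is missense + pLOF +
essential-splice variants with population MAF < 1e-4 and CADD strictly
above the gene's mutation significance cutoff (a documented flag switches
to ≥); the pLOF set is its pLOF subset; a pLOF set without any MAF or MSC
restriction; and rare synonymous variants (no CADD rule) as a negative
control. MSC values are configuration supplied with the panel, not
recomputed. Consequence classes come from the annotation file; the
package does not re-annotate.

## Recessive collapsing

Per sample per gene, one call with the strongest mechanism:
homozygous-deletion (from a consumed deletion-call table, copy number 0
only, joined by gene), homozygous (any qualifying site at dosage 2),
hemizygous (male, X-linked gene, dosage 1), then compound heterozygosity
(≥2 distinct qualifying heterozygous sites). With trio genotypes, a pair
of sites with determined opposite parental origins confirms the trans
configuration; if every qualifying site has a determined origin and all
share one parent, the cis configuration is refuted and no call is made;
anything less determined stays "potential" — and potential compound
heterozygotes count as carriers, since without parental data that is the
honest state of knowledge. Panel-level carrier status is having at least
one call in the given variant set. Segregation checking reports Mendelian
violations (a genotyped parent of an autosomal homozygote carrying zero
alleles; a hemizygote's mother carrying none) separately from unaffected
relatives who share the full genotype, which are incomplete-penetrance
observations, not inconsistencies.

## Ancestry, kinship, consanguinity

PCA standardizes each common, well-called autosomal site (MAF > 0.01,
call rate > 0.99) by 2p̂ and √(2p̂(1−p̂)) with mean imputation, then takes
the leading components via the eigendecomposition of the sample-sample
Gram matrix — algebraically the same scores as the right-singular-vector
projection, at much lower cost for samples ≪ sites. Signs are fixed by
making each component's largest-magnitude score positive.

Kinship is the KING-robust between-family estimator computed from five
indicator-matrix products, with pairs lacking heterozygotes flagged
unevaluable. Degrees follow the standard thresholds (>0.354 duplicate;
then 0.177, 0.0884, 0.0442). The unrelated subset removes, iteratively,
the sample with most related partners, breaking ties by preferring to
keep cases, then carriers, then the lexicographically smaller ID — a
deterministic rule; the source analysis removed "one sample per pair"
without stating which. Note the estimator's expectation for a
cross-subpopulation unrelated pair is ≈ −Fst: divergence pushes scores
negative, so structure cannot create false relatives, and the
|φ̂| < 0.0442 robustness property is exercised at modest divergence
(Fst = 0.02) in the tests.

ROH: sliding windows of 50 consecutive autosomal SNVs (population
MAF > 0.05), a window qualifying with ≤1 heterozygote and ≤5 missing; a
SNV enters a run when ≥5% of windows covering it qualify; maximal runs of
≥100 SNVs and ≥1,000 kb are kept. These secondary parameters are the
named tool's defaults; the "1,000 kb" figure is read as the segment
length threshold, since a hard 1,000-kb cap on a 50-SNV window would
reject every window at exome-like map densities. The homozygosity rate
divides total run length by the SNV map extent (per-chromosome max minus
min position, summed) — exome maps have no calibrated genome length, and
this denominator is deterministic and testable. Consanguinity is
rate > 1%. With fewer mapped SNVs than one window the rate is undefined
(NaN, unflagged).

## Firth regression and inference

Fitting maximizes l*(β) = l(β) + ½ log det(XᵀWX) by Newton steps on the
modified score, with two safeguards: a cap of 5 on the largest coordinate
of a single step and step-halving whenever a move would decrease l*.
Convergence is declared when the largest applied step is < 1e-8 or the
modified score norm is < 1e-8 (the observed numerical floor of the
gradient is ~1e-9). Rank-deficient designs raise an error naming the
collinear columns. P-values use the penalized likelihood-ratio test
(matching the "likelihood ratio" wording of the method this follows; Wald
is deliberately not the default), profiling the full-model penalty with
the tested coefficient pinned. Confidence limits solve
2(l*max − l*profile) = χ²₀.₀₅(1) by bisection to 1e-6 on the coefficient,
stepping out in standard-error units to bracket; if bracketing fails the
Wald limit is substituted and flagged in the result. A constant carrier
indicator yields p = 1 with a warning rather than an error. Two
properties anchor the implementation: on any 2×2 design the estimate
equals the add-0.5 closed form, and Σhᵢ equals the parameter count at any
β (hat-matrix trace), both asserted in tests alongside a brute-force grid
maximizer and an unpenalized-ML shrinkage comparison.

Reported percentages round half away from zero at one decimal (two for
the control carrier rate), the convention that reproduces fixed-precision
cohort reporting.

## Population genotype frequency

Cumulative MAF is the sum Σq rather than 1 − Π(1 − q); at q ≤ 1e-4 the
difference is < 1e-8 and cumulative MAFs are conventionally reported as
sums. Autosomal recessive genotype frequency is Q², which under random
mating captures homozygotes plus compound heterozygotes; X-linked is
m·Q + (1−m)·Q² with male fraction m (default 0.5). Panel aggregates add
across genes — rare-event additivity, validated against a 10⁷-individual
forward simulation. Inbreeding-adjusted frequencies are out of scope.

## The synthetic cohort generator

What it emulates: K subpopulations with Balding–Nichols allele
frequencies (Beta around ancestral frequencies, variance F·p(1−p));
Hardy–Weinberg genotypes within subpopulation; consanguinity as
non-overlapping autozygous blocks placed to cover exactly F × genome
length (2,875 Mb autosome map), so the expected ROH fraction equals the
inbreeding coefficient; relatives by per-site haplotype copying (copy
probability γ gives kinship γ/4: γ=1 parent-offspring-like, γ=0.5
second-degree); trios whose children re-derive haplotypes from their
parents; planted recessive carriers by mechanism with dedicated
qualifying sites; and genotype-level QC noise (Poisson depth, Gaussian
GQ, binomial allele balance, random missingness).

What it deliberately does not model: linkage disequilibrium (sites are
independent, so kinship and ROH behave as if on pruned maps), realistic
site-frequency spectra or mutation models, age structure, batch or
platform artifacts, and genotype-calling error modes beyond the QC fields.
Non-planted rare panel variants are emitted heterozygous-only (and never
hemizygous in males): with per-variant frequencies ≤ 1e-2 the suppressed
genotypes have probability ≤ 1e-4 per sample-site, and the thinning makes
planted-carrier recovery exactly scoreable (precision = recall = 1 is a
generator guarantee, not a sampling accident). Passing tests on these
cohorts therefore establishes the pipeline's correctness on data
satisfying its model assumptions, not robustness to LD or annotation
error.

## The published-cohort fixture

The fixture encodes a pediatric pneumonia case-control cohort as published:
112 patients (78 male / 34 female; 72 critical, 15 severe, 25 moderate)
with 12 carriers — one STAT2 compound heterozygote (critical), three
homozygotes for one TYK2 frameshift (moderate/critical/critical), seven
TLR7 hemizygotes (three severe, three critical, one moderate), and one
IFNAR1 homozygous deletion (critical,
consumed from the deletion table); 1,224 controls (306 male / 918 female)
including three carriers of in-silico-qualifying but biochemically
neutral variants (TLR7 hemizygous, IFIH1 and IRF7 homozygous); 26
consanguineous patients and 75 consanguineous controls, realized as
planted autozygous blocks (F = 0.04, 40-Mb blocks) that the ROH scan must
rediscover; and four related patient pairs (the two TLR7 carrier pairs
plus two non-carrier critical pairs, γ = 0.5). Documented fixture
assumptions where the source is silent: the two unnamed related pairs are
non-carrier critical patients, and the removed member of one is
consanguineous — jointly this reproduces the published unrelated
denominators (108 overall, 70 critical) and the autosomal-recessive-by-
consanguinity split (4/25 vs 1/83). Three ancestry groups with Fst = 0.05
carry patient/control composition differences for the PCA and the
covariate-adjusted burden test.

The background map holds 24,000 common autosomal SNVs. The size is set
by estimator precision: KING's sampling noise scales as ~1/√V, and at
24k SNVs an unrelated pair sits ≳7 standard deviations below the 0.0442
threshold, so none of the ~900k pairs crosses it by chance while the
planted γ = 0.5 pairs (φ̂ ≈ 0.125) are detected with a wide margin; block
SNV counts (~330 per 40 Mb) comfortably clear the 100-SNV segment
threshold. Real exome maps are denser still (~167k SNVs), so this is a
scaled-down but directionally faithful choice.

## Problem sizes in the test suite

Unit tests run on toy matrices. The end-to-end suite uses: the full
fixture (1,336 samples × ~24k sites) once per session; 200 null cohorts
of 400 samples × 300 SNPs for calibration; 100 pairs per relationship
class at 8,000 SNPs for kinship classification; 40 samples per inbreeding
level at 8,000 SNPs for ROH flagging; and a 10⁷-individual forward
simulation for the frequency arithmetic. The whole suite completes in
about a minute on one CPU.

## Known limitations

No LD modeling (see above); no external-panel PCA projection (joint PCA
of cases + controls stands in for reference-anchored ancestry); no
statistical phasing — compound heterozygosity is confirmed only through
trios; deletion calls are consumed, not discovered; the covariate-adjusted
effect sizes on the fixture differ from any real-data values since the
fixture's PCs are synthetic; and the dominant-model screen over the wider
immunity gene set is intentionally out of scope.
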