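# Methods

This note records the statistical procedures `candigene` implements, the
choices that were genuinely open, and what the synthetic-data tests do
and do not establish.

## Data model and genotype coding

Genotypes are minor-allele dosages (0/1/2) with a distinct missing
sentinel.  The minor allele is decided on the pooled sample (cases +
controls); frequency ties are broken lexicographically (the smaller
allele letter becomes the major allele), so recoding is invariant to how
the input happens to order its allele columns.  Missing genotypes are
never imputed at I/O time: each statistic defines its own handling,
because per-SNP denominators legitimately differ when genotyping success
varies by assay (the bundled study's call rates range from 78% to 100%
per SNP).  PED phenotypes are strictly 1 = control / 2 = case; `-9`/`0`
are rejected rather than guessed, to make silent label flips impossible.

## Single-SNP statistics

**HWE.** 1-df χ² goodness of fit with expected counts n·(p², 2pq, q²),
allele frequencies estimated from the tested counts.  A monomorphic SNP
is reported as χ² = 0, p = 1.  A conditional exact test (summing
heterozygote-count probabilities given the allele counts) is available
for low-MAF SNPs where the χ² approximation is poor.

**Odds ratios.** Woolf's log-interval with z = 1.96.  This choice is
validated by exact reproduction of the bundled study's printed CIs
(e.g. 0.475–1.325 and 0.075–19.497 to the printed precision).  A zero
cell triggers the Haldane–Anscombe +0.5 correction with a flag; a zero
margin yields NA rather than an arbitrary number.

**Test selection.** Pearson χ² (no continuity correction — again
validated against the printed p-values) unless any expected cell is
below 5, then the two-sided Fisher exact test (sum of all fixed-margin
tables with probability ≤ the observed one).  The threshold of 5 is the
textbook expected-count rule and is configurable; published reports
describe their small-sample switch rules too loosely to pin down.  Note
that mid-range p-values from the two tests legitimately differ by up to
the probability mass of the modal table even at large counts; the two
agree tightly in the decision-relevant tail.

**Orientation.** All odds ratios put the odds of the first-listed
exposure (major allele, first genotype class, or carrier status) in
cases over controls.  This single convention reproduces every printed
value the package re-derives; no per-row flipping is needed.

**Multiple testing.** None by default, matching common candidate-gene
practice; Bonferroni and Benjamini–Hochberg helpers exist for callers
who want them.

**Power.** Two-sided two-proportion normal approximation with the
pooled-variance null SE (matching the χ² test actually used) and
unpooled alternative SE; it returns α at δ = 0 and tracks Monte-Carlo
rejection rates within 0.02 at study-like sizes.

## Haplotypes and LD

Blocks of 2–4 SNPs are estimated by plain EM over latent phase:
initialisation at the linkage-equilibrium point (allele-frequency
products), E-step weights ∝ f(h₁)f(h₂) (×2 for heterozygous pairs)
summed over all completions of up to two missing genotypes per block,
M-step = expected haplotype counts / 2N, convergence when the largest
frequency change falls below 1e-10 (max 1000 iterations; non-convergence
returns results with a warning).  At ≤16 haplotypes the likelihood
surface is small; partition–ligation staging and restarts are
unnecessary at this scale and deliberately out of scope.  The
observed-data log-likelihood is recorded per iteration and its
monotonicity asserted in tests; EM is additionally checked against an
exhaustive 0.01-step grid-search maximum-likelihood oracle on small
panels.

Haplotype association uses group-specific EM frequencies converted to
expected chromosome counts (f·2n) in a per-haplotype 2×2 χ² against all
other haplotypes; haplotypes below 0.001 pooled frequency are not
reported.  LD statistics come from the same two-locus EM: D = p_AB −
p_A·p_B, D′ = |D|/D_max (D_max = min(p_A·q_B, q_A·p_B) for D > 0, else
min(p_A·p_B, q_A·q_B)), r² = D²/(p_A q_A p_B q_B).  LD is computed on
the pooled sample by default with a group filter, and monomorphic pairs
are flagged undefined rather than dropped.

## MDR

The cell table of a k-locus combination counts cases and controls per
multi-locus genotype over the individuals complete at those loci; the
risk threshold is the case:control ratio of exactly those individuals
(not 1.0 — the canonical choice for unbalanced designs).  Cells at or
above threshold are high-risk (ties high, deterministic); cells unseen
in training are low-risk by default, with an exclude-from-scoring policy
behind a flag since MDR software variants differ here.

Evaluation is stratified 10-fold cross-validation: labels fitted on 9/10
of the data, scored on the held-out tenth by balanced accuracy, with one
fold assignment shared by every combination so comparisons are paired.
CVC counts the folds in which a combination has the best training BA of
its size.  Selection is two-stage, by maximum cross-validation
consistency and maximum testing balanced accuracy: within each size the
candidate maximises CVC (ties by testing BA); across sizes the final
model again maximises CVC, ties by testing BA, then by fewer loci.
Preferring the consistent model over one that edges out testing BA in a
single fold split is the operative rule of the tools this package
mirrors, and on synthetic pure-epistasis cohorts it is what keeps larger
supersets of the true pair from winning on ~0.005 BA noise.

The best model's p-value is a **search-wide** label permutation: each
permutation re-runs the whole cross-validated search (same combinations,
same folds) and the statistic is the maximum mean testing BA over all
combinations.  Permuting only the selected combination would ignore the
selection step and be anti-conservative; the search-wide version is
calibrated (null cohorts give p > 0.05 in ≥ 95% of replicates) and
slightly conservative for models that are not the BA maximiser.  A
single-combination permutation (`permutation_pvalue`) is also provided
for assessing a pre-specified model.  Default 1000 permutations from the
CLI; resolving p ≈ 1e-4 claims requires ≥ 9999.

Whole-data classification metrics use the standard confusion-matrix
definitions (F1 as the harmonic mean of precision and sensitivity, MCC
bounded in [−1, 1]); PR-AUC ranks individuals by their cell's training
case proportion and is computed as step-interpolated average precision
(verified identical to scikit-learn's).  Because the scores are fitted
in-sample on few discrete cells, null PR-AUC sits above prevalence;
these metrics describe fit, not out-of-sample performance.

Entropy analysis uses plug-in entropies (log base 2, no bias
correction) over complete-data individuals, reported as a percentage of
the class entropy H(C): main effect I(A;C)/H(C), pairwise interaction
[I(A,B;C) − I(A;C) − I(B;C)]/H(C), positive = synergy, negative =
redundancy.  The dendrogram is average-linkage clustering on
1 − |IG|/max|IG|, serialised as Newick.  Plug-in estimates carry an
upward bias of order (cells−1)/(2N ln 2); tests budget ~1.5 percentage
points for it at n = 400.

## Survival

Kaplan–Meier with deaths processed before censorings at tied times and
Greenwood pointwise standard errors; the unweighted Mantel–Cox log-rank
statistic (hypergeometric variance, quadratic form over g−1 groups).
Both are hand-implemented and cross-checked against lifelines to
machine precision in tests.  `survival_by_genotype` uses cases only,
applies administrative censoring at 60 months, excludes empty genotype
groups with a note, and reports curves without a test when fewer than
two groups remain (as happens at monomorphic SNPs).

## Synthetic cohorts

The generator emulates exactly the structure the analyses assume:
haplotype blocks drawn as two independent haplotypes per individual from
a block pool (hence HWE marginals and pool-implied within-block LD),
unlinked blocks, penetrance-table disease models with retrospective
case/control rejection sampling (drawn with replacement from a simulated
population panel), per-genotype i.i.d. missingness, and exponential
survival with administrative censoring.  Defaults mirror the bundled
study's design: 120 cases / 95 controls, six SNPs in two 3-SNP blocks
with MAFs near the published panel, 8% missingness (success rate just
over 90%), 60-month follow-up.  All randomness flows from one integer
seed through a single generator; identical config + seed reproduces
cohorts and report bundles byte-for-byte.

The XOR penetrance model assigns baseline + effect to the four cells
where the two dosage parities differ.  At MAF 0.5 the HWE dosage
distribution gives P(odd dosage) = 1/2, so each locus's marginal
penetrance is baseline + effect/2 for every genotype — pure epistasis
with no marginal effect, the hardest case for single-locus tests and the
cleanest positive control for MDR.

What the generator does **not** model: population structure and
covariates, genotyping error (as opposed to missingness), linked blocks
or recombination, informative censoring, and the joint genotype
distribution of the bundled study (its printed tables determine only
per-SNP marginals, so panels rebuilt from them are valid for single-SNP
statistics only).  Passing tests therefore demonstrate correctness of
the estimators under the stated model, not robustness to these
real-data complications.

## Problem sizes used in validation

Chosen as the smallest sizes at which the checked properties are
statistically sharp: haplotype-frequency recovery at n = 1000 over 50
seeds (mean absolute error < 0.02); LD against closed form at n = 2000
individuals with delta-method sampling bands; MDR power over 20
replicates of a 200/200 cohort (recovery ≥ 80%, median CVC ≥ 8); MDR
calibration over 100 null cohorts with 99-permutation tests; type-I
error of the allelic and log-rank tests over 2000 null replicates each
(accepted band 0.035–0.065 at α = 0.05).

## Known limitations

- EM returns population haplotype frequencies, not per-individual
  phases, and blocks are capped at 4 SNPs.
- The Fisher/χ² switch is per-contrast, not familywise; with several
  contrasts per SNP the method column can mix within one SNP.
- The study-table fixture reconstructs two garbled genotype rows of the
  bundled study from its allele-count table (documented in
  `studydata.py`); the reconstruction reproduces every printed allele
  count exactly but is still an inference.
- Published MDR accuracies, haplotype frequencies and LD values of the
  bundled study require individual-level data that were never deposited;
  the package validates those code paths on synthetic cohorts instead.
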