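# Methods

This note documents the statistical models implemented in `gxeartp`, the
defaults and why they were chosen, what the synthetic-cohort generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## The interaction model

For each SNP, outcome and exposure, the package fits by ordinary least squares

    y_i = β0 + γ'·c_i + β_pm10·PM10_i + β_py·PY_i + β_G·G_i + β_GE·G_i·E_i + ε_i

where `y` is the 11-year decline of a spirometric index (follow-up minus
baseline, so losses are negative; FEV₁ in ml, FEV₁/FVC in percentage points,
FEF₂₅₋₇₅ in ml/s), `G` the allele dosage (expected effect-allele count in
[0, 2], additive coding), `E` the exposure named in the `ModelSpec`
(interval PM10 or interval packyears), and `c` the covariates: sex, age and
height at follow-up, packyears smoked up to baseline, ancestry principal
components, and study area (indicator columns, first sorted label as
reference). Both interval exposures always enter as main effects; exactly one
interaction term is fitted at a time. No follow-up-time adjustment is needed
because the interval is fixed at 11 years by construction.

**Standard errors.** The default covariance is the classic Huber–White HC0
sandwich with a standard-normal Wald reference, the behaviour of the GWAS
regression tools this pipeline is styled after; HC1 and the t reference are
one flag away (`hc="HC1"`, `use_t=True`). At n = 650 with ~19 design columns,
HC0 with the normal reference is very slightly anti-conservative (null
rejection ≈ 5.5% at nominal 5% in our calibration runs) — too small to matter
for effect reporting, and irrelevant at the gene level, where the permutation
adjustment calibrates the test by construction.

**Scaling and coding.** Exposure contrasts are reported per interquartile
range (83.4 µg/m³·years for PM10, 9.8 packyears), applied after fitting:
β_E, β_GE and their SEs are multiplied by the IQR, p-values untouched.
Median-centering of the exposure (for reporting genotype main effects at the
median exposure) changes β_G but provably not β_GE. Dosages hard-call to
genotypes at 0.5 and 1.5 with inclusive lower bounds (0.5 is heterozygous).

**Stratified reparametrization.** For per-genotype exposure effects in small
strata, one model carries a carrier indicator plus two genotype-specific
exposure columns (E·1[wild-type], E·1[carrier]) instead of an interaction
term. This spans exactly the same column space as the binary-coded
interaction model (the tests assert identical fitted values), but yields each
stratum's exposure effect and robust CI directly; the 1-df Wald test of
coefficient equality is the interaction test.

**Fast scan.** Permutation testing refits thousands of regressions, so a
vectorized Frisch–Waugh–Lovell route (`ScanDesign.scan`) residualizes the SNP
and interaction columns against a pre-orthonormalized fixed design and solves
the remaining 2×2 problem for whole dosage matrices — and whole batches of
permuted matrices — at once. The per-coefficient HC0 variance is computed
from the residualized regressor (u'diag(e²)u / (u'u)², with e the full-model
residuals), which is algebraically identical to the full sandwich; the test
suite enforces agreement with statsmodels to 1e-9. Degenerate columns
(monomorphic after permutation) report p = 1 so permutation p-vectors stay
well defined; in observed-data scans such SNPs are flagged as errors instead.

## ARTP aggregation

Gene-level evidence combines the gene's SNP interaction p-values:

1. sort the L p-values ascending; at each truncation point
   K ∈ {1, 2, 5, 10, 25, ⌈L/2⌉, L} ∩ [1, L] compute the log-product of the K
   smallest (log space avoids underflow at large K);
2. permute the rows of the gene's dosage matrix B times (default 10 000;
   all SNP columns move together, so within-gene LD is intact while
   genotype–phenotype association is broken; covariates, exposures and
   outcome stay fixed), re-running the scan each time;
3. adjust: each row's log-product is ranked against all B+1 log-products at
   that truncation point (self-inclusive, ties counted as ≤), giving
   s_K = #{rows ≤ own}/(B+1) — for the observed row this is the add-one
   estimator (1 + #{permutations ≤ observed})/(B+1), so no p-value can be 0;
4. re-adjust: the minimum s_K over truncation points is the unit statistic,
   and its own permutation distribution gives the gene p-value
   p = (1 + #{MinP_b ≤ MinP_obs})/(B+1) ∈ [1/(B+1), 1].

Pathway p-values apply steps 1–4 once more to the genes' observed and
permuted p-values (truncation points from the number of genes). Genes in
several pathways contribute to each. By default one individual permutation is
shared by all genes at a given replicate (`shared_permutations=True`), so
inter-gene correlation survives to the pathway level; per-gene independent
streams are available by flag. Every permutation is a pure function of
(seed, key, replicate), so full runs are bit-reproducible.

The truncation-point rule is pluggable: the candidate set above is this
package's pinned default, chosen to span single-SNP through whole-gene
signals; ARTP's validity does not depend on the particular candidate set,
only on using the same rule for observed and permuted data.

## QC

Samples with genotyping success below 97% are removed first; then SNPs
failing any of — exact Hardy–Weinberg test p < 10⁻⁴ (conditional enumeration
on 0.5/1.5 hard calls of non-missing dosages; the exact test avoids
small-count artifacts of the χ² approximation), call rate < 97%, empirical
MAF < 5%, imputation Rsq < 0.5 (imputed SNPs only) — are excluded, each with
an explicit reason in the exclusion report. The filter is idempotent. Gene
regions are transcription spans ±20 kb, 1-based, inclusive on both ends (a
SNP exactly at start − 20 000 is in); 0-based coordinates must be shifted at
import. The shipped gene-region table is *synthetic* (a deterministic layout
of the candidate genes, for simulation and demos); real coordinate tables are
loadable by path. The pathway fixture ships the 13 printed oxidative-stress
pathways plus the explicit not-mapped set — 148 distinct genes; an
additional user-supplied pathway table (e.g. an apoptosis set) can be passed
by path rather than inventing memberships.

## Power

The 1-df interaction Wald test has asymptotic noncentrality λ = n·f/(1−f)
when the interaction term explains the fraction f of total outcome variance;
power = P(χ²₁(λ) > χ²₁;₁₋α). At f = 0 this reduces to α exactly. The
Monte-Carlo cross-check plants exactly that variance share on the partialled
interaction contrast (G×E residualized against intercept and main effects),
fits the robust regression, and counts rejections; analytic and simulated
power agree within Monte-Carlo error in the tests. At α = 0.05 the analytic
power is ≥ 99% for (n = 650, f = 0.05) and for (n = 3320, f = 0.01 or 0.05),
and ≈ 73% for (n = 650, f = 0.01) — the last figure is sensitive to how
"variance explained" is parameterized and is not treated as a hard target.

## The synthetic cohort

The generator reproduces the *statistical structure* the analysis relies on,
not any real population:

- **Genotypes.** A latent standard normal follows an AR(1) chain along each
  chromosome's SNPs (adjacent-SNP correlation `ld_rho`, chain restarting at
  chromosome changes) and is cut at the Hardy–Weinberg quantiles of each MAF.
  This gives exact HWE marginals and tunable pairwise LD that can be checked
  against numerical integration of the thresholded bivariate normal (the
  tests do exactly that). MAF spectrum defaults to [0.05, 0.5].
- **Imputation noise.** Dosage = 2·maf + Rsq·(G − 2·maf) + noise with noise
  variance Rsq·(1−Rsq)·Var(G), clipped to [0, 2]: corr²(dosage, G) = Rsq
  before clipping, emulating the shrinkage of imputed dosages toward the
  allele-frequency expectation. Rsq = 1 yields exact integers.
- **Exposures.** Interval PM10 is log-normal with population median
  239.0 µg/m³·years and IQR 83.4 (σ solved in closed form from
  IQR/median = 2·sinh(z₀.₇₅σ)). Smoking mix defaults to
  (never, former, current) = (0.457, 0.308, 0.235); interval packyears are 0
  for never smokers and 75% of former smokers, gamma for the rest, with the
  current-smoker gamma scaled so the current-smoker IQR is 9.8 packyears
  (current-smoker medians then land near 9–10 PY over the 11-year interval;
  a *whole-sample* IQR of 9.8 would force implausible consumption given the
  majority of zeros).
- **Covariates.** Sex and age weakly depend on smoking status (fewer women
  and slightly younger individuals among current smokers); height is
  sex-specific; 4 ancestry PCs are standard normal (a conventional count —
  the number is configurable); 8 study areas, uniform.
- **Outcomes.** Linear model with configurable intercept (negative: the
  cohort declines on average), covariate effects, exposure main effect, SNP
  main effect and interaction, plus Gaussian noise (defaults: −350 ± 250 ml
  FEV₁, −4 ± 4 % FEV₁/FVC, −800 ± 550 ml/s FEF₂₅₋₇₅ over 11 years).

Not emulated: real exposure surfaces or spatial correlation, measurement
error in spirometry, non-Gaussian outcome tails, population substructure
beyond independent PCs, genotyping batch effects, missing-data mechanisms
beyond injected missingness, and haplotype-panel LD beyond first-order
autocorrelation. Passing tests therefore demonstrate that the *procedures*
are calibrated and recover planted effects under the assumed model — not
that any particular real-data finding would replicate.

All randomness flows from one integer seed; operations derive child
generators deterministically (`SeedSequence([seed, key, ...])`), so every
pipeline stage and the permutation machinery are reproducible bit for bit.

## Calibration runs and problem sizes

The shipped calibration suite uses desk-scale sizes chosen to keep the full
suite in a few minutes while leaving Monte-Carlo error well below the margins
being tested: null-uniformity over 1000 independent SNPs in one n = 650
cohort (KS test); CI coverage for a planted −3.8 %/allele/IQR interaction
over 200 replicates at n = 650 (binomial SE ≈ 1.5% around 95%); and
gene-level ARTP type-I error over 500 null cohorts × B = 200 permutations
(95% binomial band 3.1–6.9% around 5%). Production analyses should use the
default B = 10 000.

## Known limitations

- Analytic (non-permutation) ARTP approximations are not provided; runtime
  scales linearly in B × SNPs.
- The HC0/normal default is mildly anti-conservative in small samples (see
  above); switch to HC1 + t for small-n SNP-level reporting if exact nominal
  coverage matters more than tool compatibility.
- The permutation store is held in memory; genes with very many SNPs at
  B = 10 000 may need the chunked scan's chunk size lowered.
- `qc_filter` computes HWE on hard-called dosages for all SNPs, genotyped or
  imputed; pipelines that only HWE-test genotyped SNPs can pre-partition the
  panel.
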