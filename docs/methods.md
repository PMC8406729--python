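# Methods

## Model

The analysis targets inbreeding depression localized to specific homozygous
haplotypes. For one trait `y` (one record per animal):

    y = Xb + Za + Σ_{j=1..4} W_j c_j + e

- `a` — additive genetic effects with Var(a) = A σ²ₐ, `A` the pedigree
  numerator relationship matrix. Inbreeding coefficients come from the
  Meuwissen–Luo recursion (diagonal of A computed without forming A); A⁻¹ is
  assembled directly from Henderson's rules with the inbreeding adjustment.
  Animals with one unknown parent are treated as unrelated to the unknown
  side (Mendelian-sampling variance ¾ − F_known/4).
- `c_j` — four i.i.d. random factors with Var(c_j) = I σ²ⱼ, standing in for
  management groupings such as herd-year, herd within region-year-season,
  service sire and AI technician in the dairy setting. They are generic
  user-declared categorical columns; concrete national-evaluation factor
  definitions are out of scope.
- `b` — user-declared categorical fixed factors, plus per tested window the
  ROH-class indicators (non-ROH class is the reference) and centered allele
  counts of every SNP inside the window. The SNP covariates correct the
  class contrast for additive SNP effects so that it measures the
  non-additive (dominance/recessive) part of the class; the superset reading
  (all within-window SNPs, not only those segregating in the class string)
  is used.
- Variance components are a required input and are held fixed across
  windows (null-hypothesis reasoning: under no ROH effect the null-model
  components apply everywhere). EM-REML is provided to produce them from
  the null model when external estimates are unavailable.

Contrasts are one-tailed in the trait's declared unfavorable direction
(lower for MY/FY/PY/NRR, higher for NS/FSTC/AFS), with
df = N − rank(fixed); at realistic N this is indistinguishable from a normal
reference.

### Solving strategy

The mixed-model equations are solved by absorbing the random-effect block.
With Z̃ the stacked random design and M = Z̃'Z̃ + D (D holding A⁻¹·λₐ and
identity blocks times their variance ratios), the absorbed fixed-effect
system is S = X'X − (Z̃'X)' M⁻¹ (Z̃'X). M is sparse-LU factorized **once per
trait**; all genotype-column solves are precomputed as dense blocks, so a
window fit reduces to slicing precomputed cross-products plus a handful of
solves for the class indicator columns and a small dense Cholesky. S⁻¹·σ²ₑ
gives the sampling covariance of the fixed solutions, from which class
standard errors are read. This is what makes 1000 calibration fits plus all
candidate fits run in seconds per trait.

Collinear columns are detected by in-order symmetric elimination at pivot
tolerance 1e−8 (relative to the original diagonal). SNP covariates (and, in
degenerate designs, base factor columns) are dropped; class indicators are
never dropped — if a class indicator pivots to zero the window is reported
as unidentifiable. Dropping covariates rather than class indicators is
deliberate: the class contrast is the estimand.

### EM-REML

Plain EM-REML converges linearly and crawls near a zero-variance boundary,
so the implementation applies guarded Aitken extrapolation every fourth
iteration, only to component sequences that are monotone and contracting,
and never to σ²ₑ (a spurious jump to zero residual variance would be an
absorbing state). Convergence is declared when the largest component change
relative to the phenotypic variance drops below `tol` (default 1e−6) on a
plain (non-extrapolated) step; components are clamped at 1e−12 and the
clamping logged. The procedure is deterministic.

## Scan

- **Runs.** Per animal and chromosome, maximal homozygous runs of at least
  `min_run` (default 15) SNPs are stored; a window is fully homozygous for
  an animal iff it lies inside one run. A missing call breaks a run — ROH
  forbid heterozygotes, and an uncalled SNP cannot vouch for homozygosity;
  this is the conservative reading for data that are near-perfectly imputed
  upstream. Because retained windows have ≥ 50 SNPs > 15, `min_run` is inert
  at default window sizes; it remains a configuration knob.
- **Classes.** Carriers are grouped by the exact homozygote allele string;
  two carrier groups with different strings are distinct classes even if
  their effects are similar. Class frequency must exceed
  `min_class_frequency` (default 0.75%) of all animals, strictly.
- **Screening.** Raw (pre-model) carrier phenotype means are compared
  strictly against the empirical cut-off; this mirrors the screen-then-test
  structure of the procedure, with model adjustment reserved for the
  fitting stage. Classes whose carriers all lack the phenotype are skipped
  with a log message.
- **Aggregation** is applied within one window size: maximal chains of
  consecutive start positions whose class partitions (carrier sets) are
  identical merge into one record spanning the union, with the first
  window's classing as representative; "adjacent start, identical
  partition" is the operational reading of windows equivalent up to their
  first/last SNP. Cross-size redundancy is handled solely by the nested
  discard: a candidate is removed when another candidate's interval
  contains it with identical carrier sets (ties on identical intervals keep
  the larger scan-window record).
- Model fits of aggregated records use the aggregated span for the SNP
  covariates; screened-out classes fold into the non-ROH reference.

## Empirical cut-off

`threshold_samples` (default 1000) windows of the initial size are sampled
uniformly over (chromosome, start); every class is fitted with the mixed
model and the cut-off is the mean raw carrier mean of classes whose
one-tailed p falls in `threshold_sig_range` (default [0.05, 0.10]). If
fewer than 20 classes land in the band it widens symmetrically in 0.01
steps (logged) until 20 are collected or the band spans [0, 1], in which
case all sampled class means are used; the minimum of 20 and the widening
rule are package choices for small genomes where the band can be sparsely
populated. Calibration is per trait, at the initial window size only, and
deterministic given the seed.

## FDR and reporting

The family is **all tested classes of one trait genome-wise**; the
Benjamini–Hochberg step-up runs at `fdr_q` (default 1%) per trait (the
implementation delegates to `statsmodels.multipletests(method="fdr_bh")`).
Pleiotropy groups collect significant records of ≥ 2 traits whose intervals
overlap on a chromosome with identical carrier sets, re-verified from the
genotypes. Gene annotation intersects record bp spans (taken half-open as
[first-SNP bp − 1, last-SNP bp)) with BED (0-based half-open) or GFF3
(1-based inclusive, converted) gene intervals; abutting intervals do not
count as overlap. Reported precision follows the conventional style:
effects, −log₁₀ p and Mb to 2 decimals.

## Synthetic data

The generator emulates the structure of an intensely selected dairy
population at desk scale; defaults: 200 founders, 8 non-discrete
generations with 5% of males used as sires (≈ 1,800–2,000 animals), 5
chromosomes × 600 SNPs at 50 kb spacing (≈ 20× smaller than a 43k-SNP,
46k-cow national dataset), founder alternate-allele frequencies uniform in
[0.1, 0.5], 1 cM/Mb Haldane recombination (Poisson crossovers, no
interference), gene dropping so every ROH arises from identity by descent.
Trait scales follow first-lactation Holstein descriptives (e.g. milk yield
mean 9,074 kg, SD 1,732.2 kg); heritability defaults to 0.3 with 5% of
variance per i.i.d. factor. Binary (non-return rate) and count (services,
capped 1–10) traits are thresholded/discretized from the same latent
Gaussian model, matching the practice of analysing them with the linear
mixed model.

Planted unfavorable classes default to *existing* IBD classes: the
generator scans the requested chromosome for a homozygote string whose
frequency is within ±50% of the target (3% by default) and attaches the
effect (−1 phenotypic SD by default) to those carriers, editing nothing.
A force mode instead overwrites a window with a donor-derived homozygote
string for randomly chosen animals — it guarantees the carrier count but
breaks Mendelian transmission inside the interval and makes the class
indicator nearly collinear with the SNP additive covariates (an alien
string puts carriers at an extreme of a linear dosage score), which is why
the realistic non-force mode is the default for validation studies.

**Truth-labelling of discoveries.** Planted effects attach to animals, and
a planted class's shared haplotype extends beyond the requested window, so
the scan legitimately flags flanking windows whose carriers are the
affected animals. A significant record therefore counts as a true
discovery when its interval overlaps a planted interval **or** its carrier
set shares at least one animal with a planted carrier set (any such class
has a strictly unfavorable true contrast, so its one-tailed null is
false); records of genuinely null classes count as false. The acceptance
study measures the mean of V/max(R,1) over replicates under this rule.

What passing these simulations does *not* show: the generator has no
selection on phenotype, no genotyping ascertainment, no missing genotypes
by default, linkage-equilibrium founders, generic balanced-ish factor
structures, and phenotypes generated from the fitted model family itself —
real data violate all of these, so simulation results demonstrate internal
consistency and frequentist calibration of the machinery, not field
performance.

## Problem sizes and runtime choices

Validation studies run at the desk scale above: one trait, ~2,000 animals,
3,000 SNPs, 1000 calibration windows, three planted classes; a replicate
takes ~20 s on one CPU. The FDR/power study uses 20 replicates in the test
suite and 30 in `scripts/acceptance.py`; EM-REML checks run on pedigrees of
a few hundred animals, where the dense implementation is comfortable.
Null-calibration KS tests deduplicate classes by carrier set, since the
same class surfaces in many overlapping windows and duplicated p values
would break the independence assumed by the KS reference.

## Conventions and edge cases

- Windows are half-open 0-based SNP-index intervals [start, end); genomic
  spans are reported as the 1-based bp of first/last SNP and Mb to 2
  decimals.
- PLINK text recoding: the alternate allele is the lexicographically later
  of the observed alleles; "0 0" is missing; a SNP with a single observed
  allele codes as homozygous reference. ROH classing is invariant to this
  polarity choice. Triallelic SNPs are a format error naming the SNP.
- QC inequalities are strict (call rate > 0.95, MAF > 0.01, |het_obs −
  het_exp| < 0.15, taken as an absolute difference); removal reasons follow
  the first failing filter in the order call rate, MAF, heterozygosity
  deviation, autosome. Monomorphic SNPs fail MAF naturally.
- Pedigree parents that never appear as animals are added as founders (the
  base population is assumed unrelated); cycles raise an error naming one
  cycle.
- Classes with fewer than two phenotyped carriers are skipped and excluded
  from the FDR family.

## Known limitations

- The dense genotype-column precompute is O(M²) memory in the number of
  SNPs; at array scale (≥ 40k SNPs) the per-window solve path without the
  full Gram precompute (already used when no genotypes are attached) would
  need to be extended with banded or on-demand caching.
- EM-REML is dense and quadratic in pedigree size; national-scale variance
  estimation should come from specialized software, which matches the
  intended use (components supplied via configuration).
- No gap-tolerant ROH definition (one permitted heterozygote), no
  genetic-map-length run definitions, no F_ROH summary statistic, no binary
  PLINK/VCF input, no X chromosome.
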