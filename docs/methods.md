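# Methods

## Genotype coding and quality control

Genotypes of inbred/DH material are coded −1/+1 with missing allowed before
filtering.  This coding makes the per-locus genotypic variance of a
segregating DH family exactly 1, so the cross-variance formula carries no
coding constants.  Heterozygous calls are rejected at TSV import and mapped
to missing at VCF import (0/0 → −1, 1/1 → +1, anything else → NA);
multi-allelic VCF records are dropped and counted.

QC removes markers first (missing fraction > 10%, then Nei gene diversity
2p̂(1−p̂) < 10% on non-missing calls), then samples (missing fraction > 15%
computed on the retained markers).  The order matters on edge cases and is
fixed; a consequence is that the filter is idempotent except when removing
a sample pushes a retained marker's missing fraction across the threshold.
Gene diversity is the standard Nei definition for biallelic loci; the
threshold is configurable because genotyping platforms differ in how they
report it.  Remaining missing calls are mean-imputed per marker before
RR-BLUP (ridge regression needs complete data; mean imputation is neutral
for the intercept and shrinks toward no information at the imputed cells).

## Linkage and recombination

Map positions are cM; conversion to recombination fractions uses the
Haldane function r(d) = (1 − e^(−2d/100))/2 by default, with Kosambi
r(d) = tanh(2d/100)/2 available.  Haldane is the default because it is the
exact inverse of the no-interference (Markov/Poisson) crossover process the
meiosis simulator implements, making the analytical–simulation equivalence
exact in expectation rather than approximate.  Under Kosambi the simulator
is *not* a matched oracle (it has no interference); this is a documented
caveat, not a bug.  Markers on different chromosomes get r = ½ exactly.
Pairwise r matrices are materialised lazily per chromosome block so
genome-sized marker sets never allocate a p×p array.  Markers present in
genotypes but absent from the map are an error by default (`drop_unmapped`
opts out) — silently dropping markers would change variance predictions
invisibly.

## Marker effects (RR-BLUP)

Model: y = 1μ + Zβ + e, β ~ N(0, σ²_β I), e ~ N(0, σ²_e I), intercept the
sole fixed effect.  With λ = σ²_e/σ²_β given, estimates are the dual-form
ridge solution β̂ = Z′(ZZ′ + λI)⁻¹(y − 1μ̂) with μ̂ by generalized least
squares; the primal (p×p) and dual (n×n) forms agree to machine precision
(tested).  When λ is omitted it is estimated by REML: the intercept is
projected out, the projected kernel ZZ′ is eigendecomposed once (O(n³)),
and the profiled restricted likelihood is maximised over log λ by bounded
scalar search on [−10, 10] (natural log, tolerance 1e−8).  A constant
phenotype makes the REML profile degenerate and raises an explicit error
suggesting a fixed λ.  Training pools all post-QC DH lines and uses their
adjusted entry means as phenotypes; no cross-validation split is built into
fitting (validation lives in the trial comparison).

## Cross prediction

For parents p₁, p₂ and δ = (p₁ − p₂)/2:

* μ̂_g = μ + β′(p₁ + p₂)/2 — the mid-parent genomic value; equals the mean
  of the parental GEBVs.
* σ̂²_g = Σᵢⱼ βᵢβⱼδᵢδⱼ c(r_ij) with c(r) = 1 − 2r (DH from F1 gametes) or
  (1 − 2r)/(1 + 2r) (RIL by repeated selfing).  These are the standard
  disequilibrium coefficients for one meiosis and for the selfing limit;
  the Monte-Carlo meiosis oracle — not a citation — is the correctness
  authority here, and the oracle-equivalence test (analytical vs empirical
  moments of 10⁵ simulated DH lines, 3 Monte-Carlo SEs) is the package's
  central test.

The double sum is restricted to segregating loci grouped by chromosome
(cross-chromosome terms vanish since c(½) = 0), giving O(Σ_c s_c²) work
instead of O(p²).  The implied covariance matrix is positive semidefinite
for any valid map, so a negative result can only be floating-point dust;
values in (−10⁻¹², 0) are clamped to 0 with a warning and anything more
negative raises.

Usefulness U = μ̂_g + i·h·σ̂_g with defaults i = h = 1, so the shipped
ranking criterion is plainly μ̂_g + σ̂_g.  Ranking ties break
lexicographically by cross id for determinism.

## Trial analysis

Model: value ~ entry (fixed) + location (random) + location:block (random)
+ error, REML.  Errors are homoscedastic by default; a flag extends the
parameter vector to one error variance per location (the default is the
more robust choice at small synthetic sizes).  The implementation exploits
the structure — entry indicators as fixed effects, nested random
indicators — so every REML evaluation reduces to grouped sums plus two
q×q factorizations (q = locations + blocks), via the Woodbury identity for
V⁻¹ and the matrix-determinant lemma for X′V⁻¹X; no n×n or m×m matrix is
formed.  Optimization is L-BFGS-B on log-variances with a derivative-free
Powell polish if the line search stalls.  Responses are centred before
fitting, making the fit exactly translation-equivariant.  The homoscedastic
fit is cross-checked against statsmodels MixedLM in the test suite.

Adjusted entry means are the GLS fixed-effect solutions; standard errors
come from the diagonal of (X′V⁻¹X)⁻¹.  The masking variance is
s²_m = (mean SE)² — the square of the *average* standard error; the
mean-of-squared-SEs variant is also exposed.  Degenerate saturated designs
(every entry observed exactly once, zero residual df) leave the restricted
likelihood flat in all components; by convention the components collapse to
the numerical floor, so adjusted means equal plot values and s²_m ≈ 0.
Entries with no plots raise an error naming them.

## Validation statistics

* Predicted phenotypic distribution: N(μ̂_g, σ̂²_g + s²_m).
* Anderson–Darling: the null is fully specified before the family's data
  are seen (parameters come from markers and the trial model), so the
  case-0 distribution of A² applies.  A² uses log-space normal tails
  (no under/overflow; a warning marks samples far in the tail) and
  p-values use the Marsaglia & Marsaglia (2004) evaluation of the case-0
  distribution (asymptotic series plus finite-n correction; the correction
  is skipped within 10⁻⁶ of CDF 1 where its own fit error dominates, and
  the CDF is 1 beyond A² = 32 where the residual tail is < 10⁻⁸).
  Calibration at n = 15 is verified by simulation (empirical size 0.03–0.07
  at α = 0.05).
* Variance CIs: equal-tailed χ², lower = (n−1)s²/χ²_{1−α/2,n−1}, upper =
  (n−1)s²/χ²_{α/2,n−1}; sample variances use the n−1 divisor throughout
  (required for the χ²_{n−1} degrees of freedom to cohere).
* Correlations are Pearson.  Families of size 1 are excluded from variance
  statistics and AD testing but retained for the mean correlation and the
  best-line ranking.
* Ranking overlap counts |top-k ∩ top-k| for k = ⌊m/2⌋ between the
  usefulness ranking and the ranking by best observed line.

## Synthetic generator

The generator emulates a small applied program: 9 inbred parents (4 donors
× 5 elites), 14 biparental DH families with sizes 4–37 (200 lines), 7
chromosomes of 140 cM, an augmented 5-location trial with 5 blocks per
location, parents as checks in every block, unreplicated entries placed
once per location in a uniformly drawn block.  Parent genotypes are
independent draws with per-marker +1 frequencies ~ Uniform(0.1, 0.9).
Meiosis is the adjacent-interval Markov model (start haplotype fair coin
per chromosome; switch between adjacent markers with probability
haldane_r(Δd), independently per interval); for inbred parents the F1 is
never materialised and DH gametes are doubled directly.

Defaults, chosen once to match the emulated regime and frozen:

| parameter | default | why |
|---|---|---|
| markers/chromosome | 200 (1,400 total) | full pipelines in seconds; genome-density runs just scale this up |
| intercept | 90 | typical yield level, dt/ha scale |
| effect SD σ_β | 0.1206 | ≈ √(8/550): ~550 expected segregating loci per cross put σ̂²_g in the ~1–15 band |
| (σ²_L, σ²_LB, σ²_e) | (40, 20, 150) | one-replicate plots are noisy; gives s²_m ≈ 30, so masking dominates σ̂²_g as in the emulated program |

What the generator does *not* emulate: linkage disequilibrium among parents
(their genotypes are independent across markers, unlike related breeding
material), selection or drift during DH production, genotyping error,
spatial field trends, multi-year effects.  Passing tests therefore show the
formulas and machinery are correct under the stated genetic model, not that
prediction accuracy on real programs will match the synthetic correlations.

## Numerical choices

* REML optimizers and tolerances as above; variance parameters bounded in
  log space to [10⁻⁶, 10⁴] × var(y).
* Seeds are mandatory for every stochastic operation; a fixed seed gives
  byte-identical reports.
* Cross ids are `parent1xparent2`; all rankings break ties
  lexicographically.
* Output files carry a provenance header (tool version, config hash, seed)
  and floats are written at repr precision so round-trips are bit-exact.

## Known limitations

* Additive architecture only: no dominance or epistasis terms in either
  prediction or simulation; heterozygous material is out of scope.
* The trial model has no spatial (row-column) component and no multi-year
  structure.
* With 5 locations the location variance component carries 4 degrees of
  freedom; its REML estimate is unbiased but strongly right-skewed, so
  single-study estimates (and even 20-replicate medians) scatter widely —
  see the recovery test's docstring.
* The Kosambi option changes predictions but has no matched simulation
  oracle (the simulator is interference-free).
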