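# Methods

## The simulated population

The simulator emulates a progeny-testing dairy scheme. A closed historical
population (default 50 sires + 50 dams) is random-mated for 50 discrete
generations; founders start at allele frequency 0.5 at every locus, and the
bottleneck then produces a realistic allele-frequency spectrum, linkage
disequilibrium and inbreeding. The population is then expanded in one round
of mating (parents drawn with replacement from the last historical
generation) to the production scale — by default 1,000 sires and 200,000
dams — and four discrete evaluation generations G1–G4 are bred. Each
generation consists of one female offspring per dam plus `n_sires` male
offspring from randomly drawn dams; every offspring receives a uniformly
drawn sire. There is no selection, no overlapping of generations, no
mutation and no migration. Males of G1–G3 are genotyped reference bulls,
males of G4 genotyped validation bulls, and every G1–G4 female is a
phenotyped cow (the expansion-generation G0 females are dams only — they
carry no records).

**Meiosis.** Crossovers follow Haldane's model: Poisson counts proportional
to map length, no interference, independent chromosomes. Because a
no-interference crossover process is Markov along the chromosome, it is
implemented as independent strand switches between adjacent typed loci with
probability `0.5(1 − exp(−2d))` for map distance `d` Morgans (0.5 across
chromosome boundaries). This is distributionally identical at the typed
loci and fully vectorisable; the classical consequences — one expected
(observable) crossover per Morgan, recombination fraction 0.0906 at 10 cM —
hold exactly and are verified in the tests.

**Genome and trait architecture.** Five 100 cM chromosomes carry 5,000
equally spaced SNPs (0.1 cM) placed at interval midpoints, and 300 biallelic
QTLs at uniform random positions (a positional density table can be
supplied to mimic gene-rich regions; the mouse gene map sometimes used for
this purpose is not reproducible, so uniform placement is the default).
QTLs split randomly into three equal groups: trait-I-only, trait-II-only
and pleiotropic, the last with *identical* effects on both traits, so with
equal group sizes and i.i.d. effect magnitudes the expected genetic
correlation is 0.5. Effect magnitudes are gamma draws with random sign.
The default shape is 0.84 with scale 5.4; a shape of 0.64 has also been
argued to be more representative of unreported small effects, and the
parameter is configurable — the scale is immaterial because breeding values
are re-standardised. True breeding values are QTL dosage sums divided by a
per-trait constant chosen so their variance over all of G1 is exactly 1;
the same divisor applies to every generation. Cow phenotypes are
`TBV + e`, `e ~ N(0, (1 − h²)/h²)` independently per trait (defaults
h² = 0.3 and 0.05, residual correlation 0), which fixes the narrow-sense
heritability at h².

**Seeding.** A master seed spawns named `SeedSequence` streams per
replicate (genome, effects, history, breeding, phenotypes, masking), so
scenarios within a replicate share one population and masking is a single
shared draw per (replicate, scenario) — all model comparisons are paired.
Identical seeds give bit-identical populations and reports.

## Relationship matrices

The pedigree numerator matrix A is never formed: its sparse inverse is
assembled directly by Henderson's rules with Mendelian-sampling variances
`d_i = 0.5 − 0.25(F_s + F_d)` using inbreeding coefficients from the
Meuwissen–Luo algorithm (the 50-generation bottleneck makes F material).
`log|A| = Σ log d_i` falls out of the same pass and feeds the REML
likelihood. Dense A blocks, when needed, are recovered by solving
`A⁻¹X = E`.

The genomic matrix is VanRaden's first method, `G = ZZ'/(2Σ p_j(1−p_j))`
with Z the dosages centered at `2p`. Allele frequencies are observed
frequencies across all genotyped bulls (reference + validation together),
which keeps validation animals exchangeable; monomorphic markers drop out
of numerator and denominator identically. G is made strictly positive
definite by an additive ridge (default 1e−6, recorded on the object) rather
than by blending with A, to interfere as little as possible with the
marker information.

## The mixed-model engine

One model class covers all four analyses (ST/MT × pedigree/genomic):
intercept-only fixed effects (one μ per trait, exactly the study's models —
no general fixed-effect machinery), genetic covariance `K ⊗ H`, residual
`I ⊗ R` with R restricted to the traits observed on each record unit.
Henderson's mixed-model equations are assembled sparse when K⁻¹ is sparse
(pedigree) and dense otherwise (genomic); sparse systems factorize with
SuperLU under the MMD_AT_PLUS_A symmetric-mode ordering, dense ones by
Cholesky. Systems beyond `mme_exact_limit` (default 20,000 equations in the
library, 60,000 in the pipeline configuration) switch to Jacobi-
preconditioned conjugate gradients for fixed-component solving; REML and
PEV reliabilities need the factorization and refuse that scale explicitly.
Animals present in K without records receive predictions through the
covariance structure; the conditional-expectation identity
`ĝ_v = K_vr K_rr⁻¹ ĝ_r` is verified numerically in the tests.

**REML.** The restricted log-likelihood is computed from the sparse
factorization as `−2l = log|C| + log|R_big| + t·log|K| + q·log|H| + y'Py`
plus the usual constant. Four estimation methods:

- `ai` — average-information updates with exact gradients in a dense
  observation-scale (V-matrix) formulation; step-halving keeps iterates in
  the parameter space and enforces a monotone log-likelihood. Intended for
  moderate record counts (`ai_obs_limit`, default 3,000 records in the
  library; 1,000 in the pipeline, where the cubic cost of the dense
  formulation stops paying for itself).
- `em` — expectation-maximisation for complete trait patterns, using the
  dense inverse of the coefficient matrix; slow but bulletproof, used as a
  cross-check.
- `direct_search` — Nelder–Mead on a log-Cholesky parametrisation; fully
  derivative-free, the independent oracle for the other methods.
- `quasi_newton` — L-BFGS-B with numerical gradients on the same
  parametrisation, objective scaled by the record count so gradients are
  O(1); log-variances are bounded in ±8 so boundary estimates (a variance
  estimated at zero) terminate instead of drifting to −∞. This is the
  work-horse for the large sparse pedigree systems.

`auto` (the pipeline default) runs AI below the record-count limit —
polishing with the bounded quasi-Newton search if AI stalls — and the
quasi-Newton search above it. Convergence is declared at relative parameter
change < 1e−8 or gradient norm < 1e−6, with a maximum of 200 iterations; a
non-converged fit returns flagged components (`converged=False`), never an
exception. Starting values default to half the phenotypic (co)variance on
the diagonal.

**Reliability.** The PEV-based reliability is
`r²_i = 1 − PEV_i / (σ²_g(1 + F_i))`, with PEV the diagonal of the inverted
coefficient matrix at the animal's genetic-effect rows (computed by
targeted solves against the cached factorization, so only requested animals
pay for it) and F from the pedigree (or `G_ii − 1`). It is clamped to
[0, 1]. The empirical variant — squared correlation with TBV — lives in the
evaluation module because it needs the simulated truth; the study reports
use the empirical variant for EBV-reliability tables and the PEV variant
(averaged over reference bulls whose responses are not masked) for the
GEBV-rescaling step, because the two differ at finite scale and field practice
varies on which reliability enters the rescaling.

## Evaluation statistics

Reliability of genomic predictions is the squared Pearson correlation
between GEBV and TBV of the validation bulls; bias is the OLS regression of
TBV on GEBV (slope 1 = unbiased, intercepts recorded). Because EBV
responses are shrunk toward the mean, GEBVs trained on them are deflated by
roughly the mean reference EBV reliability `r̄²`; rescaled slopes
`b_c = b·r̄²` (regression on `GEBV/r̄²`) are reported alongside the raw
ones. STGM/MTGM validation correlations share the TBV, so their difference
is tested with Williams' modified t,

`t = (r_1T − r_2T) √[(n−1)(1+r_12) / (2((n−1)/(n−3))|R| + r̄²(1−r_12)³)]`,

`|R| = 1 − r²_1T − r²_2T − r²_12 + 2 r_1T r_2T r_12`, df = n−3, with n the
number of validation bulls contributing both GEBVs; two-sided p-values from
Student's t are marked `**` below 0.01. Replicates aggregate per cell as
mean and sample SD (n−1); a single replicate reports SD 0 with the
replicate count visible. The null calibration of the t (rejection rate ≈ 5%
at nominal 5%) is verified by simulation in the tests.

## The study pipeline

Per replicate: simulate; fit two single-trait and one multiple-trait
pedigree model on all G1–G4 cow phenotypes (variance components by REML,
then BLUP); record EBV reliabilities/regressions for reference and
validation bulls; build EBV_s and EBV_m response tables for the reference
bulls; per scenario, mask 90% of one trait's responses (masked bulls'
genotypes stay in G as unphenotyped connectors — the masking is a response
phenomenon, not a genotyping one); re-estimate genomic variance components
and fit STGM and MTGM per response type; score validation bulls. Responses
enter GBLUP uncentered (the intercept absorbs the mean) and unweighted
(homogeneous residual variance), although reference bulls' EBV
reliabilities differ. Genomic variance components are re-estimated per
(scenario, response) rather than recycled from the pedigree stage.

## Problem sizes and what the desk scale can show

The full-scale configuration (`configs/full.yaml`; ~804,000 phenotyped
animals per replicate) needs hours and tens of GB per replicate and is
shipped for workstation use only. The shipped default (`reduced`) is
100 sires × 2,000 dams, 1,000 markers, 60 QTLs. The test suite goes one
step further down, and deliberately scales the *genome* with the
population: with few reference bulls and a full-length genome the number of
independent chromosome segments swamps the information in the reference
set and every genomic reliability sinks to ~0.1, making directional claims
untestable. The desk conditions (2 × 100 cM, 400 markers, 30 QTLs, 25+25
historical animals × 30 generations, 75 sires × 1,500 dams ⇒ 225 reference
and 75 validation bulls, 90% masking, 2–3 replicates) keep the information
balance of the full study, so the qualitative findings — GEBV ≫ EBV
reliability with complete data, MTGM ≈ STGM for the complete
high-heritability trait, MTGM > STGM for a masked trait — are reproduced,
while the *magnitudes* (reliabilities ~0.4–0.6 rather than ~0.87) remain
scale-bound. Passing tests therefore certify the machinery and the
directions, not the full-scale numbers. Equally, the simulator's idealised
features — phenotypes with a single intercept and no systematic
environment, exactly known pedigrees, markers and QTLs on the same panel,
no genotyping error — mean real-data performance claims are out of reach by
design.

## Numerical choices and degenerate inputs

Monomorphic loci contribute nothing to G or to genetic variance and are
handled implicitly. A constant response vector raises an error in REML
rather than silently converging. Exactly singular H (genetic correlation
±1) is rejected by the precision-form equations with a pointer to jitter;
tests approach the limit at r_g = 0.999. Variance estimates at the boundary
come back as tiny positive values with `converged` flagged, and downstream
statistics treat near-constant prediction vectors as errors rather than
coercing them. Masking retains `round((1−f)·n)` bulls and refuses to retain
zero. Pedigrees may arrive in any row order (a topological sort is applied);
cycles and references to missing parents raise immediately.
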