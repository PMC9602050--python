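# Methods

## Model

Each of K standardized traits is assumed to follow a two-component
polygenic model. Causal SNPs split into a shared set (effects collinear
across all traits: a single effect vector β₀ scaled per trait by
w_i·h_i, with w²_i the proportion of trait i's heritability explained by
the shared factors and sign(w_i) the direction of the shared effect) and a
trait-specific set (per-trait effect vectors with cross-trait correlation
U_unsh, scaled by √(1−w²_i)·h_i). Residual noise is jointly normal with
correlation U_env. At the level of trait-trait correlation matrices this
gives the correlation-component decomposition

    U_gen  = w wᵀ + D U_unsh D,   D = diag(√(1−w²_i))
    U_phen = H U_gen H + E U_env E,   H = diag(h_i), E = diag(√(1−h²_i))

All traits are treated as unit-variance; heritabilities enter only through
H. The decomposition requires K ≥ 3: with two traits the rank-one shared
part is not identifiable from a single off-diagonal correlation.

## SGI screen

A shared impact is declared testable when (a) U_gen is positive definite
(smallest eigenvalue above 1e-8), (b) every off-diagonal |r_ij| exceeds a
threshold, default 0.2, and (c) there exists a sign vector s ∈ {−1,+1}^K
with sign(r_ij) = s_i·s_j for all pairs — the sign pattern a rank-one
factor would produce. The threshold comparison uses point estimates of the
absolute correlations; direction is handled entirely by the sign test, so
traits negatively coupled to the shared factor pass. Exact zeros fail both
the threshold and the sign test.

## Estimating w

w is the minimizer of the unweighted loss
Σ_{i<j} (r_ij − w_i w_j)², i.e. the rank-one fit to the off-diagonal of
U_gen (the diagonal is uninformative: both sides are 1 identically).
Minimization uses L-BFGS-B with the analytic gradient
∂Loss/∂w_i = −2 Σ_{j≠i}(r_ij − w_i w_j) w_j, box [−1+1e-6, 1−1e-6]^K,
objective tolerance 1e-14. Starts: magnitudes {0.3, 0.5, 0.7, 0.9} crossed
with the candidate sign patterns (the screen's sign vector, the all-ones
vector, and their negations, deduplicated); a start reaching loss < 1e-13
short-circuits the rest, since that is numerically a global minimum of a
nonnegative objective. Ties within 1e-12 resolve toward the larger ‖w‖²,
making the output deterministic. The solution is sign-canonicalized so
Σ w_i ≥ 0 (the loss is invariant under global negation). Estimates pinned
at the box boundary raise a warning (heritability fully shared). The
unshared matrix is recovered as D⁻¹(U_gen − w wᵀ)D⁻¹ with unit diagonal
forced and off-diagonals clipped to [−1, 1].

The loss is not normalized by the number of pairs; this affects reported
loss magnitudes, never the argmin.

## SGIT and UGITs

α maximizes the shared-heritability ratio (kᵀHw)²/(kᵀU_phen k), a
Rayleigh-type problem with the closed-form solution
α = U_phen⁻¹Hw / √(wᵀHU_phen⁻¹Hw); the normalization gives SGIT unit
phenotypic variance, which the c-coefficients presuppose. With
C_gen = H U_gen H, the impact of SGIT on trait i is
c_i = (C_gen α)_i / (αᵀ C_gen α) and Γ = I − α cᵀ; column i of Γ encodes
UGIT_i = y_i − c_i·SGIT. Algebraically Γᵀ C_gen α = 0: every UGIT is
genetically uncorrelated with SGIT. The UGIT genetic correlation matrix is
Γᵀ C_gen Γ normalized to unit diagonal; UGITs with genetic variance below
1e-8 get zeroed correlations (0/0 guard) and a warning. Re-running the
screen on that matrix should fail — the framework's internal consistency
check that no shared impact remains.

Because the practical pipeline builds α from the *estimated* w, a UGIT can
retain a small shared component (order 1e-3 of variance in the worked
example); this is the known nonspecificity of the construction, not an
error.

Confidence intervals for α and γ are out of scope.

## GIP1 baseline

The comparison method is the first principal component of C_gen, rescaled
to unit phenotypic variance (β = v/√(vᵀU_phen v), sign fixed by Σβ ≥ 0) so
its heritabilities are directly comparable to SGIT's. A leading eigenvalue
degenerate within 1e-10 is an error — the direction is undefined (e.g.
C_gen ∝ I when w = 0 and U_unsh = I).

## Simulation engine

Each scenario is parameterized by (K, w², h², s, d1, d2) plus an
equal/spread flag for the per-trait w². U_unsh entries are 0 with
probability s, else Uniform(−d1, d1); U_env entries Uniform(−d2, d2). A
draw failing positive definiteness (smallest eigenvalue ≤ 1e-6) is redrawn
up to 50 times, then shrunk toward the identity, (1−λ)U + λI with the
smallest λ on a 0.05 grid restoring definiteness. U_gen and U_phen
composed from PD inputs are PD by construction. In the "different w²"
situation per-trait w²_i are spread evenly over [w²−0.1, w²+0.1], clipped
to [0.05, 0.95], keeping the nominal value interpretable.

Per replicate, w is re-estimated from the simulated U_gen alone and scored
by ΔW = mean_i ((w0_i − ŵ_i)/w0_i)² after resolving the global sign
(ΔW aggregates across traits by mean; the global flip minimizing the
metric is used). The SGIT is then formed three ways — α from the true w0,
α from ŵ, and GIP1 — and its shared/total heritabilities and
Q = h²_shared/h²_total are computed *analytically against the true
matrices and true w0*, never against estimates. Per-replicate failures are
counted and excluded from means, never aborting a scenario. The default
grid (K ∈ {3,4,5} × w² ∈ {0.2..0.9} × h² ∈ {0.2,0.5,0.8} × s ∈ {0.3,0.8}
× {same, spread}) has 288 scenarios; per-scenario seeds spawn
deterministically from a master seed, so any table is bit-reproducible.

Default amplitudes d1 = d2 = 0.5. The acceptance script runs 1,000
replicates per scenario — enough for the Monte-Carlo error of a scenario
mean to sit well inside the bounds being checked while keeping the full
recomputation around a minute on one CPU.

One scenario sits essentially on its bound: the mean Q at K = 5, w² = 0.5
computes to ≈ 79.2% against the ≥ 80% expectation (the estimated-w α is
evaluated against the truth; the true-w α gives ≈ 83%). The value is
reported as computed.

## Individual-level cohort simulator

Genotypes are independent binomial(2, maf) dosages, maf ~ Uniform(0.05,
0.5), column-standardized; no LD. Effects are scaled by 1/√M₀ and 1/√M₁ so
the expected shared and unshared genetic variances are w²h² and (1−w²)h²
at finite SNP counts; traits are re-standardized empirically after
assembly because the unit-variance model holds only in expectation.
Variants sit on one synthetic chromosome at 10 kb spacing with
deterministic ids, so distance pruning and clumping behave meaningfully on
simulated output. The per-SNP GWAS is simple linear regression of the
trait on unstandardized dosage (monomorphic SNPs dropped with a logged
count).

What the simulator deliberately omits: linkage disequilibrium, MAF-effect
coupling, case-control liability scales, population structure and relatedness.
Passing end-to-end tests therefore demonstrate the correctness of the
combination arithmetic under the model's assumptions, not robustness to
the confounding structure of real GWAS.

## sumCOT

On the doubly-standardized scale (standardized trait, standardized
genotype) a GWAS effect is b = z/√N with standard error 1/√N. The
combination kᵀy has per-SNP effect Σ k_i b_i / √(kᵀRk) and squared error
Σ k_i k_l R_il se_i se_l / (kᵀRk), where R is the phenotypic correlation
matrix; the √(kᵀRk) standardization gives the combined trait unit variance
and cancels in z. Using b = z/√N rather than z/√(N−2+z²) is an
approximation that is negligible at GWAS sample sizes. R doubles as the
correlation of effect-estimate errors across GWASs: estimated from
insignificant Z-scores of distance-pruned SNPs (|z| < 2, one SNP per
500 kb), it equals the phenotypic correlation scaled by sample overlap,
which is exactly the error correlation; supplied as a true phenotypic
correlation it is correct under full overlap. For *disjoint* cohorts these
two roles diverge, and the single-matrix design then reports the per-SNP
precision of the combination (per-cohort N for an equal-weight combination
of two equal disjoint GWASs), not the union sample size — a documented
limitation of driving both normalization and error propagation off one
matrix.

Output beta/se are re-expressed on the per-allele dosage scale via
√(2p(1−p)), matching ordinary summary-statistic conventions; the
trait-level effective sample size is the median over SNPs of
1/(2p(1−p)·se²), which recovers the input N exactly for an identity
combination. Per-SNP N carries the harmonized minimum. Harmonization
inner-joins variants on id, flips Z where alleles are swapped relative to
the first table, and drops inconsistent and strand-ambiguous (A/T, C/G)
variants with logged counts; missing variants are never imputed.

Genomic-control correction multiplies standard errors by √intercept (and
divides Z accordingly) only when the LD-score-regression intercept exceeds
1; deflationary intercepts are left alone.

## Locus post-processing

Clumping is greedy on p (evaluated in −log10 space so underflowed p-values
rank correctly): take the most significant uncovered SNP below the
threshold (default 5×10⁻⁸), emit a locus spanning ±500 kb, remove covered
SNPs, repeat; ties break by (chr, pos). Positions are 1-based, intervals
closed. A target locus is novel when its lead lies outside every
original-trait locus span. The overlap matrix counts leads of one trait
falling inside spans of another (asymmetric by construction) and scales by
the smaller list size, the same min-scaling used for gene-set overlaps.
LD-aware clumping against a reference panel is out of scope.

## Input handling

Summary-statistic input accepts the common column dialects (SNP/rsid,
A1/ea, FRQ/eaf, NMISS/n, ...) unless strict mode disables synonyms. On
read: MAF filter (default 0.01), rows with p exactly 0 dropped (underflow
makes them unusable; outputs carry −log10 p alongside p to avoid creating
such rows), duplicate ids keep-first, unparseable rows tolerated up to
0.1% of the file. Every drop is logged with a count. P-values are carried
in −log10 space internally wherever ranking matters.

## Numerical conventions

- Correlation matrices validated on construction: symmetry and unit
  diagonal within 1e-10, entries in [−1, 1]; positive definiteness is a
  recorded flag (tolerance 1e-8) rather than a hard requirement.
- Degenerate combinations (phenotypic variance below 1e-12, e.g. the
  difference of two perfectly correlated traits) raise a dedicated error.
- All randomness flows through `numpy.random.Generator`; every simulation
  output is a pure function of its parameters and seed.

## Known limitations

- Heritabilities and correlation matrices are *inputs*; estimating them
  (e.g. by LD Score regression) is external to this package.
- Weak genetic correlations inflate the estimated shared contributions;
  with only three traits the w estimates are unstable at low w² (mean
  relative squared errors up to ~0.6 in simulation) and results should be
  read with caution.
- The estimated-w SGIT can be beaten by GIP1 in high-heritability,
  low-shared regimes (h² = 0.8, w² < 0.5 scenario means), mirroring the
  regime dependence seen in simulation.
- Binary-trait liability conversion, meta-analysis across cohorts of the
  same trait, and LD-aware conditional analysis are out of scope.
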