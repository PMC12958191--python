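# Methods

## Model

Single-trait animal model `y = Xb + Wu + e` with `u ~ N(0, H sigma_a^2)`
and `e ~ N(0, I sigma_e^2)`. Variances are parameterized by heritability
with total phenotypic variance 1: `sigma_a^2 = h^2`, `sigma_e^2 = 1 - h^2`,
`lambda = sigma_e^2 / sigma_a^2`. The combined relationship matrix H merges
pedigree and genomic information through its inverse,

    H^-1 = A^-1 + [0 0; 0  tau*G^-1 - omega*A22^-1],

added over the genotyped block (`tau = omega = 1` by default; both exposed
because scaled variants are used in practice). The binary 1/2-coded disease
trait is analyzed with this linear model, as is standard for that trait —
no threshold model is offered.

**Reliability.** `rel_i = 1 - PEV_i / (sigma_a^2 (1 + F_i))` with pedigree
inbreeding F_i, `PEV_i = sigma_e^2 [C^-1]_ii` on animal i's MME equation.
The denominator convention (pedigree `1 + F`) is used identically for the
exact and the approximated flavor, so all comparisons are internally
coherent; at desk scale (n_equations in the low thousands) C is inverted
densely (Cholesky, falling back to a pseudo-inverse for rank-deficient
fixed blocks, which are reported with generalized-inverse semantics).

## Relationship matrices

- **A, F, A⁻¹**: recursive tabular method for A and inbreeding; Henderson's
  parent-contribution rules for the sparse inverse with
  `b_i = 0.5 - 0.25 (F_s + F_d)` and unknown-parent adjustments (an unknown
  parent contributes F = −1, i.e. one unknown parent gives
  `b = 0.75 − 0.25 F_known`, two give `b = 1`).
- **GRM**: `G0 = W W' / (2 Σ p_j (1 − p_j))`, W centered at twice the
  observed allele frequencies; monomorphic loci are dropped with a warning
  (their scaling contribution is zero). The returned matrix is
  `G = alpha*G0 + (1−alpha)*A22` with `alpha = 0.95` — the blend guarantees
  positive definiteness and is declared in the run configuration. No
  mean/scale tuning of G to A22 is applied (the construction is already
  anchored to A22 through the blend).
- **Core sizing**: the SVD is taken of the *centered* gene content W, whose
  squared singular values are the spectrum of the GRM up to the scaling
  constant; raw gene content would be dominated by allele-frequency means.
  `choose_core_size(threshold)` returns the smallest k whose cumulative
  squared singular values reach the threshold; `round_up_core` implements
  the round-up-to-a-step convention used for practical core sizes.
- **APY**: `m_ii = g_ii − g_ic Gcc^-1 g_ci`; a Cholesky factor of Gcc is
  computed once and reused. Errors are loud: a reciprocal condition number
  of Gcc below 1e−12 or any `m_ii ≤ 1e−10` aborts with the offending
  animal named, because silent near-singularity corrupts every noncore
  equation. Nested cores are drawn uniformly without replacement, each
  smaller core from the next larger one, so the smallest core is contained
  in all others.

## The reliability approximation

The approximation never assembles the ssGBLUP MME. Its stages:

1. **Pedigree-only reliabilities**, exact from the pedigree MME inverse.
   Computing them exactly (rather than through a further approximation
   layer) isolates the effect under study — the APY core — from unrelated
   approximation error.
2. **Effective record contributions.** Each genotyped animal's non-genomic
   information is summarized as a diagonal weight `d_i` in residual-variance
   units. The single-animal reversal `d = lambda*r/(1−r)` is exposed as
   `reverse_reliability_weights`, but it overstates the weights when
   animals are related: a pedigree reliability already contains information
   flowing through relatives, which the genotyped-block system would count
   again through the relationship matrix. The pipeline therefore derives
   the weights with `effective_record_weights`, a damped fixed-point
   iteration for the diagonal D whose genotyped-only system
   `lambda*A22^-1 + D` reproduces the pedigree reliabilities (damping 0.8,
   up to 40 iterations, residual tolerance 1e−4 on the reliability scale;
   d is floored at 0, so reliabilities that relationships alone already
   exceed are matched as closely as the floor allows). With unrelated
   animals (A22 = I) this reduces exactly to the single-animal reversal.
3. **Genomic step.** `K = lambda*G_APY^-1 + D` has a dense core block, a
   dense core–noncore band and a *diagonal* noncore block. Its inverse
   diagonal comes from a Schur-complement sweep: form
   `S = K_cc − K_cn K_nn^-1 K_nc`, invert S densely, and recover the
   noncore diagonal as `1/k_i + (col_i K_cn)' S^-1 (col_i K_cn) / k_i^2`.
   The two expensive products — assembling the core block of `G_APY^-1`
   and forming the Schur complement — each cost O(n_c² n_n); everything
   else is O(n_c³) or O(n_c n_n). Genomic reliabilities are
   `rel_i = 1 − lambda [K^-1]_ii / g_ii`, clipped to [0, 1].
4. **Propagation.** The genomic gain is converted to pseudo-record weights
   `Delta_i = max(0, d(rel_G) − d(rel_P))` — subtracting the
   pedigree-implied effective records and flooring at zero is the simplest
   defensible guard against double counting — added to the genotyped
   animals' diagonals in the pedigree MME, and reliabilities for **all**
   animals are recomputed from the updated inverse diagonal (a Woodbury
   update of the cached pedigree inverse, so each core scenario costs one
   m×m solve with m = number of positive gains rather than a fresh full
   inversion).

Reliabilities are capped at `1 − 1e−6` before any reversal so weights stay
finite.

## Randomized matrix multiplication

The sketched variant replaces the two O(n_c² n_n) products (step 3 above)
by uniform column sampling over the noncore dimension: sample k inner
indices without replacement and rescale by `n_n/k`. The estimator is
unbiased, and k = n_n reproduces the exact product — which is why column
sampling was chosen over Gaussian projection: the full-k case is an exact
identity rather than an approximate one. The two products use distinct
sub-seeds derived deterministically from the sketch seed. Sketching the
Schur complement perturbs every diagonal entry of the inverse, and the
experiments show the resulting reliabilities decorrelate substantially from
the exact-path output already at k = 0.5 n_n.

## Synthetic populations

The generator emulates the *structure* of a dairy evaluation, not any real
dataset: discrete generations under random mating (founders alternate
male/female; each dam has `offspring_per_dam` offspring by a random sire),
gene-dropped unlinked SNPs with founder frequencies uniform on the MAF
range (emulating a MAF-filtered panel; unknown-parent gametes draw from the
founder frequency, avoiding an explicit unknown-parent-group model), true
breeding values `u = W a` rescaled so the realized Var(u) equals
`h^2`, iid residuals, and an optional categorical fixed effect. In binary
mode the liability is thresholded at the empirical quantile matching the
configured incidence and coded 1/2.

Defaults are the study conditions: 150 founders × 4 generations ≈ 1,900
animals, 40% genotyped (≈ 740), 1,000 SNPs with MAF in [0.05, 0.5],
h² = 0.042 with a binary 1/2 trait at 15% incidence (a realistic calf
respiratory-disease rate; the incidence is a modeling choice, not an
estimate), 90% of animals with one record. These sizes keep a full
replicate — two dense MME inversions plus five APY scenarios — near ten
seconds, so the five-replicate study runs in well under a minute.

What the generator does **not** emulate: selection and assortative mating,
overlapping generations, genotyping-by-merit bias, linkage between markers,
herd structure beyond a single categorical effect, and multi-trait
recording. Consequently the synthetic experiments demonstrate the
*mechanisms* (conditional-distribution loss under core shrinkage, the
F-core > N-core > R-core ordering of degradation, low-heritability
fragility of reverse-reliability weights) and the algebraic correctness of
every stage — they do not predict the magnitude of degradation in a real
population, where genotyping is strongly merit-biased and the
noncore:core ratio is far larger.

## The core-reduction experiment

Per replicate seed: simulate; build A, A⁻¹, A22, G; size the benchmark core
at the 99% eigenvalue threshold; draw nested cores at
{100, 80, 60, 40, 20}% of it; compute exact ssGBLUP reliabilities (dense
G⁻¹ path) and the approximation for every core; classify genotyped animals
into R-core (in the reduced core), F-core (dropped from the benchmark
core), N-core (never core); and compare. `MD = mean(benchmark −
candidate)`, chosen so that overestimation by the candidate is negative;
the regression takes the benchmark as response and the candidate as
predictor (both orientations are available; this one is the default).
Groups with fewer than two animals or zero variance report MD only and are
flagged undefined rather than propagating NaN. Replicate means are taken
over 5 seeds by default; an alternative-heritability pass (e.g. h² = 0.30)
can be attached via `h2_alternative`.

On the synthetic defaults the R-core group shows small *positive* MD
(mild underestimation) rather than the mild overestimation a large
merit-genotyped population can show; the monotone N-core degradation and
the F ≥ N ≥ R ordering of |MD| are the stable, mechanism-level signatures.

## Numerical choices

- Random streams: every stochastic operation draws from
  `default_rng([seed, stream_tag])` with a fixed per-operation tag, so
  stages are independently reproducible and bit-identical under a seed.
- Gcc condition cap 1e−12 (reciprocal), Mnn floor 1e−10, reliability cap
  1e−6, MME residual tolerance 1e−8 relative (1e−6 for the least-squares
  fallback), negative-PEV tolerance 1e−8·sigma_e^2.
- Fraction-to-count rounding anywhere a fraction selects animals:
  `floor(fraction · n)`, minimum 1.
- SNP file dialect: `id` + contiguous 0/1/2 string, `5` = missing, imputed
  to twice the observed locus frequency (an all-missing locus falls back to
  gene content 1). Ragged strings and foreign characters are hard errors.
- Report tables round to 2 decimals; the JSON sidecar keeps full precision
  and round-trips exactly. Writes are atomic (temp-then-rename).

## Known limitations

- Exact reliabilities require a dense inverse; the implementation is
  intended for desk-scale verification (thousands of equations), not
  production evaluations.
- The weight-fitting fixed point matches reliabilities, not the full PEV
  covariance structure; propagation updates only diagonals, so approximated
  reliabilities of *relatives* of genotyped animals are first-order
  correct only.
- At very low heritability (lambda ≈ 23 at h² = 0.042) the approximation's
  agreement with exact MME reliabilities drops markedly — the same
  fragility practitioners report for reverse-reliability-based
  approximations on low-h² traits.
- Unknown-parent groups, residual polygenic fractions, and multi-trait
  models are out of scope.
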