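# Methods

## Model

`recmt` fits the standard multiple-trait animal model (SM)

    y_i = X_i b + u_i + e_i,        i = 1..n records,
    u ~ N(0, A ⊗ G),                e ~ N(0, I ⊗ R),

where `y_i` is the m-vector of trait records of individual i (m = 5 in the
cattle-style default: birth weight BW, weights at 90 and 210 days W90/W210,
cold carcass weight CCW, conformation score CONF), `b` collects trait-specific
fixed effects, `A` is the numerator relationship matrix of all `s` pedigree
individuals (recorded or not), and `G`, `R` are the m×m additive-genetic and
residual covariance matrices. Records may be partially missing; a record with
no observed trait contributes only through the pedigree.

Premultiplying by a unit-lower-triangular matrix `Λ` rewrites the SM as a
recursive (structural equation) model

    Λ y_i = Λ X_i b + u*_i + e*_i,   G* = Λ G Λ′,   R* = Λ R Λ′,

with structural coefficients `λ_{i→j} = −Λ[j,i]`: the phenotypic effect of an
earlier trait i on a later trait j. When every cross-block pair of traits is
linked either by a coefficient or by a residual covariance, the two models
have identical likelihoods, so a recursive-model fit can be obtained from an
SM fit by pure post-processing: choose `Λ` as the inverse of the L factor of
the (block-)LDL′ factorization of `R`, which makes `R*` (block-)diagonal —
the identifying restriction of recursive models. Because `Λ y` is the
Gaussian innovation representation, the rows of `Λ` for a block are minus the
regression coefficients of that block's traits on all preceding traits, and
each `R*` diagonal block is the Schur complement `C − B E⁻¹ B′` (the
conditional residual covariance given the earlier blocks). The package
implements the factorization once for an arbitrary ordered block partition;
the "sequential" two-block entry point (`sequential_block_ldl`) exists
because nested two-block factorizations compose to the same result, and is
tested for exact agreement.

The transformation is applied to **every stored posterior sample** of
(G, R), yielding full posterior distributions for `Λ`, `G*`, `R*`, the
recursive-model heritabilities and correlations. Summaries are therefore
mean/SD over per-sample transforms ("average of transforms"); the
deterministic convenience mode (transform of the posterior-mean matrices)
differs by a Jensen gap that a Monte-Carlo test bounds well below 0.5% at
posterior spreads typical of large datasets.

## Sampler

A single-chain systematic-scan Gibbs sampler:

1. **Missing-record augmentation.** Each partially observed record draws its
   missing traits from N(μ_M + R_MO R_OO⁻¹ (y_O − μ_O), R_MM − R_MO R_OO⁻¹ R_OM)
   with μ = X_i b + u_i; records are grouped by missingness pattern so the
   per-pattern conditional factors are computed once per iteration.
2. **Location effects.** All fixed effects are drawn in one joint Gaussian
   block from the full conditional N(C⁻¹r, C⁻¹) with
   C = X′(I⊗R⁻¹)X (trait-pair cross-products precomputed once). Breeding
   values are drawn single-site: u_i | rest is m-variate Gaussian with
   precision a^{ii}G⁻¹ + R⁻¹ (data term only for recorded individuals) —
   the update used by the standard animal-breeding Gibbs samplers. This loop
   is a numba kernel with hand-rolled small-matrix Cholesky solves.
3. **G update:** inverse Wishart IW(U′A⁻¹U + S0, s + ν0) over all s pedigree
   individuals (unrecorded ones carry pedigree-conditional u draws so the
   degrees of freedom are s, not n).
4. **R update:** inverse Wishart IW(Σ e_i e_i′ + S0, n + ν0) using completed
   (observed + augmented) residuals.

Priors are flat for b and proper weakly informative IW(ν0 = m+2, S0 = 0.01·I)
for G and R, both overridable. Chains initialize G and R at half the
empirical pairwise-complete phenotypic covariance (eigenvalue-floored to be
SPD), which starts the covariance structure near plausible values and
shortens the burn-in transient relative to a diagonal start; b and u start
at zero and missing records at observed trait means. Identification of the fixed effects uses
reference coding (first level dropped) against a global intercept; any
full-rank coding leaves the variance-component posterior unchanged. One
seeded `numpy` Generator drives all draws in a fixed order, so chains are
bit-reproducible; the kernel receives pre-generated normal deviates rather
than owning its own RNG.

### Validation

The update blocks are validated by independent oracles: conditional-Gaussian
augmentation against dense joint-precision conditioning; location draws
against a dense mixed-model-equations solve; variance draws against
closed-form inverse-Wishart / scaled-inverse-chi-square moments; and the full
parameter sweep by a Geweke-style successive-conditional test (alternating
data simulation with Gibbs sweeps must leave the prior invariant — checked
for m = 2 with missing data and m = 5).

### Mixing and chain length

The G↔R partition for a trait mixes only through the breeding-value field,
and the single-site u scan relaxes that field slowly — the known behaviour of
this sampler family (published analyses run hundreds of thousands of
iterations and report effective sample sizes of order 10³ out of 5·10⁵). At
the package's desk-scale test sizes (pedigree ≈ 3,000, n ≈ 2,000, 20,000
iterations) effective sizes for genetic variances are of order 10²; posterior
summaries at this length carry visible Monte-Carlo error, which the
validation experiments account for. Three mixing aids are available: the
`u_sweeps` option repeats the breeding-value scan within an iteration (each
sweep is a valid Gibbs update, so the stationary distribution is untouched;
a handful of sweeps severalfold improves the effective size of the G/R
partition on desk-scale data at ~50% extra cost); the empirical
initialization above; and an ancillarity-sufficiency interweaving move for
G (on by default): writing ``u_i = L v_i`` with ``G = LL'`` and whitened
``v ~ N(0, A⊗I)``, the likelihood is exactly Gaussian in the free entries
of the triangular ``L`` given ``v``, so ``L`` is proposed from that
Gaussian and accepted against the transformed inverse-Wishart prior (an
independence Metropolis-Hastings step whose acceptance is near one under a
weak prior). The centered/non-centered alternation jumps along the G/R
ridge instead of diffusing along it. Exactness of every variant is checked
by the successive-conditional (Geweke-style) tests. Short, under-mixed chains understate posterior spread;
credible-interval calibration checks therefore run at data sizes where the
posterior is well identified and the chain long relative to its mixing time.

## Pedigree machinery

`A` is built by the tabular method (exact inbreeding); `A⁻¹` is assembled
sparsely from Mendelian-sampling variances d_i = 1 − 0.25(A_ss + A_dd) (two
known parents; 1 − 0.25·A_pp with one, 1 for founders), i.e. inbreeding *is*
accounted for. Inbreeding coefficients are computed by memoized pairwise
kinship recursion so large founder-heavy pedigrees never need the dense A.
Dense A is refused above 5,000 individuals; the sampler itself only needs the
sparse inverse. Unknown parents (code 0/NA) are treated as draws from the
base population; genetic groups are out of scope.

## Synthetic data

The generator emulates a beef-cattle evaluation at desk scale:

- discrete generations under random mating (600 founders + 4×600 by default,
  so related matings and inbreeding arise by chance);
- breeding values by pedigree recursion u_i = ½(u_s + u_d) + η_i,
  η_i ~ N(0, d_i·G) — realizes u ~ N(0, A⊗G) in O(s) and exactly accounts
  for parental inbreeding;
- fixed effects shaped like the real evaluations: a 25-level
  herd-year-season-like contemporary group (effect SD 25% of trait SD), sex
  (±7.5%), dam age (6 levels), and an age-at-recording covariate for every
  trait except birth weight (±15 days around the target age, slope 2% of
  trait SD per day). Level counts are reduced from the thousands of real
  contemporary groups to keep desk-scale designs full rank;
- default (G, R) equal to the published cattle posterior means, trait means
  (41.1, 134.5, 250.7, 300.3, 11.9);
- pattern-structured missingness: each individual is assigned one
  observed-trait subset. The default pattern shares mirror the relative sizes
  of the largest recorded combinations in the cattle data (≈32% BW only,
  15% BW–W90, 14% BW–CCW–CONF, ..., 5.8% all five). Missingness is
  completely at random given the pattern, matching the ignorability the
  augmentation step assumes.

What the generator does **not** emulate: selection and non-random mating,
maternal/permanent-environment effects, informative missingness, categorical
thresholds for the conformation score (treated as Gaussian), and real
contemporary-group sizes. Passing recovery tests therefore demonstrates
correctness of the inference machinery under the model's own assumptions,
not robustness to violations of them.

## Numerical choices

- (Block-)LDL′ uses a scale-aware pivot guard: a leading block is declared
  singular when its smallest eigenvalue is below 1e−10·trace(R)/m.
- Cross-block entries of R* are set to exact zeros (not left at rounding
  level); round-trip Λ⁻¹R*Λ⁻¹′ = R is property-tested to 1e−10 relative.
- Sampled covariance matrices are symmetrized and SPD-checked each iteration;
  a failed Cholesky triggers one jitter retry, then aborts with the
  iteration index.
- ESS uses Geyer's initial-positive-sequence truncation, capped at the chain
  length, with a constant chain defined to have ESS = n.

## Test problem sizes

The validation suite chooses sizes as the package's own desk-scale defaults:
parameter recovery uses the full 5-trait system on a pedigree of 3,000 with
2,000 records, 30% structured missingness and 20,000 iterations (burn-in
5,000, thinning 10, three u sweeps per iteration); credible-interval
calibration for the structural coefficients uses 20 replicates of a 3-trait
fully recursive subsystem (BW → W90 → W210, the corresponding sub-blocks of
the published matrices) on a pedigree of 3,200 with 2,400 records and 8,000
iterations per replicate — a 3-trait system because the 5-trait G/R
partition needs chain lengths of the order the original analyses used
(hundreds of thousands of iterations) before its credible intervals are
calibrated, and a data size at which the λ posterior is well identified.
Oracle comparisons (mixed-model equations, Geweke) run on systems of tens of
individuals where dense linear algebra is exact.

Known limitation: at these chain lengths the frequentist coverage of the 95%
credible intervals for structural coefficients with strong trait
correlations (e.g. the W90 → W210 path, where the two weights share most of
their residual covariance) falls a few points short of nominal (~90%
empirically over 20 replicates); the shortfall shrinks with longer chains
and larger datasets and is a property of finite-chain inference with this
sampler family, not of the transformation layer, which is deterministic and
exact.
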