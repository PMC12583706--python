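# Methods

`hetscan` maps heterotic QTL (hQTL): loci whose net contribution to
mid-parent heterosis (MPH) — dominance plus all digenic epistatic
interactions with the rest of the genome — is tested directly, one marker
at a time, instead of scanning the O(p²) space of marker pairs.

## The model

Consider n hybrids produced by crossing r inbred lines, genotyped at p
biallelic markers coded 0/1/2 (reference-allele count). Stacking hybrid and
parent phenotypes into y_ori, the MPH vector is y_MPH = T y_ori, where each
row of the sparse n×(n+r) matrix T has +1 on the hybrid's column and −½ on
each parent's. Two structural identities follow: T·1 = 0 (the intercept is
annihilated) and T·M_A = 0, where M_A is the additive coding (code − 1) —
a hybrid's additive code is exactly the mean of its parents'. Additive
effects therefore vanish from the MPH scale, and independent residuals on
the original scale induce a structured residual covariance R = TT′ on the
MPH scale.

The null model for y_MPH contains four random background terms with
covariances proportional to trace-normalized kernels K_D, K_AA, K_AD, K_DD,
plus residuals with covariance R σ²_ε. The kernels are built from the
frequency-centered codings U_A (code − 2p_k) and U_D (the classical
dominance-deviation coding −2p_k², 2p_k(1−p_k), −2(1−p_k)² for codes
0/1/2), so the variance components line up with the classical dominance and
epistatic variance decomposition. The epistatic design matrices (p(p−1)/2
to p(p−1) columns) are never materialized; their cross-products come from
Hadamard identities, e.g.

    U_AA U_AA′ = ½[(U_A U_A′)∘(U_A U_A′) − (U_A∘U_A)(U_A∘U_A)′],

at O((n+r)²p) total cost.

The net heterotic effect of marker i is h_i = Z_i γ_i, where Z_i holds the
MPH-scale contrasts T l_i (dominance; l_i is the heterozygosity indicator
column) and ½T(m_i∘m_j), ½T(m_i∘l_j), ½T(l_i∘m_j), ½T(l_i∘l_j) for every
j ≠ i. An equivalent piecewise formulation expresses h_{i,F} for each
hybrid F through the four parental genotype patterns at i; it is
implemented as an independent oracle (`heterotic_effect_piecewise`) and the
equivalence is tested exhaustively on small populations. Treating the
4p−3 component effects as i.i.d. gives h_i ~ N(0, H_i σ²_h) with
H_i = Z_i Z_i′/c_i, c_i = tr(Z_i Z_i′)/n. H_i is assembled without
materializing Z_i: with S = M_A M_A′ + M_D M_D′ precomputed once,

    Z_i Z_i′ = (T l_i)(T l_i)′ + ¼ T[D_m S D_m + D_l S D_l − self-pairs]T′

(m = m_i, l = l_i, D_v = diag(v)); the j = i self-pair terms are removed
explicitly. Cost: O(n(n+r)) per marker, O(n(n+r)p) per genome — the basis
of the method's p/(t·n) runtime advantage over exhaustive pair scans.

## Estimation and testing

Because R is not the identity, the model is whitened once by the Cholesky
factor of R (y, covariates and all kernels), after which residuals are
i.i.d. The five variance components are estimated by average-information
REML with step halving, an EM fallback on non-improving steps, and an
active-set rule keeping components non-negative; convergence is declared at
a relative restricted-log-likelihood change below 1e-6 (cap 100
iterations, warning — not an error — on non-convergence).

Per-marker testing uses the P3D shortcut: the background variance ratios
r_* = σ²_*/σ²_ε are frozen at their null estimates, V0 = Σ r_* K̃_* + I is
factored once, and each marker reduces to a one-dimensional profile of the
restricted likelihood over δ = σ²_h/σ²_ε after an eigendecomposition of
the doubly-whitened H_i: a 64-point log-spaced grid on δ ∈ [1e-6, 1e6]
warm-starts a bounded scalar optimization, and the boundary δ = 0 is always
evaluated. The LR statistic λ = max(0, 2(l(δ̂) − l(0))) is referred to the
boundary null ½χ²₀ + ½χ²₁; λ = 0 returns p = 1 (the statistic sits on the
null's point mass). Both l(δ̂) and l(0) are computed in the same
δ-profiled parameterization so the ratio is internally consistent, and
restricted likelihoods are used throughout. With no population structure
the fixed-effect block is empty — the intercept is annihilated by T — and
users may pass covariates.

Component effects (d_i, aa_ij, ad_ij, ad_ji, dd_ij) are tested as fixed
effects by Wald statistics W = x̂²/var(x̂) ~ χ²₁ under GLS with covariance
σ²_ε V0; each epistatic model carries the companion dominance regressors it
needs, while additive main effects are omitted because T·M_A = 0 makes them
unestimable and irrelevant on the MPH scale.

## Multiple testing, intervals, PVE

Genome-wide significance uses step-down Bonferroni–Holm at α (default
0.05). Significant SNPs are grown into intervals by walking outward while
r² with the significant SNP itself stays ≥ 0.3 (LD is computed on parental
additive codes; chromosome ends truncate; a SNP whose neighbors fall below
the threshold is a singleton). Intervals merge to a fixpoint: always when
overlapping, otherwise when peak SNPs are within 10 Mb and the mean
cross-interval r² over the contained SNPs exceeds 0.3; never across
chromosomes. The lead SNP is the most significant member (ties broken by
smaller position). Each hQTL's PVE is
Δ_i σ̂²_h / (Δ_i σ̂²_h + Σ_* Δ_* σ̂²_* + σ̂²_ε), with Δ = mean(diag K) −
mean(K), evaluated by refitting the alternative model at the lead SNP under
the frozen background ratios (a P3D-consistent refit rather than a full
six-component REML).

## The simulator

`generate_population` emulates a factorial crossing program: inbred
parents (default 90, split 75 females / 15 males as in a reduced hybrid
wheat panel) with per-marker reference-allele frequencies drawn uniformly
over the MAF-respecting range and rejection until the realized parental MAF
clears the threshold (default 0.05); markers are spread over 21
chromosomes (600 Mb each) and hybrids sampled without replacement from the
factorial. It does **not** emulate linkage disequilibrium along
chromosomes, population structure, genotyping error or missingness — so a
green test establishes correctness of the algebra and calibration under
linkage equilibrium and exchangeable parents, not robustness to real LD
structure.

Phenotypes follow a five-architecture design. Background effects are drawn
from the four kernels with unit variance components; their sample variance
fixes the total variance V_t = S(ũ)/0.475 so the background explains 47.5%,
the single hQTL 2.5% and residuals (covariance TT′, variance 0.5·V_t) 50%
— heritability 0.5 by construction. The hQTL's effect combines a dominance
term (architectures 3–5) and interactions with one marker on each of 20,
5, 19, 4 or 0 other chromosomes, each pair assigned one family
(aa/ad/da/dd) uniformly. Each component's effect size is the positive root
x = sqrt(V_t·P_x / var(c_x)) with per-effect PVE P_x of 0.5%, 2% or 2.5%
by architecture.

A deliberate design choice: **c_x is the full contrast** (T(m_i∘m_j), T l_i
etc.) — the vector multiplying the effect in the underlying trait model —
and the ½ applies only when h_i is assembled, because a pairwise
interaction is split between the two loci it involves. Under this
convention each epistatic effect contributes P_x/4 to S(h_i)/V_t and the
architectures are self-consistent (20 × 0.5%/4 = 2.5% expected net PVE);
sizing on the halved coefficient instead would put the expected net PVE at
~10% and the acceptance loop below could never terminate. Because the
contrasts covary, the realized S(h_i)/V_t only approximates 2.5%; the
interactor set (markers and families) is resampled until it lands within
an absolute tolerance of 0.001 on the proportion (exact equality is
measure-zero), with a cap of 1000 attempts and an error reporting the
closest achieved PVE. Per-draw acceptance probability is roughly 1.5–13%
across architectures, so the cap is effectively never hit. Effect signs
are not randomized. S(·) is the unbiased (n−1) sample variance.

Power is the proportion of replicates in which the simulated hQTL marker
itself is significant after Holm correction; the FPR is the proportion of
the other markers called significant, averaged over replicates —
marker-based, not region-based. The heterozygosity association
cross-tabulates detection against hQTL heterozygosity > 0.5 (exactly 0.5
falls in the lower class) and uses a two-sided Fisher exact test.

## Numerical choices and degenerate inputs

- Cholesky factorizations retry once with jitter 1e-8·mean(diag); failure
  is an error, as is a kernel whose minimum eigenvalue falls below
  −1e-8·n (no silent clipping).
- Kernel normalizers c are computed on the post-T matrices
  (c = tr(T·G·T′)/n); a normalizer at zero (e.g. no heterozygous hybrids)
  is a hard error.
- Allele frequencies p_k come from parent rows only: parents define the
  allele pool, hybrids are deterministic functions of them. Monomorphic
  markers are rejected with a pointer to MAF filtering; missing genotype
  calls are errors (imputation is out of scope).
- Coordinates are 1-based, intervals closed, rows ordered hybrids-then-
  parents everywhere.
- Profiled δ-optimization tolerance 1e-8 on log δ; λ below 1e-12 is
  reported as exactly 0 with σ̂²_h = 0.
- All randomness flows through explicit seeds; replicate streams derive
  from `numpy` SeedSequence spawning. The estimation code is seed-free.

## Known limitations

- **Finite-sample conservatism of the mixture null at desk scale.** At
  n = 200, p = 100 the whitened marker kernel is spiky (its top eigenvalue
  carries ~17% of the trace), the score at δ = 0 is right-skewed, and the
  observed mass at λ = 0 is ≈ 0.64 rather than ½ (empirical size ≈ 0.028
  at nominal 0.05). The effect shrinks as n and p grow (≈ 0.61 at n = 500,
  p = 400) and is expected to be minor at the scales the method targets
  (thousands of hybrids, thousands of markers). The test is conservative,
  never anti-conservative, in all settings examined.
- **Component identifiability at large p.** The AA/AD/DD kernels
  self-average toward near-identity matrices as p grows, so the five
  variance components become weakly separately identifiable (occasionally
  the REML optimum puts the residual component at zero); total genetic
  variance and the per-marker test are unaffected, but individual
  background ratios should not be over-interpreted on dense panels.
- **Power at reduced scale.** When a QTL's heterotic effect is spread over
  many small interactions, the four flexible background components absorb
  much of it during the null fit (their kernels average over all marker
  pairs, including the causal ones), and with only hundreds of hybrids and
  markers the per-marker test rarely clears a genome-wide threshold at
  2.5% PVE. Detection power at that effect size is a property of the full
  scale (thousands of hybrids and markers); desk-scale runs demonstrate
  false-positive control and the mechanics, not power.
- The piecewise heterotic-effect oracle requires strictly inbred parents;
  heterozygous parent calls are rejected rather than imputed.
- A truly monomorphic marker cannot reach the heterosis-kernel stage (it
  is rejected at coding time); the kernel's own degeneracy error triggers
  only when the whole panel carries no heterotic design variation.
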