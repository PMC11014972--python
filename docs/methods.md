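# Methods

## The behavioural model

The ASRT task interleaves a deterministic four-element pattern with
uniformly random trials. Writing `succ` for the pattern successor map (a
fixed-point-free 4-cycle over positions 1–4), a triplet (x, y, z) of
consecutive stimuli is *high-probability* iff `z = succ(x)`; the middle
element is irrelevant. In the stationary alternating stream half of all
triplets end on a pattern trial and land, uniformly, on the 16 high cells,
while the other half spread uniformly over all 64 cells, giving per-cell
long-run frequencies of 5/128 (high) and 1/128 (low) — the 5:1 ratio that
makes the task a statistical-learning instrument. Triplets are defined
within blocks only; the five warm-up trials provide (x, y) context but are
never scored. The analytic taxonomy describes the stationary stream: in a
finite 85-trial block the first scoreable triplet is dropped, which leaves
the pattern phase very slightly unbalanced (9 vs 10 appearances of one
pattern element per block, a ~2.5% relative edge effect on a quarter of
the high cells). The Monte-Carlo cross-check therefore simulates a
continuous alternating stream; the blocked stream is checked on the HIGH
share (0.625), which is phase-balanced.

Implicit learning is scored per subject and block as
`median RT(low) − median RT(high)` over correct, retained trials. Retained
means: not warm-up, a complete triplet exists, not a trill (x-y-x), not a
repetition (x-x-x), and RT ≥ 100 ms, applied with that precedence.
Repetition classification precedes trill so the categories partition.
Incorrect trials stay in the stream as triplet context (the sequence is
defined by stimuli, not responses) but never enter medians. Even-count
medians use the midpoint convention. Missing cells (e.g. an all-error
block) propagate as missing values, never zero.

## The synthetic cohort

The generator emulates the two-study design with known ground truth.
Subject i has random intercept u0 and Block slope u1 (bivariate normal,
SDs 40 ms and 0.5 ms/block, correlation −0.3), latent EF factor(s)
f ~ N(0, I), and an SL gap
`delta_i = mean_gap + rho * sd_gap * f_1 + sqrt(1 − rho²) * sd_gap * eps`,
so corr(f1, delta) = rho by construction. A trial completing a triplet has
expected RT

    base + u0 + (skill + u1)(block − centre) ∓ [delta_i + growth·(block − centre)]/2

(− for high, + for low endings), Gaussian trial noise (SD 80 ms), a 5%
chance of being marked incorrect and a 0.2% chance of an RT replaced by a
Uniform(30, 99) ms fast guess. Defaults mirror the printed study
conditions: Study 1 — 186 subjects, 25 blocks, base 366 ms, skill −0.31
ms/block, gap 3 ms growing 0.14 ms/block; Study 2 — 157 subjects, 45
blocks, base 378 ms, skill −1.12, gap 12.5 ms growing 0.33; rho = −0.15.
The 80 ms trial noise yields a mean-learning-score reliability of ≈ 0.77
at 25 blocks, inside the 0.754–0.791 range reported for the task. The
error and fast-guess rates are conventions (no published values exist);
results are insensitive to them because medians are robust and fast
guesses are filtered.

EF tables are generated at the measure level, `x_j = Σ_k λ_jk f_k +
sqrt(1 − Σ λ²) ε`, using the published varimax loading patterns as
templates (one factor over nine measures, Study-1-like; two factors over
five measures, Study-2-like), then rescaled to plausible task units. The
generator does not model explicit awareness, fatigue, session effects,
non-Gaussian RT tails, or trial-level EF task behaviour — so passing
recovery tests show the chain is consistent, not that real data meet
these assumptions.

## Factor analysis

Factorability uses the anti-image machinery: partial correlations from
the inverse correlation matrix give per-item MSA and the overall KMO;
Bartlett's sphericity statistic is −(n − 1 − (2p + 5)/6) ln|R| on
p(p − 1)/2 df. Factor count comes from Horn's parallel analysis with the
95th-percentile criterion, comparing eigenvalues of the full Pearson
correlation matrix against standard-normal data of the same shape
(PCA-style eigenvalues, chosen for determinism and convention; the
retained count is monotone in the percentile).

ML extraction profiles the loadings out of the normal-theory discrepancy:
for uniquenesses Ψ the conditional optimum over Λ leaves
F(Ψ) = Σ_{j>k} (θ_j − ln θ_j − 1) over the p − k smallest eigenvalues of
Ψ^{-1/2} R Ψ^{-1/2} (Lawley–Maxwell), minimised by L-BFGS-B on log Ψ with
a floor of 0.005 (hitting it is flagged as a Heywood case); a
derivative-free Powell pass backs up rare line-search failures on
ill-conditioned small-sample matrices. The sufficiency statistic is
χ² = (n − 1 − (2p + 5)/6 − 2k/3) F_min on ((p − k)² − (p + k))/2 df — the
Bartlett-corrected form, which reproduces R `factanal` to 4 decimals on a
fixture; other software uses slightly different correction constants, so
third-decimal χ² differences across packages are expected. RMSEA is
sqrt(max(χ² − df, 0)/(df (n − 1))) with a noncentral-χ² confidence
interval by root finding; SRMR is the RMS off-diagonal residual of
R − (ΛΛᵀ + Ψ). Varimax uses Kaiser row normalization; factor columns are
ordered by explained variance with the largest-|λ| loading made positive.
Factor scores are Thomson regression scores, Z R⁻¹ Λ.

A caveat the replicate tests expose: the published two-factor Study-2
loading pattern implies a population correlation matrix whose second
eigenvalue is 1.065 — barely above the noise line — so at n = 157 the
95th-percentile parallel-analysis rule retains the second factor in only
~20% of replicate cohorts. A single sample detecting two factors is
therefore a fragile event under this effect size, and the corresponding
replicate-detection check fails by design rather than by implementation
error; the one-factor Study-1 structure (second population eigenvalue
≈ 1.0, first ≈ 2.0) is detected reliably.

## Trajectory mixed models

Block-wise median RT is modelled with fixed effects
TripletType × Block × EF-score(s) (all interactions), TripletType coded
−1 (low) / +1 (high) so its coefficient is −gap/2, Block and EF scores
mean-centred; random effects are correlated per-subject intercepts and
Block slopes. Numerical REML fitting is statsmodels MixedLM; the default
gradient optimizer can stall on a poor local mode at this outcome scale,
so each structure is fitted with lbfgs and Powell and the best converged
restricted likelihood wins, with a logged simplification ladder
(correlated → uncorrelated → intercept-only) on failure. Fixed-effect
inference is Wald: F = z² on 1 numerator df against a normal reference
(the backend provides no Satterthwaite denominator df; at these sizes the
normal and t references differ negligibly for within-subject terms).
Marginal/conditional R² follow the variance-decomposition convention:
fixed-effect variance over total, adding the random-effect variance
(evaluated over the observed Block design) for the conditional version;
the adjusted ICC is random over random-plus-residual. Simple slopes and
the high-vs-low slope contrast are delta-method linear combinations of
the fixed effects.

One structural property matters for interpretation: the specified random
structure carries no per-subject TripletType effect, yet subjects differ
in their SL gap (SD 10 ms in the generator; certainly nonzero in real
data). Cross-level interaction tests such as TripletType × EF then use an
understated standard error — in null simulations at the generator's
heterogeneity the nominal 5% test rejects ~15% of the time, while with
homogeneous gaps it is correctly calibrated at ~5%. The model structure
is kept as specified (it is the structure used in the field), but
TripletType × EF p-values from it should be read with this
anti-conservativeness in mind; it is a property of the model class, not
of the fitting code.

## Correlation inference

Pearson/Spearman correlations use pairwise-complete data; confidence
intervals are Fisher-z, tanh(atanh r ± z_{1−α/2}/√(n − 3)), and p-values
come from t = r sqrt((n − 2)/(1 − r²)) on n − 2 df. The same machinery on
average ranks serves Spearman, flagged as a large-sample approximation.
Perfectly monotone data (|rho| = 1) short-circuit to a degenerate
interval.

The Bayes factor uses the exact sampling density of r under bivariate
normality (Gaussian-hypergeometric form; verified to integrate to 1) and
a stretched beta prior: ρ = 2B − 1, B ~ Beta(1/κ, 1/κ), so κ = 1 is
uniform on (−1, 1). One-sided alternatives truncate and renormalise the
prior to a half-line. BF = ∫ f(r|ρ) π(ρ) dρ / f(r|0), by adaptive
quadrature with interior breakpoints (needed when tiny κ concentrates the
prior near 0); a 10⁵-point trapezoid oracle and an independent library
implementation agree to ~10⁻⁶ relative. Because the published BFs were
computed from unrounded correlations, recomputation from the printed
three-decimal r can differ in the second decimal (e.g. 1.85 vs 1.88);
the printed values lie inside the BF image of the ±0.0005 rounding
interval of r. Attenuation correction is r/√reliability, clipped into
[−1, 1] with a warning.

## Meta-analysis

Correlations are pooled on the Fisher-z scale with inverse-variance
weights n − 3 (fixed effect). Heterogeneity: Cochran's Q with k − 1 df,
I² = max(0, (Q − df)/Q)·100, and τ² by REML on the z scale via bounded
scalar optimisation, returning the boundary 0 whenever the restricted
profile is monotone near zero — the typical outcome at k = 2, matching a
grid-search oracle elsewhere. Two-sided p-values use the normal on the
pooled z.

## Problem sizes and reproducibility

Every stochastic stage takes a `numpy` Generator or seed; an end-to-end
run writes byte-identical JSON artifacts under a fixed seed (timings are
kept in a separate file). Replicate-based checks use 100–200 replicates;
the type-I simulation uses 40-subject × 10-block cohorts (the size of a
test does not depend on sample size), recovery checks run at the full
186 × 25 Study-1 scale, and EFA loading recovery uses a 10,000-subject
cohort. Tolerances are statistical: 3–4 standard errors for recovered
parameters, 4 Monte-Carlo SEs for frequency cross-checks, and a priori
binomial bands for replicate rates.

## Known limitations

- Learning curves are linear in Block (matching the modelled trajectory);
  no exponential option.
- Spearman intervals are approximate, not exact rank-based.
- Wald inference in the LMM (no Satterthwaite df) and the missing random
  TripletType term (above).
- The meta-analysis module pools correlations only; no random-effects
  pooled estimate, meta-regression, or publication-bias diagnostics.
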