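# Methods

## Data model and shared conventions

Observations are right-censored pairs (T = min(X, Cr), δ = I[X ≤ Cr]) in
two independent groups. All rank-type statistics are computed from the
pooled risk table: at each distinct pooled event time t_j we record pooled
and per-group deaths (d_j, d_{1j}) and at-risk counts (n_j, n_{1j},
n_{2j}), with the convention that a subject censored at t is still at risk
at t (events precede censorings at ties; the censoring-distribution
Kaplan–Meier flips the roles of the indicators). Statistics accumulate
rows only up to τ, the last event time at which both groups retain at
least one subject at risk; rows beyond τ are kept in the table so
estimators and plots show the full follow-up. For the plain log-rank
statistic this truncation is inert (rows past τ have zero
observed-minus-expected and zero variance), but it matters for weighted,
supremum and area statistics.

Kaplan–Meier estimates carry Greenwood pointwise variances; Nelson–Aalen
estimates carry Σ d/n². Left limits Ŝ(t−) are the step value strictly
before t, with Ŝ(t₁−) = 1.

## The test statistics

**Weighted log-rank family.** U = Σ_{j≤τ} W_j (d_{1j} − n_{1j} d_j/n_j),
V = Σ W_j² (n_{1j}/n_j)(1 − n_{1j}/n_j) d_j (n_j − d_j)/(n_j − 1), z = U/√V
with a two-sided normal p-value. Weights: 1 (LR), n_j (GW), √n_j (TW), and
the Fleming–Harrington family Ŝ(t_j−)^ρ (1 − Ŝ(t_j−))^γ with the pooled
KM. Rows with n_j = 1 contribute zero variance. Cross-covariances between
two weighted numerators share the per-row hypergeometric term.

**Combined versatile tests.** With z₁, z₂ the standardized FH(1,0) and
FH(0,1) statistics and ρ̂ their plug-in correlation: SHL1 standardizes the
average, (z₁+z₂)/√(2(1+ρ̂)), two-sided normal; SHL2 = (|z₁|+|z₂|)/2 with
the exact bivariate-normal tail (conditional-normal integral on a 200-node
Gauss–Legendre grid); SHL3 = max(|z₁|,|z₂|) with the bivariate rectangle
probability via Owen's T. At ρ̂ → 1 all three collapse onto the
single-statistic two-sided p (unit test).

**Renyi.** Q = sup_{j≤τ} |U(t_j)| / √V(τ) over the partial sums of the
(weighted) log-rank increments; p-value from the Brownian-motion supremum
law P(sup_{[0,1]}|B| ≥ q), alternating exponential series truncated at
1e−10.

**MKS.** sup_{j≤τ} |Λ̂₁ − Λ̂₂|(t_j) standardized by the terminal
variance and referred to the same Brownian supremum law. The terminal
variance uses the *null-pooled* hypergeometric form
Σ d_j(n_j−d_j)/((n_j−1) n_{1j} n_{2j}) rather than the observed-count form
Σ d_{1j}/n_{1j}² + d_{2j}/n_{2j}²: in small samples the observed-count
estimator is positively correlated with the numerator (more group-1 deaths
inflate both), which self-normalizes the supremum and collapses its tail —
measured null rejection ≈ 0.000 instead of ≈ 0.05. With the pooled form
the null level at 5% is 0.034–0.047 across the benchmark cells, and the
asymptotic p-value tracks a label-permutation oracle of the same statistic
to within ~0.1, always on the conservative side (unit test).

**Censored Cramér–von Mises.** With the time change
x(t) = σ̂²(t)/σ̂²(τ), σ̂²(t) = Σ_{t_j≤t} d_{1j}/n_{1j}² + d_{2j}/n_{2j}²,
and B̂(x) = (Λ̂₁−Λ̂₂)(t)/σ̂(τ): CVM1 = ∫₀¹ B̂² dx (Brownian-motion L²
limit, eigenvalues 1/((k−½)²π²)) and CVM2 = ∫₀¹ (B̂ − xB̂(1))² dx
(Brownian-bridge L², eigenvalues 1/(k²π²)). Integrals are exact sums over
the step grid; tail probabilities come from Imhof's characteristic-
function inversion with the leading 120 eigenvalues exact and the
remaining eigenvalue mass absorbed as a mean shift (the tail variance is
negligible). The implementation reproduces the classical 5% points
(0.4613 for the bridge, 1.6557 for the motion). With the per-group
variance these statistics are conservative in moderate samples — by
design here, since anti-conservativeness is the failure mode to avoid;
the conservativeness is strongest for CVM1 at small n.

**Pepe–Fleming WKM.** √(n₁n₂/n) ∫₀^τ ŵ(t)(Ŝ₁−Ŝ₂) dt with the censoring
weight ŵ = n Ĉ₁Ĉ₂ / (n₁Ĉ₁ + n₂Ĉ₂) (censoring KMs, left limits); with no
censoring ŵ ≡ 1 and the statistic is the scaled area between the curves.
Variance: V = (n₁n₂/n) Σ_{j≤τ} A_j² d_j/(n_{1j}n_{2j}) with A_j the
forward integral ∫_{t_j}^τ ŵ Ŝ_p dt of the weight against the pooled KM —
the martingale plug-in under the null. The normal p-value agrees with a
label-permutation oracle to ~0.01 at n = 50+50 (unit test).

**Maximum WKM (MKM).** Component statistics tilt ŵ by Ŝ_p(t−)^ρ(1−Ŝ_p(t−))^γ
over the ρ,γ ∈ {0,1,2} grid (m = 9); the statistic is the largest absolute
standardized component, calibrated by seeded Monte Carlo from the
multivariate normal with the plug-in correlation matrix (eigenvalue-
clipped to the nearest correlation matrix if needed). A single-cell grid
reproduces the WKM p-value (unit test).

**Lin–Xu areas.** A_i = ∫₀^τ Ŝ_i dt over each arm's own event grid
(rectangle sums). Interval contributions σ_k = sd(Ŝ_i(u_{k−1}))·Δu_k
(Greenwood at the interval's left edge) are combined with a constant
pairwise correlation ρ = 0.5: Var(A_i) = (1−ρ)Σσ² + ρ(Σσ)². The exposed
`rho_cross` supports sensitivity sweeps. Z = (A₁−A₂)/√(VarA₁+VarA₂); LX1
is one-sided on the signed Z (oriented group 1 minus group 2 — its sign
flips under group exchange), LX2 two-sided. The original variance
estimator is not printed in the comparison literature; this reconstruction
reproduces its documented behavior — conservative at low censoring,
monotone type-I inflation with the censoring rate, exceeding nominal at
60% censoring — though the exact magnitude of the inflation at heavy
censoring comes out somewhat smaller than published (≈0.07 vs 0.087 at
n = (20,50), 60%).

**Lin–Wang.** T = Σ_{j≤τ} (d_{1j} − n_{1j}d_j/n_j)², referenced to the
group-label permutation distribution (the risk table is re-derived per
relabelling), which is exact under exchangeability; the original
asymptotic reference law is not reconstructable from the comparison
literature and the permutation null guarantees the level instead.

**Two-stage procedure.** Stage 1 is the log-rank test at level
α₁ = 1 − √(1−α). If it retains, stage 2 evaluates, for every admissible
split k (excluding the first and last rows at or before τ), the
standardized statistic with weight +1 up to k and −1 after, takes the
maximum over k, and calibrates it by label permutation at level α₂ = α₁;
under asymptotic independence of the stages α₁ + (1−α₁)α₂ = α. The
selected split estimates the *hazard*-crossing time, which precedes the
survival-curve crossing (for the middle-crossing preset the theoretical
hazard crossing is t ≈ 1.54 against a survival crossing at t ≈ 3.64; the
median selected time concentrates at the former). The reported
p_overall = 1 − (1−p₁)(1−p₂) (p₁ alone when stage 2 is not run) is a
summary; rejection decisions are per-stage, and the benchmark harness uses
the decision.

**Adaptive Neyman smooth tests.** The log hazard ratio is embedded in d
smooth directions: φ_k = orthonormal shifted Legendre polynomials
(degree 1..d; the constant direction is the log-rank itself) evaluated at
the pooled cumulative-hazard transform. The basis is evaluated at the
*midpoint* of each Nelson–Aalen step, x_j = (Λ̂(t_j) − d_j/(2n_j))/Λ̂(τ):
with right-limit evaluation the null Kolmogorov–Smirnov distance of T₄
from χ²(4) at n = 100+100 is 0.055, with midpoint evaluation 0.023–0.026,
so the midpoint is the package's convention. Scores U_k = Σ φ_k(x_j) e_j
with the hypergeometric per-row variances give Σ and T_d = U'Σ⁻¹U
(pseudo-inverse at rank deficiency). NY1 fixes d = 4; NY2 computes nested
T_d up to d_max = 8 and selects S = argmax_d T_d − (d−d₀)log(#events)
(Schwarz; d₀ = 0, ties toward smaller d), re-running the selection inside
every permutation. Both use permutation p-values
(1 + #{perm ≥ obs})/(B+1), default B = 2000.

## Permutation engine

Relabelling group membership leaves the pooled event grid, pooled counts
and pooled estimators untouched; only (n_{1j}, d_{1j}) change. The
internal engine precomputes subject-by-row at-risk and death indicator
matrices once and obtains all per-permutation counts for a batch of B
relabellings with two matrix products, then evaluates the LW, split-max
and smooth statistics vectorized across the batch (including the
per-permutation τ rule and, for NY2, the per-permutation dimension
selection). This is what keeps 500–2000 permutations per replicate
affordable inside Monte Carlo benchmarks.

## Simulation design

Failure times are drawn by inverse-CDF from exponential, Weibull
(S(t) = exp{−(t/θ)^η}) or piecewise-exponential laws. Censoring times are
U(0, a) with the per-arm limit solving P(C < X) = (1/a)∫₀^a S(t)dt = target
(Brent's method to 1e−6; the limits are unequal across arms whenever the
arms' laws differ, keeping both arms at the same expected censoring rate).
Scenario presets:

| label | arm 1 | arm 2 | crossing S(t*) |
|---|---|---|---|
| null | Exp(0.25) | Exp(0.25) | — |
| A | Exp(0.25) | Exp(0.5) | none (proportional hazards) |
| B | W(0.5, 10) | W(2, 3) | 0.639 (early) |
| C | W(2, 4) | W(0.6, 5) | 0.438 (middle) |
| D | W(3, 3) | W(1, 2.64) | 0.298 (late) |

The null and the censoring model (exponential hazard 0.25; uniform
censoring calibrated to 0/20/40/60%) are fully specified by the study
design this package reproduces. The crossing alternatives are *not*
numerically specified there, so the B/C/D Weibull pairs were chosen once
to satisfy the stated crossing-level bands — B above 0.6, C in [0.4, 0.6],
D in [0.2, 0.4], verified analytically via the closed-form Weibull
crossing point t* = exp[(η₁lnθ₁ − η₂lnθ₂)/(η₁ − η₂)] — with hazard shapes
(one decreasing-hazard arm against one increasing-hazard arm) mimicking
the short-term-benefit/long-term-harm pattern of the motivating clinical
examples. Power comparisons against the published tables are therefore
qualitative (orderings and gaps), not cell-by-cell.

What the generator does not emulate: covariate-dependent or non-uniform
censoring, ties (times are continuous), left truncation, competing risks.
Passing benchmarks therefore say nothing about robustness to informative
censoring or heavily tied registry data.

## Monte Carlo harness

One master seed spawns an independent `SeedSequence` stream per replicate
(one child for data, one for test-internal randomness), so results are
bit-identical across runs and independent of evaluation order; replicates
are processed sequentially. A replicate on which a test reports a
degenerate variance (e.g., no events in a truncated table) counts as a
non-rejection — an uninformative sample cannot reject — and is tallied.
Inside benchmarks the permutation tests default to 500 permutations
(documented reduction from the 2000 used for one-off analyses; a flag
restores the full budget). Problem sizes in the shipped acceptance runs:
5000 replicates for closed-form type-I cells, 1000 replicates × 500
permutations for permutation-test levels, 1000 replicates × 300
permutations for power orderings, 2000 replicates for the χ²(4) law check.

## Numerical choices and degenerate inputs

* Zero-variance statistics return p = 1 with a `degenerate` flag rather
  than raising; batch reports isolate per-test failures.
* Rows with n_j = 1 contribute zero hypergeometric variance.
* Permutation p-values use the add-one form (1 + #{≥})/(B + 1), which is
  valid by construction.
* The MKM correlation matrix is repaired by eigenvalue clipping when the
  plug-in estimate is not positive definite.
* Ties across groups pool into one risk-table row; ties between events
  and censorings follow the events-first convention.
* All areas/integrals are exact step-function sums; no quadrature error
  enters any statistic (quadrature appears only in reference-law
  evaluations and censoring calibration).

## Known limitations

* The MKS and Lin–Xu constructions are reconstructions of methods whose
  exact published scalings are unavailable; both are validated
  behaviorally (permutation-oracle agreement, null-level patterns), and
  their single-dataset statistics should not be expected to match other
  software to the digit.
* CVM1/CVM2 are noticeably conservative below n ≈ 50 per arm.
* Asymptotic p-values for the weighted log-rank family are normal
  approximations; at pooled n ≤ 8 they differ from the exact permutation
  law by up to ~0.1.
* Two groups only; no stratification, left truncation or competing risks.
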