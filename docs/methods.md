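# Methods

This note records the mathematical content of the package, the numerical
choices behind it, and what the validation suite does and does not
demonstrate.

## Models and nondimensionalisation

Both model families describe a promoter switching between an inactive (off)
and active (on) state.  Time is measured in protein lifetimes, i.e. all
rates are divided by the protein decay rate.

**Model A** (one stage): switching rates κ_f (on) and κ_b (off),
production at rate λ while on, protein decay at unit rate.  Feedback adds a
copy-number-proportional term to a switching propensity: autoactivation
adds δα·n to the on-switch, autorepression adds δρ·n to the off-switch.
The factorisation of the feedback rate into δ·(Greek coefficient) is a
convention; only the product enters the equations, so the package stores
the whole scaled strength in δ and fixes the coefficient at 1.

**Model B** (two stage): switching rates κ₀, κ₁; transcription λ while on;
mRNA decay γ = 1/ε; translation at rate γμ per mRNA; protein decay at unit
rate.  ε < 1 encodes the fact that mRNA turns over faster than protein —
the regime documented for many microbial genes — and μ is the mean number
of proteins per mRNA lifetime (burst size).  Four feedback channels add
δ·(coefficient)·(m or n) to a switching propensity.

The promoter state at the start of an interval is not observed; the
package introduces χ, the probability that the promoter is off at time
zero given the observed counts.  The default ("markov") closes this by the
promoter's own jump-rate balance at the observed state,
χ = down/(up + down), with the feedback contributions evaluated at the
initial copy numbers; this makes χ a rational function of δ whose
geometric δ-series the generating-function expansion consumes.  χ can also
be fixed by the user or supplied as an explicit series; marginalising over
χ, or inferring it, is left to downstream inference code.  When both
switching propensities vanish the promoter state is undefined and the
package raises rather than guessing.

## Model A generating functions

With v = z − 1, the generating-function pair (F⁽⁰⁾, F⁽¹⁾) obeys a
transport equation whose characteristics are v = v₀eˢ.  On a
characteristic, each δ-order obeys a linear ODE pair; in the variable
w = λv₀eˢ the homogeneous second-order forms are Kummer equations.

*Leading order.*  Each component is expanded in its own Kummer basis
(M(κ_f, 1+K, w), e^{−Ks}M(−κ_b, 1−K, w)) and
(M(1+κ_f, 1+K, w), e^{−Ks}M(1−κ_b, 1−K, w)), K = κ_f + κ_b.  The two free
constants per component are obtained by solving the 2×2 linear system
given by the value and slope of the initial condition at s = 0 (the slope
follows from the ODE system itself), rather than by transcribing printed
closed forms.  This has three advantages: it provably satisfies the
initial data, it involves no division by κ_f or κ_b (so the
immigration-death limits κ_b → 0 and κ_f → 0 need no special casing), and
writing the second basis function with e^{−Ks} instead of w^{−K} removes
all fractional powers — the representation is entire in v₀ and
branch-safe on any contour.  The assembled leading order is the exact
generating function of the unregulated telegraph CME; the test suite
checks it against the master equation to solver precision and against a
direct ODE integration of the characteristic system.

*First order in δ.*  The correction solves the same linear system with a
source R(s) = (feedback coeff)·(v₀ + e^{−s})·∂F/∂v₀ of the leading order.
∂/∂v₀ of the leading order is computed analytically by differentiating the
2×2 constant system (c' = A⁻¹(b' − A'c)) together with the Kummer
parameter-shift rule M'(a,b,·) = (a/b)M(a+1,b+1,·).  (Complex-step
differentiation was considered and rejected: it is only machine-exact at
real base points, and v₀ is complex on the contour.)  Two independent
routes produce the correction:

* **quadrature** — variation of constants.  The particular solution is
  taken to vanish at s = 0 (lower integration limits at w(0) = λv₀), the
  integrals are evaluated by Gauss–Legendre quadrature along the ray in w
  (on which all power ratios are real and positive, so no branch
  ambiguity arises), and the two homogeneous constants are then fixed by
  the first-order initial conditions — again a 2×2 solve with the same
  matrix as the leading order.
* **ode** — direct numerical integration of the first-order
  characteristic system with the analytic source (DOP853,
  rtol 1e-10).

The routes agree to ~1e-8 relative or better on random contour points;
quadrature is the default and falls back to the ODE route on
ill-conditioned inputs.  The δ-expansion is capped at first order; the
remainder is O(δ²), which the validation ladder confirms with a log-log
slope ≈ 1.9 over δ ∈ {0.1, 0.05, 0.025}.

*Degenerate parameters.*  When K = κ_f + κ_b sits within 1e-6 of a
positive integer the second Kummer parameter 1 − K is a non-positive
integer and the basis degenerates.  The solution is continuous in the
rates, so the package nudges κ_f (or κ_b) by a relative 1e-8 and logs it.
Consequence: results near integer K carry an O(1e-8) parameter-nudge
error, which the test tolerances account for.

## Model B generating functions

With u = w − 1, v = z − 1 the characteristic system is
εu̇ = u − μv(u+1), v̇ = v — a slow-fast system with repelling critical
manifold u = c₀(v) = μv/(1−μv).  On the fast time σ = s/ε the
characteristic and the generating functions are expanded in ε.  All
expansion coefficients are exponential polynomials in σ with the single
rate q = 1 − μv₀; the package manipulates them exactly with a tiny
exp-polynomial algebra (closed under +, ×, d/dσ, ∫dσ), so no quadrature
error enters the hierarchy.

The free constants of the hierarchy are fixed by the χ-split initial data
at σ = 0 (this requires κ₁ > 0, which divides the on-component).  The
inverse characteristic transform supplies the base point: v₀ = ve^{−t}
exactly, and u₀ from the ε-series inverse of the fast flow (orders 0 and
1).  At ε-order 0 the composition collapses to a closed form — protein
thinned binomially, mRNA relaxing to its quasi-steady value 1/(1−μv) at
rate (1−μv)/ε — which the implementation reproduces to machine precision
and which also yields the pure-death binomial marginal for m₀ = 0.

*Expansion depth.*  The off-component is carried to O(ε²) and the
on-component to O(ε) — the depth at which the hierarchy closes with the
five initial-condition constants.  `eps_order` selects the truncation; the
on-component always lags the requested order by at most one.

*Validity domain — important.*  The fast-time expansion is a
boundary-layer expansion around the frozen-base-point flow, whose
deviation from the critical manifold grows like e^{qσ}.  On the inversion
contour Re q ≥ 1, and the base point delivered by the (exact or series)
inverse transform sits an O(ε) distance from the critical manifold (the
slow manifold's offset), so the composed first- and second-order terms
contain contributions of size ε·e^{t/ε}: they converge beautifully at
fixed σ (measured slopes 1.5–2.3 in ε) but *diverge* at fixed t as
ε → 0.  This is an intrinsic property of composing the inner expansion
with the inverse transform, not an implementation artifact — we verified
it by evaluating the hierarchy with the exact (incomplete-Gamma) backward
characteristic and against two independent oracles.  A classical
Poincaré-type argument that polynomially secular expansions retain
accuracy on σ = O(1/ε) intervals does not apply here because the secular
growth is exponential.  Practical guidance: use the analytic model-B
propagators for sampling intervals up to a few mRNA lifetimes
(σ = t/ε ≲ 3); the library warns when an evaluation leaves this regime,
and the FSP engine covers longer intervals.  The acceptance suite reports
the ε-ladder both at fixed t = 1 (where the error grows, recorded
honestly) and at fixed σ = 2 (where it converges with slope ≈ 1.6).
Uniform (composite) slow-manifold evaluation would remove the
restriction but is deliberately out of scope, consistent with treating
the backward-flow sensitivity as a reason to avoid slow-segment
expansions altogether.

*Autoregulation.*  Weak feedback adds a copy-number operator (w∂_w or
z∂_z acting on the off- or on-component) as a source at each δ-order.
The operators are transported to characteristic coordinates —
w∂_w = (1+u)(∂u/∂u₀)⁻¹∂_{u₀}, and the two-term analogue for z∂_z — and
expanded in ε; the resulting source coefficients G_n are exp-polynomials
built from the analytic u₀- and v₀-derivatives of the δ⁰ hierarchy.  The
δ¹ coefficients are then obtained by directly integrating the first-order
characteristic system order by order in ε (equivalent to the second-order
forms, but uniform across all four feedback channels).  Depth: δ ≤ 1,
ε ≤ 1.  Validation is by FSP δ-response: the analytic feedback response
[P(δ) − P(0)] matches the master equation's to within 15% of the response
size at ε = 0.02, and the paired-difference ladder (which cancels the
δ-independent ε-truncation error; the feedback term's own ε-error is
linear in δ, hence the small ε) shows the O(δ²) remainder with slope
≈ 1.85 at ε = 0.01, σ = 1, m₀ = 4.

## Kummer functions

M(a, b, x) is evaluated by Taylor series with the Kummer transformation
e^x·M(b−a, b, −x) applied for Re x < 0 so the dominant exponential sits in
a prefactor.  Cancellation is monitored (largest partial term vs result);
entries estimated to lose more than ~4 significant digits are recomputed
with mpmath at elevated precision.  Worst-case relative error measured
against 40-digit arithmetic over the parameter/argument box used by the
package: ~1e-12.

## Cauchy inversion

P_n is the n-th Taylor coefficient of F, computed as a trapezoidal
discretisation of the Cauchy integral on a circle — identically the DFT
of the contour samples (asserted bit-level in the tests).  Node count
defaults to the smallest power of two ≥ max(64, 4(n_max+1)); accuracy is
spectral for functions holomorphic beyond the contour.  Default radii:
unit circle for model A (the generating function is entire; radius
invariance is tested over r ∈ {0.8, 1, 1.2}); for model B the protein
radius is min(1, 0.75(1 + 1/μ)) to respect the generating function's pole
at z = 1 + 1/μ, and contour points within 1e-8 of the pole raise a
configuration error rather than being silently regularised.  Inverted
tables report total mass, the largest residual imaginary part and any
negative entries; tiny negatives are a diagnostic of expansion error and
are only clipped/renormalised on explicit request.

## Oracles

*FSP*: the master equation truncated to a copy-number box (default
initial-state + 10·mean + 10·√mean margins) and integrated with a sparse
Krylov matrix exponential; tail mass > 1e-10 triggers one box enlargement,
then an error.  All feedback channels enter at full propensity.
*SSA*: Gillespie's direct method vectorised across paths, reproducible
from a single seed, with pre-jump checkpointing at the record times.
*Closed forms*: immigration-death Poisson and pure-death binomial pmfs.

The synthetic time-series generator draws one SSA path sampled on a
regular grid and keeps protein counts only, mimicking the structure (not
the noise model) of fluorescence time-lapse data: no measurement error,
no cell division, no extrinsic rate fluctuations, perfectly regular
sampling.  Passing likelihood tests therefore demonstrates correctness of
the propagator arithmetic on model-generated data, not robustness to
real-data artefacts.

## Likelihood

The transition log-likelihood computes one propagator row per distinct
observed initial count (cached per parameters/interval/contour) and sums
log P over transitions.  Probabilities are floored at 1e-300 before the
log, with underflows counted.  For model B only protein is observed; the
unobserved initial mRNA is fixed to a user-supplied m₀ (default 0) — the
natural alternative, averaging over an m₀ distribution, is exposed at the
API level by calling the propagator with several m₀ values.  χ is
re-evaluated from each interval's initial state in markov mode.  A row
with negative mass below −1e-6 raises an expansion-accuracy error that
recommends smaller δ/ε or the FSP engine.

## Problem sizes in the validation suite

Chosen as the smallest sizes that make each check meaningful: propagator
grids of ≤ 3 rate sets × 3 initial states × 3 times; contour inversions
up to ~160 coefficients (model A) and 18×31 joint tables (model B);
convergence ladders of 3 points with log-log slope fits; 10⁴ SSA paths
against a 3·√(K/paths) total-variation bound; 20-sample likelihood
series.  The full suite runs in a few minutes.
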