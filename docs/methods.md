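# Methods

## Model class

`vbsa` analyzes deterministic, well-stirred mass-action reaction systems:
N species with concentrations q(t) (molecules/cell) and M reversible
reactions with forward/reverse rate constants κ_f,m, κ_r,m (s⁻¹),

    dq_n/dt = Σ_m (ν′_nm − ν_nm) ρ_m,
    ρ_m = κ_f,m Π_n q_n^ν_nm − κ_r,m Π_n q_n^ν′_nm.

Integration uses LSODA (stiff/non-stiff switching) through
`scipy.integrate.odeint` with an analytic Jacobian; both the right-hand
side and Jacobian are numba-compiled because a sensitivity run performs
10³–10⁵ integrations.  Default tolerances are rtol 1e−8 / atol 1e−10 on a
uniform 1201-point output grid over a 6-hour window (t_max = 21600 s) —
tight enough that trajectory error is negligible against the trapezoidal
error of the response integrals.  Output undershoots below zero at the
tolerance level are clipped; larger negativity aborts with an integration
error rather than silently propagating.

## Thermodynamically consistent perturbations

The uncertain inputs are standard chemical potentials, expressed in k_BT
units so the perturbation scale λ is dimensionless.  In Eyring–Polanyi
form a rate constant is exponential in (potential differences), so a
Gaussian perturbation w enters the log-rate linearly:

- **ROSA** (reaction-oriented; J = M): perturbing the activated complex of
  reaction m by w_m raises its barrier in both directions,
  K_f = κ_f e^{−w_m}, K_r = κ_r e^{−w_m}.  Equilibrium constants are
  exactly invariant — detailed balance holds for every realization.
  A ±λ excursion moves rates within 100[e^{−λ}−1, e^{λ}−1]%, e.g.
  (−9.52%, +10.52%) at λ = 0.1 and (−32.97%, +49.18%) at λ = 0.4.
- **SOSA** (species-oriented; J = N): perturbing species n by w_n
  destabilizes it, multiplying the rate of every elementary direction that
  consumes it by e^{ν w_n}: K_f = κ_f e^{Σν_nm w_n},
  K_r = κ_r e^{Σν′_nm w_n}.  ln(K_f/K_r) then shifts by exactly the
  reaction free-energy shift Σ(ν−ν′)w, and Wegscheider cycle conditions
  are preserved (tested on a three-reaction cycle).

Factors are independent zero-mean Gaussians; by default homogeneous
(λ_j = λ for all j), but `FactorSpace` stores a full vector so
heterogeneous uncertainty is available.  Correlated or non-Gaussian
factors are out of scope.

## Response characteristics

For the output species' transient q(t), with t0 the convergence time
(first grid time after the global maximum where q stays below ε·max q
through t_max; t_max if never; ε = 1e−3 of the maximum — an absolute
threshold would be scale-dependent), and moments T_k = ∫₀^{t0} t^k q dt
(composite trapezoid on the stored grid; no re-solving inside response
functionals):

    I = T₀ (integrated response), τ = T₁/T₀,
    D = √(T₂/T₀ − τ²) (duration), S = I/(2D) (strength).

These are the established moment-based signaling measures (integrated
activity, temporal width, area-per-width amplitude); the identity
S·2D = I holds by construction.  An alternative convention (D = t0,
S = I/D) is kept behind the `response_defs` switch so other definitions
can be dropped in without touching any estimator.  Analyses use
R = ln D, ln I, or ln S; the log tames outliers under large rate
perturbations and makes the duration response near-additive in practice.

## Variance decomposition and indices

The ANOVA (Sobol) decomposition of Var[R(W)] is truncated at pairs:
V = ΣV_j + Σ_{j<j′}V_jj′ with V_j = Var[E[R|W_j]] and
V_jj′ = Var[E[R|W_j,W_j′]] − V_j − V_j′.  SESI σ_j = V_j/V and JESI
η_j = Σ_{j′≠j}V_jj′/V; since each pair feeds two JESIs,
Σσ + ½Ση = 1 (asserted to 1e−10 for every estimator output).
Negative sampling estimates are clamped to zero for index computation
(raw values and a clamp mask are retained in metadata).  Classification
against a threshold θ = 0.10 uses strict ≥ at the boundary (published
tables are integer-truncated, so the boundary convention is unobservable
there; ≥ is the natural closed rule).  The table renderer truncates
percentages toward zero and applies a separate 5% display floor keyed to
a reference method; display floor and decision threshold are independent.

## The five estimators

All estimators count system evaluations exactly; no point is evaluated
twice, and the counts equal the closed-form budgets for every J
(asserted at J = 21 and 23).

**MC** — Saltelli-style double-matrix design on Latin hypercube samples:
two independent LHS matrices A, B and the column-swapped hybrids A_B^(j),
B_A^(j), 2L(J+1) evaluations.  The shared-coordinate correlation
identities of this design (E[R(B)R(A_B^(j))] = f0² + V_j, etc.) are
evaluated in centered difference form, V̂_j = ⟨c(B)[c(A_B^(j)) − c(A)]⟩
and V̂_jj′ = ⟨[c(B_A^(j)) − c(B)][c(A_B^(j′)) − c(A)]⟩ with c = R − f0,
each averaged with the A/B roles swapped.  The differences cancel the
lower-order effects of the shared coordinates sample-by-sample, so the
estimator noise scales with the effect sizes rather than with E[R]² —
the raw product form is unusable for log-responses, whose mean (≈6) dwarfs
their standard deviation (≈0.1).  Error decays as O(L^{−1/2}) (measured
slope ≈ −0.43 over L = 500…8000).

**DA** — second-order Taylor surrogate at w = 0 with symmetric finite
differences, Δ = 0.1 (configurable).  Axis stencils use five points
(0, ±Δ, ±2Δ), pairs the four-point cross stencil — the only symmetric
design consistent with the 2J(J+1)+1 budget, and degree-4 exact, which
removes the leading stencil error on quartics.  Gaussian moments give
V_j = g_j²λ² + ½h_jj²λ⁴, V_jj′ = h_jj′²λ²λ′².  DA is structurally blind
to interactions beyond the bilinear term (e.g. w₁w₂² contributes a third
derivative it never samples); the suite documents this failure mode.

**PA** — cut-polynomial surrogate: per-factor quadratics fitted by least
squares at ±1σ, ±2σ (S = 4 points), per-pair cross terms
α^{(κ,κ′)}w^κ w′^κ′ (κ, κ′ ∈ {1,2}) fitted on the S×S pair grids;
budget J(J−1)S²/2 + JS + 1.

**GHI** — exact cut-HDMR components anchored at w = 0, tabulated on
probabilists' Gauss–Hermite nodes scaled by λ_j (order Q = 5 default);
all expectations by Q-point quadrature.  Odd-Q rules have a zero node,
which reuses the center and axis evaluations — that node-sharing is what
produces the 2J(J−1)⌊Q/2⌋² + 2J⌊Q/2⌋ + 1 budget.

For PA and GHI the surrogate's cut components vanish on the axes but are
*not* orthogonal under the Gaussian measure, so pair components leak into
one-factor conditional means.  V_j and V_jj′ are therefore always
computed as Var[E[R̃|W_j]] and Var[E[R̃|W_j,W_j′]] − V_j − V_j′ of the
surrogate (for polynomial surrogates, via the exact orthonormal-Hermite
re-expansion; for GHI, by nested quadrature of conditional means).  This
reconstruction reduces to the DA formulas for the Taylor surrogate and is
validated against a brute-force tensor-quadrature oracle.

**OHA** — global polynomial-chaos surrogate: least-squares regression of
R on the orthonormal Hermite basis {1, ψ₁(x_j), ψ₂(x_j),
ψ_k(x_j)ψ_k′(x_j′)} of standardized factors x = w/λ, on L LHS samples
(L = 6000 default; condition-number guard at 1e8).  Orthonormality makes
the variance terms plain sums of squared coefficients.  Whether the pair
block includes ψ₂ψ₂ is exposed as `oha_pair_degree` (default 2, i.e.
included, mirroring PA's cross terms).

## Verification harness

- Closed-form families: quadratic (exact second-order ANOVA, nothing
  higher), additive, pure-interaction, and product-exponential
  exp(Σa_jw_j) whose every ANOVA subset has a closed form — the
  nonadditive stress case.  Each closed form is cross-checked against the
  tensor-quadrature oracle (full Q^J grid, inclusion–exclusion; default
  Q = 30, J ≤ 4).
- On random quadratics, DA/PA/GHI/noiseless-OHA reproduce (V_j, V_jj′) to
  1e−6 of scale or better (DA to 1e−8: its stencils are exact there).
- Product-exponential (J=2, a=0.5): GHI(Q=5) reproduces V_j = 0.46828,
  V₁₂ = 0.13300 to 1e−3 relative.  OHA at L = 20000 carries a ≈ −1.9%
  truncation bias (the degree-2 Hermite span misses ψ₃-and-higher mass);
  its V_j and second-order portion V sit within 2% of the closed form.
  The pair term V₁₂ alone fluctuates more (seed s.d. ≈ 3% at L = 20000:
  the empirical ψ₂ψ₂′·R cross-moment has a heavy-tailed integrand), which
  is an intrinsic property of the regression estimator at that sample
  size, not an implementation artifact.

## Synthetic cascade fixture

The end-to-end testbed is a three-tier phosphorylation cascade in the
style of MAPK models: an input kinase activated by a decaying signal,
then two double-phosphorylation cycles with distributive
kinase/phosphatase mechanisms (explicit enzyme–substrate complexes), and
a signal-inactivation step — exactly M = 21 reversible reactions and
N = 23 species at three tiers, matching the scale of the published
cascade study.  Base rates (association 1e−3, dissociation 0.1, catalysis
0.1, catalytic reverse 1e−6, signal decay 2e−3; initial pools 30–300
molecules/cell) are jittered by exp(U(−0.3, 0.3)) under a seed, and the
nominal output ("ERK-PP") is asserted to be a transient pulse within the
6-hour window; non-pulsing draws are rejected (next substream, ≤10
attempts).  The fastest/slowest rate ratio stays ≤ 1e4, stiff but well
inside LSODA's comfort zone at the default tolerances.

What the fixture does *not* emulate: the published supplementary
parameter values (the real MAPK fixture loader raises
`FixtureUnavailableError` until a transcription is added under
`vbsa/data/mapk_cascade.yaml`), receptor-level detail, conservation
breaking by synthesis/degradation of enzymes, and experimentally
calibrated time scales.  Passing end-to-end tests therefore demonstrate
method agreement on a realistic cascade topology and stiffness, not
reproduction of the published table values.

## Problem sizes and numerical choices in the test suite

The end-to-end comparison runs all five estimators on the cascade (ROSA,
λ = 0.1, log-duration) with MC at L = 2000 as reference — about 9×10⁴
stiff ODE solves, the dominant cost of the suite.  For that comparison
the solver runs at rtol 1e−6 / atol 1e−8 on a 601-point grid: solver
error enters the indices only through ratios of variances and is two
orders below the 5-percentage-point comparison tolerance, while the cost
halves.  All defaults elsewhere remain 1e−8/1e−10 and 1201 points.
Every stochastic component (LHS permutations, MC matrices, OHA designs,
fixture jitter) derives from a single integer seed through
`numpy.random.SeedSequence` substreams, so runs are bit-reproducible
given the seed and library versions.

## Known limitations

- Second-order truncation: all indices ignore ANOVA terms of order ≥ 3;
  under large perturbations (λ ≳ 0.3) of strongly nonadditive responses
  those terms are not negligible and all five estimators inherit the
  truncation (the product-exponential family quantifies this exactly).
- DA degrades first under nonadditivity (see above); OHA degrades last.
- The MC pair estimator needs large L for small interactions; clamping
  makes small-JESI estimates biased upward at finite L.
- No SBML/CellML import, no stochastic kinetics, no events/delays.
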