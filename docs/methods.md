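# Methods

## Model class and scope

`loopchar` analyses ODE models of regulatory networks in the form
ẋᵢ = dᵢ(fᵢ(x) − xᵢ): every species decays linearly at a strictly positive
rate dᵢ and is produced at rate dᵢfᵢ, with fᵢ a composition (sums and
products) of bounded, monotone regulation functions of *other* species.
Direct self-regulation (∂fᵢ/∂xᵢ ≠ 0) is rejected at network construction,
because the loop expansion of the characteristic polynomial assumes a zero
production diagonal; extending the expansion to self-edges is out of scope.
Models that do not fit this form — the dimeric auto-repressor, whose
mass-action dimerisation couples species nonlinearly outside the d(f − x)
pattern — are carried as raw right-hand sides with a user-supplied analytic
Jacobian (finite differences with step 1e−7·(1+|x|) as fallback). Delay,
spatial, compartmental and stochastic models are out of scope, as is
classifying crossings as sub- or super-critical.

## Loop expansion of the characteristic polynomial

At a steady state x*, stability is governed by det(λI − J) with
J = D(∂f/∂x − I), D = diag(d). Expanding the determinant by permutations
and noting that a permutation contributes only if its moving points form
vertex-disjoint cycles of the regulation graph gives, after dividing by
∏ⱼdⱼ,

    P(λ) = Σ_S (−1)^{l_S} H_S ∏_{j∉S} (1 + λ/dⱼ),

summed over all sets S of pairwise vertex-disjoint feedback loops
(empty set included, H_∅ = 1); H_S is the product of production gradients
∂fⱼ/∂x_pred around the member loops. The implementation enumerates simple
cycles with networkx (Johnson's algorithm), canonicalises each cycle to
start at its smallest vertex, and enumerates disjoint subsets by
backtracking over loops ordered by minimum vertex — adequate for the n ≤ 12
networks this tool targets. Coefficients are assembled with numpy
polynomial arithmetic; the independent oracle `characteristic_direct`
computes det(λI − J) from the Jacobian (numpy.poly) under the same
normalisation, and the two constructions are compared coefficientwise on
100 random signed Hill networks in the tests.

## Hopf conditions and angle geometry

Setting λ = iα and θⱼ = arctan(α/dⱼ) ∈ [0, π/2) converts each factor
(1 + iα/dⱼ) into sec θⱼ e^{iθⱼ}. For a single negative ring of gain F the
crossing with minimal |F| satisfies Σθⱼ = π and |F| = ∏ sec θⱼ; the angle
sum is monotone in α, so the solve is a bracketed scalar root find
(tolerance ~1e−14). For n ≤ 2 the sum cannot reach π and no crossing
exists.

With one sub-loop W of gain G, the degradation rates are taken equal inside
W (angle θ) and equal outside (angle φ) — the characteristic equation
cannot distinguish species within the same loops, so the optimum inherits
this symmetry. The crossing satisfies

    π = (n−|W|)φ + Arg(−G + (1 + i tanθ)^{|W|}),
    |F| = sec^{n−|W|}φ · |−G + (1 + i tanθ)^{|W|}|.

`subloop_phi` solves the first relation by direct complex phase evaluation
(numerically robust where the tangent form has poles) and asserts
consistency with the tangent form; `subloop_threshold` evaluates both the
modulus form and the sine-rule form and asserts their agreement at 1e−10.
A zero-frequency (α → 0) crossing exists only for G > 1, where the
sub-loop block 1 − G is already negative at θ = 0.

For n = 3, |W| = 2 the threshold reduces to the closed form
|F| = 4 + 2/λ + 2λ(1−G) in the rate ratio λ = d_in/d_out = tanφ/tanθ, with
branch structure:

- G < 1: attained minimum 4(1+√(1−G)) at λ* = 1/√(1−G);
- G = 1: infimum 4 as λ → ∞ (boundary case, flagged unattained);
- G > 1: |F| is decreasing on the admissible interval λ < 2/(G−1), so the
  infimum G−1 at λ → 2/(G−1) is reported with `attained=False` — the
  limiting crossing has α → 0 and is degenerate.

`optimize_subloop` minimises the general-(n, w) threshold over θ by
multi-start bounded scalar minimisation (20 uniform subintervals of
(0, π/2), xatol 1e−12; a finite sentinel value marks θ with no admissible
crossing). The stationarity relation used to validate optima is derived
from d ln|F|/dθ = 0 along the crossing constraint:
tanφ = (sinθ + G cos^w θ sin((w−1)θ)) / (cosθ − G cos^w θ cos((w−1)θ)).
At small |G| this gives θ ≈ φ ≈ π/n, recovering the equal-rate ring
optimum. The very-large-|G| asymptotics are covered only by qualitative
tests.

A note on direction: at equal rates the crossing threshold is 8 − 2G, so a
positive sub-loop *lowers* both the angle sum and the required ring gain,
and a negative sub-loop raises them; this is the direction all the derived
crossovers (optimum near G slightly above 1, parity with the plain ring at
G = 9) rely on, and it is verified by eigenvalue oracles on a G grid.

## The dimeric auto-repressor

The three-species model (dimer a, mRNA b, monomer c)

    ȧ = kc² − la − d_a a,
    ḃ = d_b(f(a) − b),
    ċ = d_c(g(b) − c) + 2la − 2kc²,

with decreasing f and increasing g has a unique steady state satisfying
kc*² = (l + d_a)a* and b* = f(a*); the package solves the remaining scalar
equation for c* by bracketed root finding on [0, sup g]. Writing kc* for
k·c*, the imaginary and real parts of the characteristic equation at λ = iα
give

    α² = d_a d_b + d_b d_c + d_c d_a + l(d_c + d_b) + 4kc*(d_a + d_b),

and a threshold on |f′g′| that depends on d_b only through d_b + C/d_b with
C = d_a d_c + l d_c + 4kc*d_a, hence the optimal mRNA rate d_b* = √C. In
the stable-dimer limit l, d_a → 0 the threshold becomes
(2d_c/4kc*)(1 + 4kc*/d_c)², minimised at 8 when d_c = 4kc* — at the
optimum, one in three monomers dimerises and the others degrade. The
crossing frequency then reduces to √(2 d_b d_c), giving the 111-minute
Hes1 period estimate at d_b = d_c = 1/25 min⁻¹. An equivalent three-angle
formulation (effective rates l+d_a, d_b, d_c+4kc* and sub-loop gain
G = 4kc*l/[(d_a+l)(d_c+4kc*)]) is implemented as an independent route and
tested to agree with the direct threshold at 1e−9 relative on random
parameter draws.

The packaged worked configuration uses the piecewise-linear repression
f (value f_max below a = 0.9, zero above 1.1, slope −5f_max between) with
f_max = 1, g(b) = 5b, l = d_a = 0.1, d_b = 3, k = 25. Bisection on the real
part of the complex eigenvalue pair locates its two crossings in d_c at
1.3279 and 86.772; the same values solve threshold(d_c) = |f′g′| = 25, and
the simulated oscillating band has its onset and cessation at exactly these
points. These are the values the package reports.

## Four-species linked repressilators

Two three-species negative loops sharing a positive two-species loop (b, c)
admit a symmetric reduction when the negative-loop coefficients are equal:
d_b = d_c = 1 (time units), d_a = d_d = δ, and L the ratio of negative- to
positive-loop coefficients. Splitting the quartic characteristic equation
into its two square-root branches and taking imaginary parts gives the
crossing condition h_b g_c = (δ+1)² with α² = δ(L + Lδ − δ); negative α²
means no crossing. In dimensional terms the frequency scales with
√(d_b d_c); the package works in the scaled units and documents this
restoration explicitly rather than fixing one dimensional convention. The
oracle instantiates a concrete Jacobian with h_b = g_c = −(δ+1),
f′ = j′ = −1, h_a = g_d = −L(δ+1) and checks the eigenvalue pair sits on
the axis. The concrete Hill-4 example network has five steady states
(found by multi-start search) and oscillates in simulation at small δ,
ceasing at large δ where the positive loop dominates as a bistable switch.

## Steady states

Fixed points solve f(x) = x (or rhs = 0 for raw models). The search runs
MINPACK's hybrid method (scipy.optimize.root) from a Latin-hypercube sample
of [0, x_max] per species, with x_max = sup fᵢ where finite — any fixed
point of the d(f − x) form must satisfy xᵢ* ≤ sup fᵢ — and 10 otherwise.
Roots are accepted at residual max-norm < 1e−9, deduplicated at 1e−6
max-norm, sorted by species values, and reported with their residual;
components meaningfully negative (< −1e−8) are discarded as unphysical
(even-power Hill kinetics admit mirror-image negative roots). The default
200 starts find all five steady states of the four-species example across
seeds; the count-5 result is tied to this search box and start budget.
Results are bit-for-bit reproducible for a fixed seed. Concentrations are
never clipped during root finding — only simulation initial conditions are
clipped at zero.

## Simulation and oscillation metrics

Integration uses scipy's LSODA (stiff-capable, dense output) at
rtol 1e−8/atol 1e−10, resampled on a uniform grid (default dt 0.05) so
amplitude and period extraction are independent of adaptive step placement.
Piecewise-linear kinks are integrated through (the RHS is continuous);
only Jacobian-based analysis refuses breakpoints, with an error naming the
species. Amplitude is max − min of the observed species over the window
[500, 1000]; the period is the mean spacing of upward mean-crossings —
with k crossing timepoints the divisor is k − 1 (the number of whole
cycles between the first and last crossing; dividing by k would
overestimate the frequency by one interval).

Sweeps integrate once per parameter value from the model's fixed standard
initial condition and classify `oscillating` as amplitude > 1e−3
(configurable). Because trajectories just below a bifurcation can carry
slowly decaying transients through the window, a second flag `sustained`
additionally requires the second half-window amplitude to exceed the
threshold and at least half the first half-window amplitude; this
separates limit cycles from decaying ringing (visible in the ring+sub-loop
model just below G = 0, where onset is analytically exactly at G = 0) and
is the flag band-location checks use. The ring+sub-loop example assumes
equal unit degradation rates, consistent with that analytic onset.

## Numerical conventions and limitations

- Angle solves and bisections use xtol 1e−10…1e−14; ties at multiple
  crossings break toward the smaller root (first crossing).
- Polynomial coefficients are real by construction; an imaginary residue
  below 1e−12 is asserted before discarding.
- `locate_hopf` requires a sign change of the leading complex-pair real
  part across the bracket; multiple steady states are handled by
  continuation from the previous parameter value's state, falling back to
  multi-start search. It tracks one branch only; it is not continuation
  software and does not switch branches.
- The random-network generator emulates smooth, bounded, monotone Hill
  regulation with log-uniform rates in [0.1, 10] — adequate as an oracle
  domain for the algebraic identities, but it does not emulate stiffness
  extremes, conservation laws, or the piecewise kinetics of the worked
  models, so passing oracle tests on it does not by itself validate those
  regimes.
- Symbolic (parameter-free) characteristic polynomials and n > 12 networks
  are out of scope.
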