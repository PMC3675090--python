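# Methods

## Model

The simulator couples four ingredients, all in normalized units (time in
units of the bond association time 1/k_on, energies in k_B·T, forces in
units of the single-filament stall force, densities relative to
saturation).

**Coupled FA/SF kinetics.** The bond density ξ of a focal adhesion and
the filament density ζ of the attached stress fiber obey

    dξ/dτ = (1 − ξ) − ξ·exp(−Ĝ)
    dζ/dτ = c·ξ − d·ζ

Bond formation fills the unoccupied fraction at unit rate; dissociation
is Bell-type with rate exp(−Ĝ), so a larger energy reduction Ĝ per bond
means slower unbinding. Filament growth is proportional to the bond
density (SFs polymerize from adhesion anchors), giving the quasi-steady
ratio u_ss = c/d. The dissociation prefactor equals the association
rate; this is what produces the logistic closed form of the static
steady state below.

**Bond energy.** Ĝ = g₀ + a·u − (β/s)·(u·F̂)² with u = ζ/ξ. The three
terms: (i) the bare energy g₀ < 0 gained by recruiting one bond against
membrane fluctuations and glycocalyx repulsion — bare bonds are
unstable, adhesions exist only because of (ii) the reinforcement a·u by
plaque proteins whose density tracks the filament density, counted per
bond; and (iii) the elastic energy stored in the bond–substrate spring
under the average per-bond load. All filament forces are transmitted
through the plaque and shared equally by the bonds, so the per-bond load
is F̂·ζ/ξ = u·F̂; the stored energy is quadratic in the load and inversely
proportional to the spring constant, which scales with the substrate
modulus — hence the compliance parameter β divided by the stiffening
factor s. The ratio u is evaluated only while ξ > 10⁻⁶; below that the
cell is treated as detached (collapsed states are absorbing in
practice).

**Substrate stiffening.** s(ε) = 1 for |ε| < ε_c and (|ε|/ε_c)^{3/2}
above, continuous at the threshold, evaluated on the magnitude of the
*instantaneous effective strain along the cell axis*. This convention
makes stiffening strongest for cells parallel to the stretch, which is
what produces parallel alignment under quasi-static stretch; ε_c = ∞
encodes a linearly elastic substrate.

**Viscoelastic filament.** Each contracting filament is a constant
stall force in parallel with a Maxwell element (spring k̂, relaxation
rate γ): F̂ = 1 + F̂_v with dF̂_v/dτ + γ·F̂_v = k̂·dε_f/dτ. Static stretch
of any magnitude leaves F̂ = 1 (the filament relaxes by remodeling its
crosslinks); only the *rate* of stretching loads the spring. Because the
branch is linear, the initial-value solution used inside the kinetics is
evaluated in closed form (decaying transient plus steady-periodic
response); an independent numerical integration of the Maxwell relation
serves as the oracle in the test suite.

**Effective strain and Poisson effect.** A cell at angle θ feels
ε_a(θ) = ε_A(cos²θ − ν·sin²θ). For ν = 1/2 the effective strain vanishes
at θ* = arctan √2 ≈ 54.7° and is compressive beyond; cells then prefer
the zero-strain direction rather than the perpendicular one.

**Stretch waveform.** The substrate strain follows the nonnegative
cycle ε_f(τ) = (ε_a/2)(1 − cos Ωτ): stretch chambers cycle the membrane
between its rest length and the nominal amplitude, they do not compress
it. The force modulation is therefore k̂(ε_a/2)·Ω/√(γ²+Ω²). A signed
sinusoid ε_a·sin Ωτ is available as `waveform="signed"`; it doubles the
force modulation at equal nominal amplitude and makes the model collapse
even at 1% amplitude for parallel cells, which is inconsistent with the
observed insensitivity to small-amplitude stretch — hence it is not the
default. Physical frequency maps to Ω = 2π·f/k_on with k_on = 6.25 s⁻¹
(one time unit = 0.16 s, fixed by the SF disassembly time scale
1/d = 10 τ ≈ 1.6 s).

**Static steady state and stability.** With F̂ = 1, s = 1 and
u_ss = c/d, Ĝ_ss = g₀ + a·u_ss − β·u_ss² and ξ_ss = 1/(1 + e^{−Ĝ_ss}),
ζ_ss = u_ss·ξ_ss: the bond density decays with substrate compliance.
`classify_fixed_point` labels the fixed point by the eigenvalues of the
central-difference Jacobian and also reports the feedback threshold
β* = a·d/(2c) at which dĜ/du = a − 2β·u_ss changes sign. Note that β* is
a *necessary-condition* marker, not the bifurcation point: at the fixed
point the Jacobian determinant is d·(1 + e^{−Ĝ_ss}) > 0 identically (the
dĜ/du contribution cancels because u_ss = c/d), so stability is lost
only through the trace — a Hopf-type crossing at β ≈ 1.02 for the
default kinetics (β* = 0.875). From nascent initial conditions the
collapse boundary is β ≈ 1.01. Physically both numbers say the same
thing: adhesions fail on substrates with compliance of order one.

## Reorientation loop

A trial attaches the cell with ξ₀ = 0.3 (nascent focal complex),
ζ₀ = 0 and an unloaded filament, and integrates for the assessment
window `trial_time` = 500 τ. Unstable orientations collapse; the cell
detaches at the collapse time, hops by Δθ = √(2·D_r·t₀)·N (standard
normal N, nucleation interval t₀ = 0.2 τ), and tries again. A cell that
survives the window settles: the attached dynamics are deterministic, so
a stable state cannot destabilize spontaneously, and the orientation is
frozen (and excluded from further integration, for cost control only).
Orientations live on the half-circle (−π/2, π/2]; the order parameter
S = ⟨cos 2θ⟩ is insensitive to the fold. S(τ) is sampled on a 200-point
uniform grid by zero-order hold of each cell's orientation.

Because each trial starts from the same state and the protocol phase
restarts at attachment (a freshly nucleated adhesion sees the stretch
from its own clock), the trial outcome depends only on the orientation.
The population Monte Carlo therefore precomputes outcomes (stable /
collapse time / mean density) on a 0.5° grid over [0°, 90°] — exact up
to grid resolution after folding, since the dynamics are even and
π-periodic in θ — and the stochastic loop reduces to table lookups.

The rotational diffusivity D_r is the one constant not pinned by the
reference parameter set; the default 5×10⁻³ rad²/τ respects the required
scale separation (whole-cell reorientation in ~10⁴–10⁵ τ, far slower
than FA/SF remodeling) and places the fitted 1-Hz decay time at
≈2.7×10⁴ τ. Absolute decay times scale ≈ 1/D_r; the settled order
parameter does not depend on it.

## Parameters

| symbol | meaning | default |
|---|---|---|
| c | SF association rate | 0.2 (0.1 Rho-inhibited) |
| d | SF dissociation rate | 0.1 |
| g₀ | bare bond energy | −5 |
| a | bond–reinforcement energy | 3.5 |
| β | substrate compliance | 0.6 (physical range ~0.03–3) |
| k̂ | SF spring constant | 15 |
| γ | elastic/viscous ratio | 0.5 |
| ε_c | critical stiffening strain | 0.04 (∞ = linear) |
| ν | substrate Poisson ratio | 0 (0.5 for strong Poisson effect) |
| k_on | bond association rate | 6.25 s⁻¹ |
| t₀ | FX nucleation / hop interval | 0.2 τ |
| D_r | rotational diffusivity | 5×10⁻³ rad²/τ |

## Numerical choices

* Adaptive RK45, rtol 10⁻⁶ / atol 10⁻⁹, max step min(period/40, 5):
  the step cap resolves the forcing; the error control resolves the
  exp(−Ĝ) nonlinearity. Closed-form cross-checks: static steady state
  recovered to <10⁻⁴, Maxwell force to <10⁻⁶.
* Collapse detection: threshold ξ < 0.02 as a terminal downward-crossing
  event, armed only after a grace window of 10 τ (= 1/d). The grace is
  required because with ζ₀ = 0 the nascent transient necessarily dips to
  ξ ≈ 1/(1+e^{−g₀}) ≈ 0.007 before reinforcement builds; with it,
  thresholds 0.01–0.04 classify the default regimes identically. If the
  solver underflows its step size while the load ratio is in the runaway
  regime (u > 3·u_ss, where the dissociation rate diverges faster than
  any explicit step), the failure point is the collapse time; underflow
  with a benign load ratio raises a distinct `SolverError`.
* exp(−Ĝ) is capped at e²⁰⁰ — rates beyond that are indistinguishable
  from instantaneous and the cap keeps the solver's error norm finite.
* Long-time averages: horizon 500 τ; transient discard max(200 τ, 10
  periods); mean over an integer number of complete cycles. At ≤0.05 Hz
  (periods ≥ 125 τ) the state tracks the quasi-equilibrium, so two
  periods are integrated and the second is averaged.
* Decay fitting: S(τ) = S_∞ + (S₀ − S_∞)e^{−τ/τ_c}, least squares with
  all three parameters free, refused when the trace shows no net decay
  (|ΔS| ≤ 0.1, the decay time is then unidentifiable).
* Population runs: 100 cells, horizon 1.5×10⁵ τ (all or nearly all
  cells settle well within it at 10% amplitude), ensembles of 10 seeds
  with the spread reported as the standard deviation over seeds.

## What the simulations do and do not show

The model generates its own study conditions; there is no external data.
Simulated populations are independent cells — no crowding, contact
inhibition or cell–cell alignment interactions — and each cell is a
single axis with one FA/SF pair; there is no intracellular distribution
of fiber orientations, no spatial adhesion growth, and no translation of
detached cells. Collapse times and transient shapes depend on the
(unmeasured) densities at nucleation, so only long-time quantities
(steady densities, stable bands, settled order parameter) should be
compared across parameterizations. Agreement of the test suite with the
anchor values therefore supports the mechanism — competition between
force-accelerated disassembly and stiffening-promoted adhesion — not a
quantitative fit to any particular cell type.

Known limitations: myosin activity is a constant stall force (no
force–velocity relation or activation dynamics); the first-order
kinetics carry a single relaxation time each, which compresses the
frequency dependence of the population decay time — at 10% amplitude the
fitted decay times at 1.0 vs 0.2 Hz differ by ≈100% here (the 0.2 Hz
stable band is markedly wider because the Maxwell force amplitude falls
2.4-fold between the two frequencies), larger than the ~40% difference
the underlying experiments and the original analysis suggest, though the
direction (faster, shallower decay at 0.2 Hz) is reproduced. The
decay-time *ratio* also retains some sensitivity to D_r through the
per-trial clock, so it should be read as qualitative.
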