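# Methods

## Model class and scope

The single neuron is the adapting quadratic (Izhikevich) integrate-and-
fire model: a voltage v with F(v) = v(v − α), reset at v_peak to
v_reset, and a slow adaptation current w incremented by w_jump at each
spike and decaying with time constant τ_w = 1/a. Coupling is all-to-all
through a single network gating variable s with exponential synapses:
every spike anywhere increments s by s_jump/N, and each neuron feels the
conductance g_i s (E_r − v_i). The membrane nonlinearity is pluggable in
the quadrature fallback (`rate_by_quadrature`), but only the quadratic
model ships with closed forms; exponential and quartic variants are out
of scope.

Two simplifications hold in every shipped configuration and in all
numerical work here: the linear voltage-to-adaptation coupling is
dropped (b = 0, i.e. η = 0 — the term is carried in all formulas and the
original fit's b = −0.0062 remains available), and the synaptic reversal
is excitatory at E_r = 0 mV (e_r = 1), the standard AMPA convention.
All-to-all coupling, no delays, no inhibitory population.

### Units

Dimensional parameters (pF, nS, mV, pA, ms) live at the user boundary;
everything internal is dimensionless via v = 1 + V/|V_R|,
w = W/(k V_R²), t → t·k|V_R|/C. One dimensionless time unit is
C/(k|V_R|) ≈ 1.54 ms for the default CA3 parameter set (C = 250 pF,
k = 2.5 nS/mV, V_R = −65 mV, V_T = −24.6 mV, V_peak = 30 mV,
V_reset = −55 mV, W_jump = 200 pA, τ_W = 200 ms, τ_syn = 4 ms,
s_jump = 0.8). All conversions are linear, so normal parameter
distributions remain normal after nondimensionalization. Rates cross the
boundary in spikes/ms.

## Quasi-steady-state closure

With τ_w ≫ 1 the fast voltage density equilibrates between changes of
(w, s), making the population rate algebraic: the reciprocal of the
reset-to-peak transit time when the drift F(v) − w + I + g(e_r − v)s is
everywhere positive, zero otherwise. The switching function
H = I − w − (α + gs)²/4 + g e_r s is the drift's global minimum plus
drive; H = 0 is assigned to the firing branch, where the rate limit is
zero anyway, so the tie-break is numerically immaterial. The closure also
requires τ_s not to be significantly faster than the voltage relaxation;
constructing a mean-field system with τ_s < 1 (dimensionless) emits a
warning rather than an error, because the systems remain integrable even
where the approximation degrades.

## The three reductions

* **MFI**: two ODEs for (⟨w⟩, s) at the mean parameters. Exactly the
  homogeneous mean field; accurate for narrow heterogeneity away from
  the rheobase.
* **MFII**: same two ODEs, but the rate and voltage are conditional
  moments averaged against the parameter density. Discretization:
  Gauss–Hermite nodes for a single normal parameter, Monte Carlo samples
  with uniform weights (recorded seed) for mixtures or several
  parameters.
* **MFIII**: the β-conditioned adaptation field ⟨w|β⟩ by the method of
  lines: one adaptation ODE per grid node, one shared gating variable.
  The grid is generated from the parameter density itself (Monte Carlo,
  default M = 1000 nodes for production runs; Gauss–Hermite where a
  smooth 1-D representation is needed), which makes the integrals in the
  s-equation plain node averages.

### A smooth MFII for eigenvalue work

Fixed-node quadrature of the hard-switched rate integrand makes the
right-hand side only piecewise smooth in state: whenever a node crosses
its switching point, the Jacobian picks up a 1/√H spike (the residual of
a Newton solve stalls near 1e−8, and finite-difference eigenvalues jump
discontinuously along a parameter scan). For heterogeneity in the
applied current alone the integral can instead be taken over the firing
region I > I*(w, s) with the substitution I = I* + u², which absorbs the
√H edge behavior into the measure and leaves a C¹-smooth right-hand side
(`MFIICurrent`, Gauss–Legendre with 80 nodes on the transformed axis; it
matches a brute-force trapezoid of the original integral to ~1e−13). All
Hopf location and criticality work on heterogeneous-current systems uses
this form; the generic Gauss–Hermite MFII remains the general-purpose
reduction. This replaces a fixed 20-node Gauss–Hermite rule for
bifurcation work; the accuracy comparison in the test suite documents
why.

### Integration

Mean-field trajectories use adaptive RK45 with rtol = atol = 1e−8
default. The √H non-smoothness is continuous, so no event detection is
needed. One caveat: in strongly driven corners of parameter space
(large g_syn and I_app) trajectories can slide along H ≈ 0, where
adaptive step control chatters (hundreds of thousands of steps for a few
time units). Sweeps therefore use fixed-step RK4 (dt = 0.1 dimensionless
by default), which is immune to chatter and has predictable cost;
accuracy there is bounded by the envelope classification tolerance, not
by the integrator.

## Ground-truth network simulator

Fixed-step forward Euler (default dt = 0.05 ms, dt = 0.01 ms for
rate-inference work) on the dimensional equations; the spike test runs
after each step, all simultaneous spikes increment s within the step, and
v is clamped to the reset without interpolating the crossing time, so
per-spike timing error is O(dt). A dt-halving test bounds the effect on
mean traces at under 1%. Initial conditions are desynchronized
(v uniform on [V_reset, V_peak), w = 0, s = 0) unless a fixed v_init is
configured. Per-neuron heterogeneous parameters are drawn independently
per parameter from the configured distributions with the run's seed and
are stored with the raster.

What the simulator (as the synthetic-data source) does and does not
emulate: it is the exact model the reductions approximate — same
equations, same parameter draws — so agreement between network and mean
field tests the *closure*, not the model. It does not emulate features of
real recordings (measurement noise, non-stationary drive, synaptic
failure, correlated parameters), so passing tests certify the method's
internal consistency, not its robustness to those effects. Finite-size
effects are real and visible: at N = 1000 the tonic "steady state"
carries a collective ripple in s of a few percent, which is the dominant
error source in last-interspike-interval rate estimates.

## Rate distributions, inversion, and recovery

In a tonically firing network the steady MFIII fixed point defines a
monotone map g(β) = ⟨R|β⟩; pushing the parameter density through g (or a
measured rate density back through it) is a 1-D change of variables.
Numerical choices: maps are tabulated on the β grid and interpolated
with monotone PCHIP (preserves invertibility; derivatives from the
interpolant); predicted densities are renormalized on their tabulated
support; network rate densities are estimated by Freedman–Diaconis
histograms; quiescent grid nodes (rate 0) are excluded from the map
before inversion, which is valid when the non-firing mass is negligible
(at the shipped operating points it is below 1e−3). Inversion pins the
gating variable at s̄ = τ_s s_jump ⟨R⟩ using only the measured mean rate,
then solves the per-node adaptation balance w = τ_w w_jump R(w, s̄, β) by
bracketed root finding; this reproduces the dynamical fixed point to
1e−6 and needs no knowledge of the parameter density. Per-neuron
recovery inverts the tabulated map at each measured rate, clamping (with
a warning) rates outside the map image. Multi-parameter heterogeneity
uses Monte Carlo sampling of the joint density plus linear interpolation
over the sampled (β, R) pairs; inverting a 1-D rate density to a
multi-dimensional parameter density is not implemented (the problem is
underdetermined).

The recovery experiment (1000 neurons, I ~ Normal(4500, 1000²) pA,
g_syn = 200 nS, 2000 ms at dt = 0.01 ms, rates from the last interspike
interval) yields a mean relative absolute error of individual currents
around 0.4–0.7% depending on the realization; the spread is dominated by
the finite-network gating ripple, not by the map or the integrator.

## Bursting fractions

On an oscillatory MFIII attractor, each node's rate envelope over one
period classifies its slice of the population: tonic if the rate never
reaches zero, quiescent if it never leaves zero, bursting otherwise
(Heaviside convention h(0) = 1, so the three fractions sum to one
exactly). The numerical zero is 1e−8 in dimensionless rate; varying it
over [1e−10, 1e−6] moves fractions by less than one grid weight.
Parameter-plane sweeps classify each point from a single observation
window (default 400 time units after a 600-unit transient, fixed-step
RK4) rather than resolving the period — sufficient for envelopes, and
about five times cheaper; the window envelopes agree with full
period-detected envelopes to 2e−3. Production sweeps here use 10×10
meshes with 21 Gauss–Hermite nodes; finer meshes change the contours'
resolution, not their structure. The "fully bursting area" reported for
heterogeneity comparisons counts mesh cells with p_burst = 1, a monotone
proxy for the area inside the 100% contour (marching-squares contour
extraction is available separately).

## Bifurcation location without continuation

Equilibria: damped-Newton on the planar systems, with jittered restarts;
eigenvalues from central-difference Jacobians. Hopf points: bisection on
the leading eigenvalue's real part along the continued equilibrium
(tolerance 1e−3 nS in conductance scans).

Unstable cycles are computed as attractors of the time-reversed flow,
started just off the stable focus they surround. Two numerical points
matter: the reversed cycle is only weakly attracting near the fold of
limit cycles, so loose integrator tolerances let local error kick the
trajectory across the cycle into the divergent exterior (rtol = 1e−10 is
used); and convergence is declared on the stabilization of successive
peak values of s, whose sampled precision (~1e−4 relative) sets a noise
floor of roughly 0.2 nS on bisection answers that depend on the cycle's
shape.

The grazing bifurcation is bisected on the sign of min_t H along the
tracked cycle (min H grows toward the Hopf, shrinks away from it; a
vanished cycle counts as "past the fold", hence below the grazing). The
non-smooth saddle-node of limit cycles is bisected on the existence of
the stable bursting cycle under forward simulation, inheriting the
attractor state from the existing side so each probe starts inside the
cycle's basin; "bursting" requires a sustained oscillation whose network
rate vanishes over part of the period.

Hopf criticality is classified from simulation, not from a first
Lyapunov coefficient (the right-hand side is non-smooth nearby): the
attractor amplitude A is measured at relative parameter offsets
{1%, 2%, 4%, 8%} past the Hopf on the unstable side, integrating in
chunks until the amplitude settles. Square-root scaling of A with the
offset (log–log slope ≥ 0.3) marks a supercritical Hopf; an
offset-independent jump to a distant attractor (slope < 0.2 with
comparable amplitudes at all offsets, divergence capped and counted as
"distant") marks a subcritical one; anything else returns "unknown".
The classifier is exact on both cubic normal forms. Offsets below 1%
would sharpen the scaling estimate but make transients impractically
long (the growth rate vanishes linearly at the Hopf).

For the homogeneous system at I_app = 2000 pA this machinery gives a
subcritical Hopf near g_syn ≈ 57.5 nS, a grazing of the unstable cycle
at ≈ 52.4 nS, and a saddle-node of limit cycles at ≈ 51.9 nS — the
unstable cycle born at the Hopf becomes non-smooth (grazing) *before*
colliding with the bursting cycle as it grows away from the Hopf, so the
fold necessarily sits below the grazing on the conductance axis. With
σ_I = 500 pA the low-conductance Hopf of the heterogeneous reduction
moves to ≈ 120 nS and switches to supercritical, which is the mechanism
behind the gradual low-conductance bursting boundary.

## Limitations

* The closure needs τ_w large and fails quantitatively when many neurons
  sit near their switching point; MFII in particular bifurcates back to
  tonic firing too early for large σ_I.
* Rate-distribution inversion assumes a single known heterogeneous
  parameter and all other parameters known exactly — strong assumptions
  for real data.
* Sliding segments of the switching manifold are integrated through, not
  treated with sliding-mode (Filippov) machinery; fixed-step integration
  bounds the cost but the local order there is reduced.
* Chaotic attractors are not detected as such; period-doubled cycles are
  reported through their envelopes only.
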