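# Methods

## Signal model

The package models a multi-echo spin-echo sequence with equidistant echo
spacing τ as an extended-phase-graph (EPG) recursion.  The magnetization of
a voxel, dephased by applied gradients, is expanded in configuration states
(F_k+, F_k−, Z_k): Fourier coefficients of the transverse and longitudinal
magnetization with respect to the dephasing angle.  An RF pulse with
amplitude α and phase φ acts on every triple (F_k+, F_k−, Z_k) through the
same 3×3 complex rotation block; relaxation over an interval dt scales the
triple by diag(e^{−dt/T2}, e^{−dt/T2}, e^{−dt/T1}); one unit of gradient
dephasing shifts transverse content one step up the configuration ladder,
F(k) → F(k+1), and leaves Z_k untouched.

States are stored one-sided: row F_k+ holds the coefficient of order +k,
row F_k− holds the conjugate of the coefficient of order −k, for
k = 0 … K.  The two order-zero slots are redundant (F_0+ = conj(F_0−)); the
echo is read from F_0−.

### Timing convention

Each period between refocusing pulses is composed as

    f_{n+1} = (S · E(τ/2)) · R(α_n, φ_n) · (S · E(τ/2)) · f_n ,   n ≥ 1,

i.e. half-period relaxation plus one dephasing unit before the pulse and the
same after it; the excitation (n = 0) is a pure rotation.  The ladder unit
is therefore the dephasing accrued over τ/2, states sampled at echo times
occupy even orders only, and the n-th state (n ≥ 2) carries echo n−1 exactly
at order zero — CPMG timing, with the first echo at f_2.  E and S commute on
transverse states, so the ordering inside a half-period is immaterial.

Relaxation is pure decay by default: Z_0 is *not* regrown toward
equilibrium, matching the short-train regime where T_R ≫ echo-train length
makes recovery during the train negligible.  An opt-in
`longitudinal_recovery` flag adds the standard (1 − e^{−dt/T1}) regrowth; no
bundled study uses it.

### Truncation

The configuration order is truncated at K = min(N, 25) by default (content
shifted past K is discarded), overridable per problem.  Although stored
high-order slots can differ between truncation levels, every *echo* is exact
for K ≥ N: reaching order k costs at least (k+1)/2 periods and returning to
order zero at least (k−1)/2 more, so content that ever exceeds order N
cannot rephase into an echo within N periods.  The tests assert echo
agreement between K = N and K = 2N at the 1e−12 level.

## Design problems

A design problem is min s(θ) subject to q_j(θ) ≤ 0 over θ = per-pulse
(amplitude, phase) pairs or, for parallel transmit, per-pulse per-channel
real/imaginary weights (x, y) in nominal flip-angle radians.  Building
blocks (usable as objective or constraint):

* **error to target**  ½ Σ_r Σ_n c_n |s_{n,r} − t_n|²  (σ²-shifted when used
  as the fidelity constraint),
* **signal energy**  −½ Σ_r Σ_n c_n |s_{n,r}|²,
* **total RF power**  ½ Σ_n α_n²  (pTx: ½ Σ_n Σ_l x² + y²),
* **peak amplitude**  α_n − α_max  (pTx: x² + y² − α_max² per channel).

Echo weights c_n default to 1; zero weights mask echoes (e.g. the first five
in the capped study), larger weights emphasize central k-space echoes.
Target trains store only the echo component; they are complex, carrying the
echo phase the CPMG convention produces (a 0°/90° excitation/refocusing
train yields echoes along +i, so "constant intensity 0.6" is the target
train 0.6i).

Piecewise-constant reduction ties (α_n, φ_n) to shared values over a
partition {Q_j} of the pulse indices through the binary incidence matrix Q
(α = Q a); gradients project back as Q^T g.  Free parameters: 2G standard,
2GL for L channels.

## Adjoint-state gradients

For s = Σ_n g_n(f_n) the gradient follows from the backward recursion
λ_{N−1} = ∇g_N(f_N), λ_n = P_{n+1}* λ_{n+1} + ∇g_{n+1}(f_{n+1}), and
∂s/∂θ_n = ⟨λ_n, (∂P_n/∂θ_n) f_n⟩.  Two implementation details matter:

* **Real inner product.**  The one-sided ladder's shift is only R-linear
  (the redundant F_0+ slot is refreshed with a conjugate), so adjoints are
  taken with respect to Re(u^H v): C-linear blocks contribute their
  conjugate transposes, the conjugation slot contributes a conjugation.  All
  gradients are then exactly real by construction.
* **Cartesian pTx chain rule.**  Per voxel, the effective pulse is
  z = Σ_l conj(B_l)(x_l + i y_l) = α e^{iφ}.  Since φ degenerates at z = 0,
  the rotation block and its derivatives are expressed directly in
  (Re z, Im z) through functions smooth at the origin (sin α/α,
  sin²(α/2)/α² and their radial slopes, series-guarded below |z| = 1e−4).
  Only the two blocks ∂R/∂u, ∂R/∂v are formed per (pulse, voxel); per-channel
  derivatives are cheap linear combinations with conj(B_l).

One gradient evaluation costs four EPG-equivalent passes — forward states,
backward adjoints, and the combined derivative-product double loop —
independent of the parameter count; the instrumented counters report this.
Purely explicit components (total power, peak amplitude) need no passes and
their analytic gradients (α_j, 2x, 2y) are added directly.  A central
finite-difference oracle (default step 1e−6 rad; 2N_p + 1 simulations,
counted) is the independent arbiter of correctness; complex-step
differentiation is deliberately not used because the operators are already
complex.  ASM and oracle agree to better than 1e−6 relative error on every
objective and constraint, standard and pTx, in the test suite.

## Solver

`scipy.optimize.minimize` drives the constrained solve with the exact ASM
gradients and BFGS quasi-Newton curvature.  Two methods are wired:

* **SLSQP** (default for standard mode): an active-set SQP that handles the
  α ≥ 0 bounds and optima sitting exactly on constraint boundaries (the
  minimum-power constant-intensity design) without barrier bias.
* **trust-constr** (default for pTx): interior-point flavour whose iterates
  stay feasible, which matters when a run is halted at an iteration budget
  (the pTx studies stop after 50 iterations).

Amplitudes are bounded below at 0 to remove the (α, φ) ↔ (−α, φ+π) gauge
ambiguity; reported trains are canonicalized (amplitude ≥ 0, phase wrapped
to [−180°, 180°)).  Standard-mode peak caps are passed as linear constraints
on the grouped amplitudes; implicit constraints carry their ASM Jacobians.
Defaults: gradient tolerance 1e−8, constraint feasibility 1e−9, 200
iterations (50 in the pTx presets).  The solve path contains no randomness.

Two solver-facing subtleties of the bundled studies:

* The capped constant-refocusing study's printed start (all refocusing
  amplitudes at the 60° cap, all phases 0) is itself a first-order KKT
  point: the bound is active and the phase gradient is a structural zero,
  because the objective is even under a global sign flip of the phase
  offset.  It is a saddle — the 90° offset is far better — but invisible to
  a first-order method, so the preset nudges the initial refocusing phase by
  0.5°; the solver still finds the 60°/90° CPMG solution on its own.
* The minimum-power design's optimum lies exactly on the σ² fidelity
  boundary, so the converged deviation equals σ up to the feasibility
  tolerance, not below it.

## Synthetic transmit maps

Measured B1+ maps are out of scope, so the pTx studies run on a bundled
deterministic generator emulating an 8-channel loop array around the head at
7 T: per channel, an amplitude that decays with distance from its coil plus
a common centre-brightening bump, and a phase combining the azimuthal
channel offset 2πl/L, a propagation ramp, and smooth low-order seeded
perturbations.  Scales are set so the circularly-polarized (CP) mode has a
coefficient of variation of ≈ 0.25 over the elliptical ROI — the level
typically reported for the human head at 7 T — and unit mean amplitude
(nominal flip = mean achieved flip).  The generator reproduces the *shape*
of the design problem (smooth complex inhomogeneity, destructive
interference away from centre) but not any specific subject or coil: wave
physics, tissue-dependent loading and transceive-phase structure of real
maps are absent.  Passing homogenization tests therefore show the machinery
homogenizes realistic inhomogeneity levels, not that it reproduces any
measured in-vivo curve.  Maps travel in an HDF5 container
(`/B1/channel_<l>/real`, `/imag`, `/B1/mask`); voxel indices are 0-based,
axis order (x, y, z), sensitivities enter the effective pulse conjugated.

ROI thinning offers a plain stride lattice and an alternating-offset
("tetrahedral") lattice; the choice affects conditioning only.

## Bundled study sizes and parameters

* Signal maximization: N = 60, T1/T2 = 1000/150 ms, start 90°/60° CPMG.
* Constant intensity: N = 50 (train length not fixed by the reference
  description; chosen here), relaxation off, I_c = 0.6, σ = 1e−3, start 18°,
  excitation frozen at 90°.
* Capped design: N = 60, cap 60°, echoes 6+ weighted, constant-refocusing
  and per-pulse variants.
* pTx 3D: 52 pulses (90°, 151°, 90°, 67°, 60°×48), τ = 2.9 ms,
  T1/T2 = 500/400 ms, 22 singleton + 3×10 grouped pulses → 400 parameters,
  ~90 ROI voxels, peak 270°, total power twice the CP drive, 50 iterations.
* pTx 2D: 10 pulses (105°, 174°, 145°, 140°×7), τ = 12 ms,
  T1/T2 = 1500/100 ms (white matter), stride-4 ROI (~105 voxels), central
  echo weight 2, same constraints, 50 iterations.

τ = 10 ms is used for the standard-mode studies (a typical TSE echo
spacing; the relaxation-free study is τ-independent).  All study sizes run
in seconds on one CPU.

## Limitations

Fixed echo spacing only (no τ optimization, no variable T_R/T_E); no
diffusion, flow, or magnetization transfer; no SAR models beyond peak/total
RF power; local optimization only (a different basin can win for strongly
non-convex designs — the time-varying capped study is one such landscape);
equality constraints are accepted by the interface but unused by the bundled
studies.
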