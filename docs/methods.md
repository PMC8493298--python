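# Methods

This note records the models implemented in `cardiorom`, the numerical
choices behind them, and the reasoning for the design decisions that were
genuinely open.  It states no measured result; the test suite and
`scripts/acceptance.py` compute every number the package claims.

## Tissue model

The electrical activity of a cardiac tissue patch is modelled by the
Bidomain equations in parabolic–elliptic form on a rectangle Ω, coupled to a
single-gating-variable phenomenological ionic model:

    du/dt − div(D_i ∇u) − div(D_i ∇u_e) + I_ion(u, w) = I_app^i,
    −div(D_i ∇u) − div((D_i + D_e) ∇u_e)              = I_app^i + I_app^e,
    dw/dt = g(u, w),

with homogeneous Neumann (insulation) boundary conditions and rest initial
data u = w = 0.  `u` is the transmembrane potential, `u_e` the extracellular
potential, `w` a recovery variable.  Time is in ms; the membrane capacitance
coefficient is absorbed into the model constants.  The conductivity tensors
are axisymmetric around the local fiber direction f0(x):

    D_{i,e} = σ_t^{i,e} I + (σ_l^{i,e} − σ_t^{i,e}) f0 ⊗ f0,

with conductivities in Ω⁻¹cm⁻¹ and lengths in cm.  Fibers are either a
constant unit vector or the normalized gradient of a harmonic function with
Dirichlet data 0/1 on two marked edges (the rule used to assign atrial
fiber fields on curved surfaces; on a rectangle with left/right markers it
reproduces (1,0) exactly, which the tests verify).

### Gating sign convention

The recovery ODE is integrated as `dw/dt = +g(u, w)` with

    A-P:  g = (ε0 + c1 w/(c2+u)) (−w − K u (u−b−1)),
    R-M:  g = η2 (u/u_p − η3 w).

With these right-hand sides `w` grows during the action potential and
relaxes back to rest afterwards; integrating `dw/dt = −g` makes the rest
state unstable and produces no repolarization, so the `+g` orientation is
the only one consistent with the models' published dynamics and with the
0-D behaviour the tests pin down.

### Ionic models

Two phenomenological models are provided (constants in `ionic.PRESETS`):

* **Rogers-McCulloch** (`test1_1_rm`): u in mV on [0, u_p];
  G = 1.5 ms⁻¹, η1 = 4.4 ms⁻¹, η2 = 0.012, η3 = 1, u_th = 13 mV,
  u_p = 100 mV.
* **Aliev-Panfilov** (`test1_2_ap`): dimensionless u on ≈ [0, 1];
  K = 8, a = 0.1, b = 0.1, ε0 = 0.01, c1 = 0.05, c2 = 0.3.

The Aliev-Panfilov restitution factor ε0 + c1 w/(c2+u) makes its gating ODE
quadratic in w; the integrator freezes the factor at the extrapolated
gating value (second-order accurate), after which both models are linear in
w and solved exactly per quadrature point.

## Spatial discretization

Tensor-product B-splines of degree p with open uniform knot vectors (global
C^(p−1) continuity) on rectangles; plain splines (all rational weights 1)
because the slab is a flat patch — the data model keeps the door open for
rational weights.  Quadrature is Gauss–Legendre with p+1 points per
direction per element, exact for the mass matrix on affine elements.  The
boundary conditions are natural in the Galerkin form, so no boundary terms
are assembled.  Basis values come from the Cox–de Boor recursion
(`scipy.interpolate.BSpline.design_matrix`); derivatives use the standard
two-term degree-lowering formula.  Stimuli are indicator functions in space
and time, integrated with the same element quadrature (no sub-cell
cutting): the committed error is O(h), localized at the region boundary,
which matches the coarse footprints of the benchmark stimuli (tests check
the integral against the region area to 1%).

The printed full slab space is degree 3 on 160 × 32 elements over
(0,10) × (0,2) cm, giving N_h = 163·35 = 5705 basis functions and 5120
elements.

## Time integration

Semi-implicit BDF2 ("SBDF2"):

* diffusion implicit — one sparse LU factorization of (3/(2Δt))M + A_i per
  (μ, Δt), reused across all steps (plus one for the implicit-Euler
  bootstrap of the first step);
* the ionic current evaluated explicitly at the second-order extrapolant
  u* = 2u^k − u^{k−1};
* the coupling segregated per step: parabolic solve for u with u_e at its
  extrapolant, then the elliptic solve for u_e — one Gauss–Seidel pass, no
  sub-iteration;
* gating advanced implicitly (it is linear in w given u*, see above) at
  quadrature points.

Ionic evaluation is "state-variable interpolation": w lives at quadrature
points and I_ion is sampled where it is integrated, because spline
coefficients are not interpolatory, so coefficient-level ("ICI") evaluation
is ill-defined as a field statement.  A cheaper coefficient-level mode is
available behind `ionic_mode="ici"` for comparisons only.

The scheme is second order (the suite measures slopes ≈ 2 on both a 0-D
cell problem and a forced tissue problem).  Its accuracy limit is worth
stating: across the ~1 ms action-potential upstroke the BDF2 truncation
error at Δt = 0.05 ms is of order 10⁻² on the normalized potential — also
for a fully implicit BDF2 — and reaches 10⁻³ only around Δt ≈ 0.01 ms.
A blow-up guard aborts a step if any coefficient leaves
[−0.3 u_p, 1.3 u_p]; beyond divergence this also catches spatially
under-resolved fronts, whose Gibbs under/overshoot grows with h.

### Elliptic compatibility

The extracellular matrix A = A_i + A_e is singular (constants span its
kernel; pure Neumann problem).  With an intracellular-only stimulus the
load violates the compatibility condition.  The solver uses a bordered
system [[A, m], [mᵀ, 0]] with m = M·1: the multiplier subtracts a spatially
*uniform balancing current* (whose load vector is exactly m), and the
constraint fixes the M-weighted mean of u_e to zero.  This is the physical
reading of "project the incompatible part out": the balancing current is
uniform in space, not uniform across coefficients.  Adding any multiple of
m to the load provably leaves u_e unchanged (tested).

## Reduced-order model

The surrogate approximates (t, μ) ↦ V^T u_h(t; μ):

1. **Snapshots.** Trajectories at N_train parameter instances sampled at
   N_t instants, stacked column-wise per field channel (u and u_e are
   separate channels with separate bases — their scales differ by two
   orders of magnitude).  No centering: the basis projects raw fields.
2. **Randomized POD.** Halko-style randomized SVD: Gaussian range finder
   with oversampling 10 and 2 subspace iterations with QR
   re-orthonormalization (standard settings), deterministic given the seed;
   the basis sign is fixed by making the largest-magnitude entry of each
   column positive.  The requested dimension N must not exceed the
   numerical rank — the basis is never padded with noise directions.
3. **Networks.** An encoder maps the N·d stacked intrinsic coordinates to n
   latent coordinates; a deep feedforward network (DFNN) maps normalized
   (t, μ) to the same latent space (time is treated exactly like a
   parameter); a decoder maps latents back to intrinsic coordinates.  The
   default latent dimension is the intrinsic dimension of the solution
   manifold, n = n_μ + 1.  The joint per-example loss is

       L = ω_h/2 ‖V^T u_h − ũ_N‖² + (1−ω_h)/2 ‖ũ_n − u_n‖²,

   averaged over all N_s = N_train·N_t pairs; ω_h ∈ [0,1] (default 0.8 for
   the fixtures: the reconstruction term is the quantity of interest and
   the latent-consistency term acts as a regularizer — raising its weight
   measurably slowed reconstruction convergence at desk scale).
   Optimization is Adam from a seed-fixed Glorot initialization, per-epoch
   shuffling, mini-batches, an exponential learning-rate decay over the
   epoch budget, a seed-fixed 80/20 train/validation split over (t, μ)
   pairs, and early stopping on the validation loss (patience configurable)
   with best-validation parameters restored.
4. **Prediction.** normalize (t, μ) → DFNN → decoder → denormalize per
   channel → lift with V per channel.  The encoder is not involved online;
   the cost is independent of N_h until the final lift.

### Architecture

All widths are config-exposed.  The default is dense: encoder
(N·d → 64 → n), DFNN (n_μ+1 → 50 → 50 → n), decoder
(n → widths → N·d), ELU activations, linear outputs.  Two choices matter and are
worth recording:

* **Sinusoidal decoder lift.**  The intrinsic coordinates of a travelling
  front oscillate along the latent "phase" coordinate (POD mode j
  oscillates ~j/2 times while the front crosses its support), and plain
  dense stacks are spectrally biased against such maps.  The decoder input
  is therefore lifted to [z, sin(2πkz), cos(2πkz)], k = 1..K (default
  K = 8, `decoder_fourier_modes`); gradients flow through the lift to the
  dynamics network.  In the development experiments this roughly halved
  the testing-set error at equal budget.  The same lift on the *network
  input* (t, μ) is harmful (periodic wrap-around under extrapolation) and
  is not offered.
* **Normalization.**  Inputs (t and each μ component) are min-max scaled
  per coordinate to [0,1] from the training split.  Intrinsic coordinates
  are min-max scaled with a *single scalar range per channel*, which
  preserves the relative scales of the POD coordinates — so the normalized
  loss stays proportional to the field reconstruction error.  (Scaling
  each coordinate separately equalizes the loss weight of all N modes and
  makes the many small, fast-oscillating trailing modes dominate training;
  it was tried and rejected.)  Degenerate (constant) coordinates map to
  0.5 with a warning.

### Grid view

The stacked per-channel intrinsic coordinates of one snapshot can be viewed
as a √N × √N × d tensor (row-major per channel; N must be a perfect
square), the layout a convolutional autoencoder would consume; the reshape
and its inverse are exposed and tested, and the network engine would accept
convolutional blocks as a future extension.

## Evaluation metrics

* Scalar indicator: mean over test instances of
  √(Σ_k ‖u_h^k − ũ_h^k‖² / Σ_k ‖u_h^k‖²), Euclidean norms of coefficient
  vectors.  Norms are plain 2-norms of coefficient vectors (no mass
  weighting): coefficient 2-norms keep the indicator consistent between full fields and
  intrinsic coordinates (V has orthonormal columns).
* Space-resolved relative error at time k:
  |u_h^k − ũ_h^k| / ((1/N_t) Σ_k ‖u_h^k‖₂), plus its spatial mean per k.
* **Exact lower bound.**  For any reconstruction of the form V·c the
  indicator is bounded below by the indicator of the orthogonal projection
  V V^T u_h (per-snapshot best approximation in span(V)).  The pipeline
  asserts this inequality on every evaluation.  The numbers relate the
  projection error (how good the linear subspace is) to the reconstruction
  error (how well the networks parametrize it).
* Activation map: per point, the earliest sampled time at which u attains
  its temporal maximum (ties resolve to the first occurrence; invariant
  under monotone rescaling).  Points whose maximum stays below a threshold
  (default 0.9·u_p in the callers) are flagged NaN, never given a time.
* AP traces evaluate the spline field at a physical point.
* Sustained-activity flag: true iff max_x u(x,t) stays above a threshold at
  every sampled t ≥ t_check — the operational re-entry detector: after a
  plain S1 beat the tissue repolarizes; a re-entrant circuit keeps a front
  alive indefinitely.

## Benchmarks and fixtures (what the generator emulates)

`test1_1` reproduces the printed slab protocol in full (degree-3 splines,
N_h = 5705, Δt = 0.05 ms, N_t = 1500, N_train = 11, N_test = 10 midpoints,
N = 256, n = 2, batch 40, learning rate 2·10⁻⁴, up to 20 000 epochs,
early-stopping patience 1000).  It is hours-scale on a workstation and is
shipped for completeness, not run by the tests.

The desk-scale fixtures keep the physics family but change four things,
each forced by a measured property of the reduced setting:

1. **Δt = 0.1 ms** (not 0.2): with the explicit ionic treatment the R-M
   reaction Jacobian (~0.2 ms⁻¹ near the peak) makes 0.2 ms unstable.
2. **Focal (ball) S1** at the left edge (the atrial benchmarks' stimulus
   form, 60 mA for 1 ms) instead of the half-space stimulus: the planar
   protocol's snapshot rank equals the number of x-direction basis
   functions (the fields are 1-D), which is *below* the fixture POD
   dimensions — a planar fixture cannot exercise the compression stage
   meaningfully.
3. **Conductivities scaled up at milder anisotropy**
   (σ_l^i = 1.84·10⁻², σ_t^i = 9.6·10⁻³, σ_t^e = 8·10⁻³ Ω⁻¹cm⁻¹;
   μ = σ_l^e ∈ [1.2·10⁻², 1.2·10⁻¹]): focal waves see the transverse
   conductivity, whose printed value would need meshes several times finer
   than the fixtures'; the widened front stays resolved (the solver guard
   verifies this across the whole μ range).
4. **Post-stimulus sampling window** (t ∈ [2, T]): during the 1 ms stimulus
   the elliptic response ‖u_e‖ is ~50–100× its propagation-era magnitude;
   a min-max normalization over the transient squashes the entire
   propagation era of u_e into a sliver of the unit interval.  Windowed
   sampling (exactly like the re-entry protocol's (300, 500) ms window in
   the source setting) keeps both channels learnable.

Consequences for interpretation: passing fixture tests demonstrates the
pipeline end to end on genuinely 2-D, resolved, multi-parameter dynamics at
desk scale; it does not certify accuracy at the printed slab's sharper
fronts, its 10:1 anisotropy, or its 20 000-epoch training budget, and no
fixture number should be compared against the full-scale printed protocol.

The re-entry slab (`reentry_slab`) replaces the out-of-scope atrial surface
with a 6 × 6 cm slab: planar S1 at t = 0, focal S2 (ball radius 1.2 cm,
center the 2-D parameter μ) delivered in the repolarization wake at
t = 60 ms.  A shortened-recovery R-M variant (η2 = 0.03, APD ≈ 43 ms at the
cell level) makes the re-entrant wavelength (conduction velocity × APD) fit
the domain.  An S2 inside the vulnerable window induces a figure-of-eight
re-entry (sustained-activity flag true 100 ms after S2 ends); an early S2
(t = 40 ms, fully refractory tissue) or no S2 leaves the flag false.

## Numerical edge cases

* Sampled output instants snap to the time grid; colliding instants are a
  configuration error, not silently deduplicated.
* `randomized_pod` refuses N above the numerical rank
  (max(m,n)·eps·σ₁ threshold) rather than padding.
* Degenerate normalization ranges map to 0.5 (warning).
* Elliptic and parabolic solves run on one reused LU factorization; the
  elliptic residual is checked against its tolerance every step.
* Training aborts with the epoch index if the loss turns non-finite.

## Known limitations

* Rectangular slabs only; the curved atrial surface geometry (and
  image-based geometry construction) is out of scope, as is multi-fidelity
  pretraining and electrogram computation.
* The IMEX scheme's explicit reaction imposes Δt ≲ 0.1 ms for R-M-class
  stiffness; no operator splitting alternatives are provided.
* The network engine is plain numpy: ideal for desk-scale reproducibility,
  not for the full printed training budgets (hours on GPU in the source
  setting).
* One Gauss–Seidel pass per step for the u/u_e coupling; a monolithic
  solve is a possible extension.
* With only a handful of training parameter instances, generalization to
  *unseen* parameter values is sensitive to the training run's random seed:
  the validation split holds out (t, μ) pairs but draws them from the
  training instances, so it cannot detect overfitting along the parameter
  axis.  The shipped benchmarks pin their seeds (they are part of the
  protocol); runs under other seeds can interpolate substantially worse in
  μ even at lower validation loss.  Denser parameter sampling or a
  validation split by whole parameter instances would harden this.
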