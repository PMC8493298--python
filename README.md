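# cardiorom

Reduced-order modelling of cardiac tissue electrophysiology: a Bidomain
full-order model (tensor-product B-spline Galerkin in space, semi-implicit
BDF2 in time) with phenomenological Aliev-Panfilov / Rogers-McCulloch
kinetics, randomized-POD snapshot compression, and a non-intrusive
deep-learning surrogate that reconstructs transmembrane and extracellular
potentials in real time for new parameter instances — including S1-S2
re-entry protocols.

## Who this is for

Computational electrophysiology groups who need *many* tissue-scale
simulations — parameter sweeps over conductivities or stimulation sites,
vulnerability analyses, re-entry induction studies — where a full-order
solve per query is too slow.  The package trains a surrogate once on a
modest set of full-order trajectories and then evaluates new scenarios in
milliseconds.

## The model

The tissue is a two-phase conductor (intracellular/extracellular), giving
the parabolic–elliptic Bidomain system for the transmembrane potential `u`
and extracellular potential `u_e`, coupled to a single recovery variable
`w`:

    du/dt − div(D_i ∇u) − div(D_i ∇u_e) + I_ion(u, w) = I_app^i
    −div(D_i ∇u) − div((D_i + D_e) ∇u_e)              = I_app^i + I_app^e
    dw/dt = g(u, w)

with insulation (Neumann) boundaries, axisymmetric conductivity tensors
`D = σ_t I + (σ_l − σ_t) f0 ⊗ f0` around the fiber direction `f0`, and the
cubic ionic models of Aliev-Panfilov or Rogers-McCulloch for `(I_ion, g)`.

The reduced-order model approximates the parametrized solution map
`(t, μ) ↦ V^T u_h(t; μ)`:

1. full-order trajectories at `N_train` parameter instances are stacked
   into snapshot matrices (one per field channel);
2. a randomized SVD gives an orthonormal basis `V` of dimension `N`;
3. a deep feedforward network maps `(t, μ)` to `n`-dimensional latent
   coordinates (`n = n_μ + 1` by default — the intrinsic dimension of the
   solution manifold) and a decoder expands them to the `N` intrinsic
   coordinates; an encoder regularizes the latent space during training
   through the joint loss
   `ω_h/2 ‖V^T u_h − ũ_N‖² + (1−ω_h)/2 ‖ũ_n − u_n‖²`;
4. online, `ũ_h(t; μ) = V · decoder(dfnn(t, μ))` — no equations are solved.

Accuracy is measured by the testing-set error indicator
`ε_rel = mean_i sqrt(Σ_k ‖u_h^k − ũ_h^k‖² / Σ_k ‖u_h^k‖²)`, which is
bounded below by the same indicator of the orthogonal projection
`V V^T u_h` — an exact inequality the pipeline asserts on every evaluation.

See `docs/methods.md` for the numerical choices (IMEX-BDF2 scheme, elliptic
compatibility handling, normalization, the sinusoidal decoder lift) and the
design of the reduced-scale benchmarks.

## Worked example

`examples/04_train_surrogate.py` runs the whole pipeline on the tiny slab
benchmark (4 × 1 cm slab, Rogers-McCulloch kinetics, focal stimulus, the
longitudinal extracellular conductivity as parameter, 5 training / 2
testing instances):

```
$ python examples/04_train_surrogate.py
benchmark: tiny_slab  (N = 64, n = 2)
  channel u : epsilon_rel = 8.931e-02   projection lower bound = 8.218e-04
  channel ue: epsilon_rel = 3.143e-01   projection lower bound = 3.563e-03
stage timings (s): {'design': 0.0, 'simulate': 1.6, 'compress': 0.0, 'train': 15.9, 'evaluate': 0.0}
```

Reading the numbers: `epsilon_rel` is the relative reconstruction error of
the surrogate on parameter instances it never saw; the projection lower
bound is the best any reconstruction through the same 64-dimensional POD
basis could do.  The surrogate sits above the bound (it must) and the gap
is what training buys down.  The other examples show single-cell action
potentials (`01`), planar wavefronts and conduction velocities (`02`), POD
compression diagnostics (`03`), and S1-S2 re-entry induction (`05`).

A thin command-line interface wraps the same pipeline:

```bash
cardiorom fixture --scale small --output small.yaml
cardiorom pipeline --config small.yaml --output runs/small --seed 0
```

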