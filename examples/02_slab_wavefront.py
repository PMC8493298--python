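"""Planar wavefront on a tissue slab: activation map and conduction velocity.

Runs the Bidomain full-order model on a 4 x 1 cm slab (p = 2 splines) with a
half-space stimulus at the left edge, then reports midline activation times
and the conduction velocity for two longitudinal extracellular
conductivities (the benchmark's parameter).
"""

import numpy as np

from cardiorom import (
    ConductivityModel,
    PRESETS,
    SolverConfig,
    StimulusSpec,
    activation_map,
    build_spline_space,
    evaluate_basis,
    make_fiber_field,
    simulate,
)

space = build_spline_space(2, (32, 8), ((0.0, 4.0), (0.0, 1.0)))
fiber = make_fiber_field(space, "constant", (1.0, 0.0))
cond = ConductivityModel(1.84e-2, 9.6e-3, 2.4e-2, 8e-3, fiber=fiber,
                         param_map={"sigma_l_e": 0})
stim = StimulusSpec(amplitude=100.0, region="half_space", x0=0.2,
                    t_start=0.0, t_end=1.0)
cfg = SolverConfig(dt=0.1, T=40.0, n_save=200)

xs = np.linspace(1.0, 3.8, 15)
B, _, _ = evaluate_basis(space, np.column_stack([xs, 0.5 * np.ones_like(xs)]))

for mu in (1.2e-2, 4.8e-2):
    traj = simulate(space, cond, PRESETS["test1_1_rm"], [stim], cfg, mu=[mu])
    ac = activation_map(np.asarray(B @ traj.u), traj.times)
    cv = (xs[-1] - xs[0]) / (ac[-1] - ac[0])
    print(f"sigma_l_e = {mu:.3g} 1/(Ohm cm): midline activation "
          f"{ac[0]:.1f} -> {ac[-1]:.1f} ms over {xs[0]:.1f} -> {xs[-1]:.1f} cm "
          f"(CV ~ {10 * cv:.1f} mm/ms)")

print("\nActivation time grows monotonically with distance from the stimulus;"
      "\nraising the longitudinal conductivity speeds conduction up.")
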