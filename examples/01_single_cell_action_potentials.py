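"""Single-cell (space-clamped) action potentials of the two ionic models.

Integrates the 0-D cell ODEs du/dt = -I_ion(u, w) + I_app(t), dw/dt = g(u, w)
for the Aliev-Panfilov (dimensionless) and Rogers-McCulloch (mV) models with
a brief suprathreshold stimulus, and prints the AP peak and duration.
"""

import numpy as np
from scipy.integrate import solve_ivp

from cardiorom import PRESETS, potential_scale, reaction_terms

for name, params, repol_frac in [("Aliev-Panfilov", PRESETS["test1_2_ap"], 0.1),
                                 ("Rogers-McCulloch", PRESETS["test1_1_rm"], 0.1)]:
    scale = potential_scale(params)

    def rhs(t, y):
        i_ion, g = reaction_terms(params, y[0], y[1])
        stim = 0.5 * scale if t <= 1.0 else 0.0
        return [-i_ion + stim, g]

    sol = solve_ivp(rhs, (0.0, 400.0), [0.0, 0.0], rtol=1e-8, atol=1e-10,
                    dense_output=True)
    ts = np.linspace(0.0, 400.0, 8000)
    u = sol.sol(ts)[0]
    peak = u.max()
    above = ts[u > repol_frac * scale]
    apd = above.max() - above.min() if len(above) else 0.0
    unit = "" if scale == 1.0 else " mV"
    print(f"{name}: peak u = {peak:.3g}{unit}, "
          f"duration above {repol_frac:.0%} of peak = {apd:.1f} ms")

print("\nThe peak approaches the model's peak potential (1 for A-P, 100 mV for"
      "\nR-M); the durations are the plateau lengths the tissue model inherits.")
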