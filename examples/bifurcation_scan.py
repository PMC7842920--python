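"""Map the oscillatory window of the PLC-driven subsystem.

Treats the fraction of active PLC as a constant parameter of the
(c, y, p) subsystem (small-dose constants, dose frozen at 1 ug/ml) and
scans it: the resting state loses stability at a lower Hopf bifurcation,
oscillates inside the window, and restabilizes at an upper Hopf point —
the classic "Hopf bubble".
"""

import numpy as np

from calbeta import (
    DoseParams,
    InjectionProtocol,
    equilibrium_branch,
    find_hopf,
    orbit_envelope,
)

params = DoseParams.small_doses()
proto = InjectionProtocol(a=1.0, frozen=True)
grid = np.linspace(1e-5, 0.02, 80)

branch = equilibrium_branch("subsystem_cyp", params, proto, "PLC", grid)
hopf = find_hopf(branch)
print("Hopf bifurcations in PLC (K_s = 0.15):")
for h in hopf:
    print(f"  PLC = {h.param_value:.4f}, angular frequency {h.frequency:.3f} rad/s")

inside = 0.5 * (hopf[0].param_value + hopf[1].param_value)
env = orbit_envelope("subsystem_cyp", params, proto, "PLC",
                     np.array([inside]), t_transient=500, t_window=500)
print(f"\nAt PLC = {inside:.4f} (inside the bubble) the Ca2+ attractor swings "
      f"between {env.c_min[0]:.3f} and {env.c_max[0]:.3f} uM — sustained "
      "oscillations between the two Hopf points.")
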