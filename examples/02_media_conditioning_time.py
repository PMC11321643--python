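"""How long does cell-free medium take to reach a hypoxic setpoint?

Simulates normoxic medium (18.6 % O2) placed in a 1 % O2 incubator and
reports the time for the vessel-bottom tension to come within 0.1 % O2 of
the setpoint — the practical "conditioning time" before a hypoxia
experiment can start at its nominal tension.
"""

import numpy as np

from pericell import (
    GasSchedule,
    MediaColumn,
    TransportParams,
    simulate_diffusion,
    time_to_threshold,
)

transport = TransportParams()  # D = 0.09684 cm2/h, kL = 0.1 cm/h
schedule = GasSchedule.constant(1.0)

print("Conditioning time to 1% +/- 0.1% O2 at the vessel bottom:")
for vessel, volume in [("6-well", 1.0), ("6-well", 2.0),
                       ("24-well", 1.0), ("24-well", 2.0)]:
    column = MediaColumn.from_vessel(vessel, volume)
    t = np.linspace(0.0, 300.0, 3001)
    field = simulate_diffusion(column, transport, 18.6, schedule, t)
    hours = time_to_threshold(t, field.pericellular_trace(), target=1.0, tol=0.1)
    print(f"  {vessel:8s} {volume:.0f} mL (L = {column.height_cm:.3f} cm): "
          f"{hours:6.1f} h")

# The same volume equilibrates several-fold slower in a 24-well than a
# 6-well: a smaller growth area means a taller column, a longer diffusion
# path and a smaller interface-to-volume ratio.
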