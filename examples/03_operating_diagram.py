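"""Map reactor fate over the operating plane (inlet ammonium x dilution).

Each cell of the grid gets the survivor sets of its stable equilibria
(ecological diagram) and the collapsed operational label (operating
diagram): CN = complete nitrification, PN = partial nitrification
(NOB washed out, nitrite accumulates), WO = washout.
"""

import numpy as np

from chemotrack import CommunityModel, ecological_diagram, operating_diagram

model = CommunityModel.build(
    groups=[1, 2], mu_max=[0.77, 1.07], K=[0.7, 0.3], inv_yield=[3.98, 16.12],
    A=[[-0.1, 0.0], [-2.5, -0.1]],     # strong AOB-on-NOB inhibition
)

s_axis = np.linspace(0.25, 2.0, 8)
d_axis = np.linspace(0.08, 0.88, 9)
eco = ecological_diagram(model, s_axis, d_axis)
od = operating_diagram(eco)

print("rows: s_in [g/L] (top = high), columns: D [1/day] (left = low)\n")
header = "s_in\\D " + " ".join(f"{d:5.2f}" for d in d_axis)
print(header)
for i in reversed(range(s_axis.size)):
    row = " ".join(f"{'/'.join(od.labels(i, j)):>5s}" for j in range(d_axis.size))
    print(f"{s_axis[i]:6.2f} {row}")

# The PN wedge at low dilution and high inlet is the interaction effect:
# more inlet ammonium means more AOB biomass, and with a21 < 0 that
# biomass suppresses the NOB below break-even even though nitrite is
# plentiful.  Without interactions those cells would all be CN.  Raising
# the inlet at constant D can therefore *remove* the second oxidation
# step -- an operating intuition pure Monod models cannot produce.
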