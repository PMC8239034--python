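"""Compare the two species' functional responses and find the crossover.

A. lapachosus has the steeper density-dependent attack rate but the
longer handling time, so it out-attacks A. cachamai at low host
densities and is overtaken at high ones.  The script prints both
expected-attack curves and the largest density at which A. lapachosus
is still ahead.
"""

import numpy as np

from igparasitoid import FRFamily, crossover_density, expected_attacked
from igparasitoid.reference import CACHAMAI, FR_MEANS, LAPACHOSUS

densities = np.arange(10, 121, 10, dtype=float)
cach = expected_attacked(FR_MEANS[CACHAMAI], FRFamily.FRIII_G, False, densities)
lapa = expected_attacked(FR_MEANS[LAPACHOSUS], FRFamily.FRIII_G, False, densities)

print("density  A.cachamai  A.lapachosus  (expected hosts attacked / 24 h)")
for p, rc, rl in zip(densities, cach, lapa):
    marker = "<-- lapachosus ahead" if rl > rc else ""
    print(f"{p:7.0f}  {rc:10.2f}  {rl:12.2f}  {marker}")

crossover = crossover_density(
    FR_MEANS[CACHAMAI], FR_MEANS[LAPACHOSUS], FRFamily.FRIII_G, depletion=False
)
print(f"\nA. lapachosus is the more efficient species up to {crossover} hosts;")
print("above that density A. cachamai attacks more (its handling time is 10x shorter).")
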