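"""Map the dynamical regimes of a single Wilson-Cowan node.

Depending on the static external inputs, the node sits in a low-activity
(down) or high-activity (up) fixed point, oscillates, or is bistable
between down and up.  This prints a coarse map of the input plane.
"""

import numpy as np

from oscontrol import classify_regime

symbols = {"down": ".", "up": "#", "oscillatory": "o", "bistable": "B",
           "unclassified": "?"}

e_grid = np.linspace(0.0, 4.0, 11)
i_grid = np.linspace(2.0, 0.0, 9)

print("I_ext \\ E_ext:", "  ".join(f"{e:4.1f}" for e in e_grid))
for i_ext in i_grid:
    row = [symbols[classify_regime(e_ext, i_ext)] for e_ext in e_grid]
    print(f"{i_ext:10.2f}   ", "     ".join(row))
print("\n. = down   # = up   o = oscillatory   B = bistable (down/up)")
print("The oscillatory tongue sits between the down and up regions; the")
print("bistable strip appears at strong excitatory and inhibitory drive.")
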