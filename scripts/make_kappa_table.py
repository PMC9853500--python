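"""Generate the packaged kappa lookup table.

Enumerates every response pattern reachable under the default up-down
protocol (8 filaments, start at 0.4 g = index 3, stop 4 measurements
after the first response), reconstructs the boundary-clamped staircase
levels in delta units, and computes the ML estimate of the 50% point
under the normal-ogive model with unit (= delta) scale, bounded to
+/-2 delta of the final level.  kappa = mu_hat - x_final.
"""

import itertools
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

N_FIL = 8
START = 3
STOP_AFTER = 4
BOUND = 2.0


def levels_for(pattern: str) -> list[int]:
    lv = [START]
    for c in pattern[:-1]:
        nxt = lv[-1] + (1 if c == "O" else -1)
        lv.append(min(max(nxt, 0), N_FIL - 1))
    return lv


def kappa(pattern: str) -> float:
    lv = np.asarray(levels_for(pattern), float)
    resp = np.array([c == "X" for c in pattern])
    xf = lv[-1]

    def nll(mu):
        z = lv - mu
        return -float(np.sum(np.where(resp, norm.logcdf(z), norm.logcdf(-z))))

    res = minimize_scalar(nll, bounds=(xf - BOUND, xf + BOUND),
                          method="bounded", options={"xatol": 1e-8})
    return float(res.x - xf)


rows = []
for lead in range(0, N_FIL - START):      # leading no-response run: 0..4
    for tail in itertools.product("OX", repeat=STOP_AFTER):
        pat = "O" * lead + "X" + "".join(tail)
        rows.append((pat, kappa(pat)))

with open("src/painprint/data/kappa_table_computed.csv", "w") as fh:
    fh.write("pattern,kappa\n")
    for pat, k in rows:
        fh.write(f"{pat},{k:.6f}\n")
print(f"{len(rows)} patterns written")
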