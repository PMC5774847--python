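"""Interference records far beyond brute force, via the lattice backend.

For powers of the second-order algebraic number sigma - 1/2 the interference
statistic decays at the generic rate only up to a critical distance, beyond
which the second-order character takes over and the decay steepens to 1/l.
The sup-norm shortest-vector sweep finds the records out to l ~ 1e9, where
direct scanning is hopeless; the brute-force scan cross-checks the overlap.
"""

import numpy as np

from gridcode import ScaleSystem
from gridcode.diophantine import record_lows_M
from gridcode.lattice import sweep_records

system = ScaleSystem.geometric("phi-1/2", 5)
lattice_records = sweep_records(system, 1, 10**9)
brute_records = record_lows_M(system, 10**6)

print("lattice records (l, gap):")
for r in lattice_records:
    print(f"  {r.l:>10d}  {r.gap:.3e}")
agree = [r.l for r in lattice_records if r.l <= 10**6] == [r.l for r in brute_records]
print("brute-force cross-check up to 1e6:", "agree" if agree else "DISAGREE")

ls = np.array([r.l for r in lattice_records], dtype=float)
gs = np.array([r.gap for r in lattice_records])
early, late = ls <= 10**3, ls >= 10**4
print("early log-log slope:", round(np.polyfit(np.log(ls[early]), np.log(gs[early]), 1)[0], 2),
      " (generic decay, exponent -1/(M-1) = -0.25)")
print("late  log-log slope:", round(np.polyfit(np.log(ls[late]), np.log(gs[late]), 1)[0], 2),
      " (second-order regime, exponent -1)")
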