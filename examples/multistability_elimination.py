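"""Multistability elimination at strongly negative memristor coupling.

When the coupling k drops below about -6.5 the coexistence disappears: both
initial conditions end on the same attractor, the run started at (5,0,0)
merging after a long quiescent transient.  This demo measures the merging
time at k=-7 and brackets the elimination boundary on a coarse k grid.
"""

import numpy as np

from memhr import (ModelParams, DriveParams, detect_coexistence,
                   convergence_time, elimination_threshold)

drive = DriveParams(A1=3.0, f1=0.5)
ics = ((-5.0, 0.0, 0.0), (5.0, 0.0, 0.0))

for k in (1.0, -7.0):
    res = detect_coexistence(ModelParams(k=k), drive, ics, t_end=2000.0)
    print(f"k={k:+5.1f}: coexists={res.coexists} "
          f"(fingerprint distance {res.distance:.2f})")

ct = convergence_time(ModelParams(k=-7.0), drive, ics, t_end=2000.0)
print(f"\nk=-7: the (5,0,0) run merges into the chaotic-bursting attractor "
      f"near t ~ {ct:.0f}")

res = elimination_threshold(np.arange(-8.0, -5.99, 0.5), ModelParams(),
                            drive, ics, t_end=1500.0)
print(f"coarse elimination boundary: largest merged k ~ {res.critical_k}")
print("\nMeaning: below the boundary every tested initial condition reaches "
      "the same long-run firing pattern — the memristor coupling acts as a "
      "multistability control knob.")
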