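"""MAPK double-phosphorylation cascade on the mesh hierarchy.

A kinase KK phosphorylates the substrate K twice (K -> Kp -> Kpp) through
enzyme-substrate complexes, a phosphatase P reverses both steps, and each
catalytic release leaves the enzyme transiently inactive (KK*, P*).  With
diffusion-limited association and fast enzyme recovery, the distributive
cascade becomes partly processive through rapid enzyme-substrate rebinds —
spatial detail a well-mixed model cannot capture.  All 11 species start on
the finest mesh and coarsen as they diffuse.  (The published setup runs
200 trajectories to 50 s; this example runs a small ensemble to 2 s.)
"""

import numpy as np

from hrdme import ensemble_series, fixture, run_ensemble

model = fixture("mapk")
n, t_final = 5, 2.0
times = np.linspace(0.0, t_final, 9)

trajs = run_ensemble(model, n, t_final, times, seed=7)

print(model.describe().splitlines()[0])
print(f"{n} trajectories to t = {t_final} s\n")
print(f"{'t':>5} " + " ".join(f"{s:>6}" for s in ("K", "Kp", "Kpp", "KK", "P")))
series = {s: ensemble_series(trajs, s) for s in ("K", "Kp", "Kpp", "KK", "P")}
for i, t in enumerate(times):
    print(f"{t:>5.2f} " + " ".join(f"{series[s].mean[i]:>6.1f}"
                                   for s in series))
print("\nKpp rises as the kinase arm works through the substrate pool; "
      "free KK/P dip while sequestered in complexes.")
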