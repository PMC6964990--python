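"""Fast-rebinding chain S1 -> S11 + S12 -> S2: hierarchy vs well-mixed.

100 S1 molecules dissociate into product pairs that usually re-associate
within microseconds because they are born in the same fine voxel.  A
well-mixed model forgets that spatial correlation and converts S1 to S2
noticeably slower.  The hierarchical solver keeps the correlation (the
products start on the 64^3 mesh) while carrying S1 and S2 on the
single-voxel level.
"""

import numpy as np

from hrdme import child_seeds, ensemble_series, fixture, run_ensemble, ssa_run

model = fixture("single_layer")
n, t_final = 100, 1.0
times = np.linspace(0.0, t_final, 11)

hier = ensemble_series(
    run_ensemble(model, n, t_final, times, seed=3), "S2")
wm = ensemble_series(
    [ssa_run(model, t_final, times, seed=int(s)) for s in child_seeds(4, n)],
    "S2")

print(f"mean S2 copy number, {n} trajectories")
print(f"{'t':>5} {'hierarchy':>10} {'well-mixed':>11}")
for i, t in enumerate(times):
    print(f"{t:>5.1f} {hier.mean[i]:>10.2f} {wm.mean[i]:>11.2f}")
x = hier.at_time(1.0)
print(f"\nat t = 1.0 s: mean {x.mean():.1f}, SD {x.std(ddof=1):.2f} "
      "(expect roughly 58.8 and 4.8)")
print("the well-mixed curve lags because it misses the fast rebinds that "
      "convert S11 + S12 to S2 almost immediately after each dissociation")
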