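"""Rebinding-time distribution: hierarchy vs fine single mesh.

Collects dissociation-to-reassociation times of the reversible pair
S1 + S2 <-> S3.  The hierarchical run resolves the products on the 64^3
mesh right after each dissociation and coarsens them as they diffuse; the
reference pins everything to the 64^3 mesh throughout.  The two
distributions should be statistically indistinguishable — at a fraction
of the event count.  (A publication-scale comparison uses >= 1e4 events;
this example runs 2000 to stay quick.)
"""

import numpy as np
from scipy import stats

from hrdme import fixture, rebind_sample

model = fixture("rebind")
n = 2000

hier = rebind_sample(model, n, seed=1, C=20.0)
ref = rebind_sample(model, n, seed=2, single_mesh_level=6)

print(f"{n} rebind events per sample")
print(f"{'':>16} {'hierarchy':>12} {'64^3 mesh':>12}")
for label, f in (("median", lambda d: f"{np.median(d):>12.3e}"),
                 ("P(< 1 ms)", lambda d: f"{np.mean(d < 1e-3):>12.3f}"),
                 ("mean", lambda d: f"{d.mean():>12.3f}")):
    print(f"{label:>16} {f(hier.durations)} {f(ref.durations)}")
ks = stats.ks_2samp(hier.durations, ref.durations)
print(f"\ntwo-sample KS: statistic {ks.statistic:.4f}, p = {ks.pvalue:.3f}")
print("p > 0.05 means the hierarchical solver preserves the fine-mesh "
      "rebinding statistics, including the sub-millisecond rebinds that a "
      "coarse mesh cannot represent.")
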