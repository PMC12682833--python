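"""Deep-rooting traits from a single synthetic root profile.

Builds a root profile whose per-image root length declines logistically with
depth, then computes DeepRoot40 (the depth below which 40 cm of cumulative
root length is observed — deeper is better), the sigmoid-inflection rooting
depth proxy, pRLD in 30-cm bins, and an interval root length.
"""

import numpy as np

from rhizotrace import TubeGeometry, bin_profile, deep_root_threshold, interval_root_length, sigmoid_inflection
from rhizotrace.root_traits import RootProfile

geom = TubeGeometry()
depths = geom.image_depths_m()
rng = np.random.default_rng(7)
expected = 2.0 / (1.0 + np.exp(0.05 * (depths * 100.0 - 120.0)))  # midpoint 120 cm
observed = expected * rng.lognormal(0.0, 0.3, depths.size)
profile = RootProfile("row-1", "2023-06", depths, observed)

print(f"total root length along the tube: {profile.total_length_cm:.1f} cm")
print(f"DeepRoot40: {deep_root_threshold(profile):.1f} cm "
      "(40 cm of root observed below this soil depth)")
print(f"sigmoid inflection: {sigmoid_inflection(profile):.1f} cm "
      "(transition from dense shallow to sparse deep roots)")
print(f"root length at 1.6-1.8 m (tracer depth): "
      f"{interval_root_length(profile, 1.6, 1.8):.2f} cm")

binned = bin_profile(profile, geom)
print("\npRLD by 30-cm depth bin (cm of root per cm^2 of image):")
for lo, hi, prld in zip(binned.bin_edges_m[:-1], binned.bin_edges_m[1:], binned.prld_cm_per_cm2):
    print(f"  {lo:.2f}-{hi:.2f} m: {prld:.3f}")
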