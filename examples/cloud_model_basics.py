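"""Backward and forward cloud transformations on a single criterion.

Estimates cloud parameters (Ex, En, He) from simulated Likert-like scores,
then regenerates droplets from them and checks the round trip.
"""

import numpy as np

from climacop import BackwardCloudConfig, backward_cloud, forward_cloud, membership

rng = np.random.default_rng(0)
scores = rng.normal(4.3, 0.6, size=5000)  # one group's responses on one item

cloud = backward_cloud(scores, BackwardCloudConfig(c=30, d=200, seed=1))
print(f"estimated cloud: Ex={cloud.ex:.4f} En={cloud.en:.4f} He={cloud.he:.4f}")
# Ex tracks the group's mean answer, En its spread, He the instability of
# that spread (near 0 here because the simulated variance is homogeneous).

batch = forward_cloud(cloud, 100_000, seed=2)
print(f"droplet mean over {batch.n:,} draws: {batch.mean:.4f} (expect Ex)")
print(f"droplet sd: {batch.droplets.std():.4f} (expect ~sqrt(En^2+He^2)={np.hypot(cloud.en, cloud.he):.4f})")

mu = membership(cloud.ex + cloud.en, cloud, enn=cloud.en)
print(f"membership one entropy from center: {mu:.4f} (exp(-1/2)={np.exp(-0.5):.4f})")
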