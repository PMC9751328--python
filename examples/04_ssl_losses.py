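"""The two self-supervised objectives on small, transparent inputs.

InfoNCE reduces to log(K+1) when the positive is indistinguishable from K
negatives; the redundancy-reduction loss is zero exactly when the
cross-correlation of the two views' embeddings is the identity.
"""

import numpy as np

from semssl import barlow_twins_loss, cross_correlation, info_nce
from semssl.nn import Tensor, batch_norm

rng = np.random.default_rng(0)

# --- contrastive ----------------------------------------------------------
d, K = 8, 5
q = np.zeros((1, d)); q[0, 0] = 1.0
k_pos = np.zeros((1, d)); k_pos[0, 1] = 1.0       # similarity 0, like all negs
negs = np.zeros((K, d)); negs[:, 2] = 1.0
loss = info_nce(q, k_pos, negs, tau=0.2).item()
print(f"uninformative positive among {K} negatives: "
      f"InfoNCE = {loss:.6f}  (log(K+1) = {np.log(K + 1):.6f})")

# --- non-contrastive ------------------------------------------------------
z = batch_norm(Tensor(rng.standard_normal((32, 6))))
C_self = cross_correlation(z, z)
print(f"identical views:  diagonal of C = "
      f"{np.round(np.diag(C_self.data), 3)},  "
      f"loss = {barlow_twins_loss(np.eye(6)).item():.1f}")
C_zero = np.zeros((6, 6))
print(f"uncorrelated views (C = 0): loss = {barlow_twins_loss(C_zero).item():.1f} "
      f"= embedding dimension (pure invariance penalty)")
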