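"""Optimal hard thresholding of singular values on a planted-rank matrix.

Plants 18 orthogonal components 1.5x above the Gavish-Donoho cutoff in a
1600 x 368 noise matrix (the 10-second training-set shape) and shows that the
threshold retains exactly those 18 components while a pure-noise matrix keeps
essentially none.
"""

import numpy as np

from vtwarn.pca import fit_decomposition, gavish_donoho_omega

m, n = 1600, 368
rng = np.random.default_rng(3)
omega = gavish_donoho_omega(n / m)
print(f"omega({n}/{m} = {n/m:.3f}) = {omega:.3f}")

noise = rng.standard_normal((m, n))
tau = omega * float(np.median(np.linalg.svd(noise, compute_uv=False)))
U = np.linalg.qr(rng.standard_normal((m, 18)))[0]
V = np.linalg.qr(rng.standard_normal((n, 18)))[0]
X = 1.5 * tau * (U @ V.T) + noise

decomp = fit_decomposition((X - X.mean(axis=0)) / X.std(axis=0))
print(f"planted rank 18 -> retained k = {decomp.k} (tau* = {decomp.threshold.tau_star:.2f})")

noise_only = fit_decomposition((noise - noise.mean(axis=0)) / noise.std(axis=0))
print(f"noise only      -> retained k = {noise_only.k}")
# k counts singular values above tau* = omega(beta) * median(singular values);
# it recovers the planted rank and collapses to ~1 on pure noise.
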