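"""Two-stage compression: Nyström feature map, then a random Fourier sketch.

Fits the landmark-based feature map on a synthetic matrix, measures how well
the finite-dimensional embeddings reproduce the exact kernel, and compresses
the whole dataset into a single complex vector whose length is independent
of the number of chromatograms.
"""

import numpy as np

from chickn import (
    KernelConfig,
    derive_parameters,
    estimate_gamma,
    estimate_sigma2,
    generate_matrix,
    gram_matrix,
    nystrom_fit,
    sample_frequencies,
    sketch,
    two_cluster_spec,
)

matrix, labels = generate_matrix(two_cluster_spec(seed=1, columns_per_cluster=40))
N = matrix.n_columns
sizes = derive_parameters(N, k=2, k_total=8)
print(f"N={N} columns -> l={sizes['l']} landmarks, rank s={sizes['s']}, "
      f"sketch m={sizes['m']}, depth T={sizes['T']}")

rng = np.random.default_rng(0)
landmarks = np.sort(rng.choice(N, sizes["l"], replace=False))
gamma = estimate_gamma(matrix.columns(landmarks), nu=8, p=2, reciprocal=True)
cfg = KernelConfig(p=2, gamma=gamma)

model = nystrom_fit(matrix, l=sizes["l"], r=sizes["l"] // 2,
                    s=min(sizes["s"], sizes["l"] // 2), cfg=cfg,
                    landmark_indices=landmarks)
emb = model.embed(np.asarray(matrix.values))
exact = gram_matrix(np.asarray(matrix.values), cfg)
err = np.abs(emb @ emb.T - exact).max()
print(f"max |<phi(x), phi(y)> - k(x, y)| = {err:.2e} "
      f"(rank-{model.s} approximation of the {N}x{N} Gram)")

sigma2 = estimate_sigma2(model, matrix, seed=0)
freqs = sample_frequencies(sizes["m"], model.s, sigma2, seed=0)
sk = sketch(matrix, np.arange(N), model, freqs)
print(f"sigma^2 = {sigma2:.3f}; sketch = {sk.values.shape[0]} complex numbers "
      f"summarizing {sk.n_points} profiles")
print(f"largest sketch modulus = {np.abs(sk.values).max():.4f} "
      f"(bound 1/sqrt(m) = {1 / np.sqrt(freqs.m):.4f})")
# Clustering now only needs this m-vector: its cost no longer depends on N.
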