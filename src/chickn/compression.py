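"""Nyström kernel approximation and random-Fourier-feature data sketching.

The full N x N kernel Gram matrix of a large chromatogram collection is never
formed.  Instead:

1. *Nyström*: l landmark columns are sampled uniformly; the l x l landmark
   Gram W and the landmark similarities k_x of any column x define an explicit
   finite-dimensional feature map phi~(x) in R^s with
   <phi~(x), phi~(y)> ~ k(x, y) (K ~ C W^+ C^T at rank s).
2. *Sketching*: the whole embedded dataset is summarized by a single complex
   m-vector, the empirical average of random Fourier features
   exp(-i w_j^T phi~(x)) over sampled frequencies w_j ~ N(0, (1/sigma^2) I).

Clustering then operates on the sketch alone, independent of N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import KernelConfig, cumulative_profiles, w1_cross_distances

__all__ = [
    "NystromModel",
    "FrequencySet",
    "Sketch",
    "nystrom_fit",
    "estimate_sigma2",
    "sample_frequencies",
    "sketch",
    "sketch_point",
]

_EIG_CLIP = 1e-12  # relative eigenvalue floor when inverting W


@dataclass
class NystromModel:
    """Landmark set plus truncated spectral factors defining the feature map.

    phi~(x) = Sigma_s^{-1/2} U_s^T k_x, where k_x is the l-vector of kernel
    similarities between x and the landmarks.  U_s / sigma_s come from a
    rank-r regularized eigendecomposition of the landmark Gram W followed by
    a rank-s truncation.
    """

    landmark_indices: np.ndarray
    l: int
    r: int
    s: int
    U_s: np.ndarray       # l x s, orthonormal columns
    sigma_s: np.ndarray   # s positive, non-increasing
    cfg: KernelConfig
    landmark_cum: np.ndarray  # rows x l normalized cumulative landmark profiles

    def kernel_to_landmarks(self, columns: np.ndarray) -> np.ndarray:
        """Kernel similarities between given columns (rows x B) and landmarks (B x l)."""
        cum = cumulative_profiles(np.atleast_2d(columns.T).T)
        dist = w1_cross_distances(cum, self.landmark_cum)
        return np.exp(-self.cfg.gamma * dist**self.cfg.p)

    def embed(self, columns: np.ndarray) -> np.ndarray:
        """Feature-space embeddings phi~ of a column block; returns B x s."""
        k_x = self.kernel_to_landmarks(columns)
        return (k_x @ self.U_s) / np.sqrt(self.sigma_s)

    def embed_one(self, x: np.ndarray) -> np.ndarray:
        return self.embed(np.asarray(x, dtype=float).reshape(-1, 1))[0]

    def save(self, path) -> None:
        np.savez(
            path,
            landmark_indices=self.landmark_indices,
            lrs=np.array([self.l, self.r, self.s]),
            U_s=self.U_s,
            sigma_s=self.sigma_s,
            kernel_p=self.cfg.p,
            kernel_gamma=self.cfg.gamma,
            kernel_nu=self.cfg.nu,
            landmark_cum=self.landmark_cum,
        )

    @classmethod
    def load(cls, path) -> "NystromModel":
        z = np.load(path)
        l, r, s = (int(v) for v in z["lrs"])
        cfg = KernelConfig(
            p=int(z["kernel_p"]), gamma=float(z["kernel_gamma"]), nu=int(z["kernel_nu"])
        )
        return cls(z["landmark_indices"], l, r, s, z["U_s"], z["sigma_s"], cfg,
                   z["landmark_cum"])


@dataclass(frozen=True)
class FrequencySet:
    """Sampled Fourier frequencies w_1..w_m (rows of an m x s matrix)."""

    frequencies: np.ndarray
    m: int
    sigma2: float
    seed: int


@dataclass(frozen=True)
class Sketch:
    """Complex m-vector summary of a column set (mean random Fourier feature)."""

    values: np.ndarray
    n_points: int


def nystrom_fit(
    matrix,
    l: int,
    r: int,
    s: int,
    cfg: KernelConfig,
    seed: int = 0,
    landmark_indices: np.ndarray | None = None,
) -> NystromModel:
    """Fit the Nyström feature map from l uniformly sampled landmark columns.

    Pipeline: sample landmarks -> landmark Gram W -> eigendecompose -> clip
    eigenvalues below machine tolerance -> keep rank r -> rank-s truncation by
    a second SVD of the embedded landmark block (numerical stabilization).
    """
    n_cols = matrix.n_columns if hasattr(matrix, "n_columns") else matrix.shape[1]
    if not (1 <= s <= r <= l <= n_cols):
        raise ValueError(f"require 1 <= s <= r <= l <= N, got s={s} r={r} l={l} N={n_cols}")
    if landmark_indices is None:
        rng = np.random.default_rng(seed)
        landmark_indices = np.sort(rng.choice(n_cols, size=l, replace=False))
    else:
        landmark_indices = np.asarray(landmark_indices)
        if len(landmark_indices) != l:
            raise ValueError("landmark_indices length must equal l")

    cols = (
        matrix.columns(landmark_indices)
        if hasattr(matrix, "columns")
        else np.asarray(matrix)[:, landmark_indices]
    )
    cum = cumulative_profiles(cols)
    dist = w1_cross_distances(cum, cum)
    W = np.exp(-cfg.gamma * dist**cfg.p)
    W = (W + W.T) / 2.0

    eigvals, eigvecs = np.linalg.eigh(W)
    eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
    floor = _EIG_CLIP * max(eigvals[0], 1.0)
    valid = eigvals > floor
    if valid.sum() < s:
        raise ValueError(
            f"landmark Gram is rank deficient (rank {int(valid.sum())} < s={s}); "
            "increase l or decrease s"
        )
    keep_r = min(r, int(valid.sum()))
    U_r, sig_r = eigvecs[:, :keep_r], eigvals[:keep_r]

    # embedded landmark block B = Sigma_r^{-1/2} U_r^T W; its rank-s SVD yields
    # the final stabilized factors (here B = Sigma_r^{1/2} U_r^T, so the SVD
    # re-orders nothing but guards against numerically noisy spectra)
    B = (U_r / np.sqrt(sig_r)).T @ W
    _, svals, Vt = np.linalg.svd(B, full_matrices=False)
    # singular values of B are sqrt-eigenvalues of W; square back so that
    # k_x^T U_s Sigma_s^{-1} U_s^T k_y reproduces the Gram at rank s
    sigma_s = svals[:s] ** 2
    U_s = Vt[:s].T  # l x s, orthonormal

    return NystromModel(
        landmark_indices=landmark_indices,
        l=l, r=keep_r, s=s,
        U_s=U_s, sigma_s=sigma_s, cfg=cfg,
        landmark_cum=cum,
    )


def estimate_sigma2(
    model: NystromModel,
    matrix,
    subsample_size: int = 1000,
    seed: int = 0,
) -> float:
    """Estimate the frequency-scale parameter sigma^2 from a small data fraction.

    Default estimator: mean squared norm of the embeddings over a random
    subsample, so that frequency magnitudes (~1/sigma) scale inversely with
    the data spread and the sketch resolves the occupied region of feature
    space.
    """
    n_cols = matrix.n_columns if hasattr(matrix, "n_columns") else matrix.shape[1]
    rng = np.random.default_rng(seed)
    size = min(subsample_size, n_cols)
    idx = np.sort(rng.choice(n_cols, size=size, replace=False))
    cols = (
        matrix.columns(idx)
        if hasattr(matrix, "columns")
        else np.asarray(matrix)[:, idx]
    )
    emb = model.embed(cols)
    sigma2 = float(np.mean(np.sum(emb**2, axis=1)))
    if sigma2 <= 0 or np.allclose(emb, emb[0], atol=1e-15):
        raise ValueError("degenerate embeddings: zero spread, cannot scale frequencies")
    return sigma2


def estimate_sigma2_from_embeddings(embeddings: np.ndarray) -> float:
    """Same estimator applied to a precomputed B x s embedding block."""
    emb = np.asarray(embeddings, dtype=float)
    if emb.size == 0 or np.allclose(emb, emb[0], atol=1e-15):
        raise ValueError("degenerate embeddings: zero spread, cannot scale frequencies")
    return float(np.mean(np.sum(emb**2, axis=1)))


def sample_frequencies(m: int, s: int, sigma2: float, seed: int = 0) -> FrequencySet:
    """Draw m i.i.d. frequency rows from N(0, (1/sigma^2) I_s), reproducibly."""
    if m < 1 or s < 1:
        raise ValueError("m and s must be >= 1")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    freqs = rng.normal(0.0, 1.0 / np.sqrt(sigma2), size=(m, s))
    return FrequencySet(frequencies=freqs, m=m, sigma2=float(sigma2), seed=seed)


def sketch_point(feature_vector: np.ndarray, freqs: FrequencySet) -> np.ndarray:
    """Random Fourier feature of one feature-space point: (1/sqrt(m)) e^{-i W f}."""
    phase = freqs.frequencies @ np.asarray(feature_vector, dtype=float)
    return np.exp(-1j * phase) / np.sqrt(freqs.m)


def sketch(
    matrix,
    column_indices,
    model: NystromModel,
    freqs: FrequencySet,
    chunk: int = 2048,
) -> Sketch:
    """Sketch of a column subset: mean random Fourier feature of its embeddings.

    Component j = (1/(n sqrt(m))) sum_i exp(-i w_j^T phi~(x_i)).  Columns are
    streamed in chunks; the full embedding block is never materialized.
    """
    idx = np.asarray(column_indices)
    if idx.size == 0:
        raise ValueError("cannot sketch an empty column subset")
    acc = np.zeros(freqs.m, dtype=complex)
    for start in range(0, idx.size, chunk):
        sub = idx[start:start + chunk]
        cols = (
            matrix.columns(sub)
            if hasattr(matrix, "columns")
            else np.asarray(matrix)[:, sub]
        )
        emb = model.embed(cols)  # B x s
        phase = emb @ freqs.frequencies.T  # B x m
        acc += np.exp(-1j * phase).sum(axis=0)
    return Sketch(values=acc / (idx.size * np.sqrt(freqs.m)), n_points=int(idx.size))


def sketch_embeddings(embeddings: np.ndarray, freqs: FrequencySet) -> Sketch:
    """Sketch of a precomputed B x s embedding block (small-scale / testing)."""
    emb = np.atleast_2d(np.asarray(embeddings, dtype=float))
    phase = emb @ freqs.frequencies.T
    values = np.exp(-1j * phase).sum(axis=0) / (emb.shape[0] * np.sqrt(freqs.m))
    return Sketch(values=values, n_points=emb.shape[0])
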