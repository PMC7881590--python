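"""Synthetic chromatogram matrices with known cluster structure.

Emulates the two axes along which real elution profiles differ — peak apex
time and peak shape — by drawing each column as a scaled Gaussian (optionally
exponentially-modified, for chromatographic tailing) peak whose apex is
jittered around its cluster's apex, plus clipped additive noise.  The
generator also emits trace-CSV fixtures (five-column layout with -1 noise
labels) and profile-mode spectrum lists, so the whole pipeline is testable
without any instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import DataMatrix, Spectrum

__all__ = [
    "SyntheticSpec",
    "generate_matrix",
    "generate_trace_csv",
    "generate_spectra",
    "two_cluster_spec",
    "eight_cluster_spec",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Cluster-structured chromatogram generator settings.

    Apex times and widths are in row (retention-time sample) units;
    apex_jitter is the within-cluster apex standard deviation; intensities
    are scaled uniformly from intensity_range; noise_sd is the additive noise
    scale as a fraction of the peak height.
    """

    n_times: int = 120
    n_clusters: int = 2
    columns_per_cluster: int = 30
    apex_times: tuple = (40.0, 80.0)
    widths: tuple = (4.0, 4.0)
    apex_jitter: float = 1.0
    intensity_range: tuple = (5e4, 5e5)
    noise_sd: float = 0.02
    tailing: float = 0.0  # exponential tail scale (rows); 0 = pure Gaussian
    seed: int = 0

    def __post_init__(self):
        if len(self.apex_times) != self.n_clusters or len(self.widths) != self.n_clusters:
            raise ValueError("apex_times and widths must have n_clusters entries")
        if any(not (0 <= a < self.n_times) for a in self.apex_times):
            raise ValueError("apex times must lie inside the time grid")
        if any(w <= 0 for w in self.widths):
            raise ValueError("widths must be positive")

    @property
    def separation(self) -> float:
        """Min inter-apex gap divided by max width (cluster separability)."""
        apexes = np.sort(np.asarray(self.apex_times, dtype=float))
        if len(apexes) < 2:
            return np.inf
        return float(np.min(np.diff(apexes)) / np.max(self.widths))


def _peak(t: np.ndarray, apex: float, width: float, tailing: float) -> np.ndarray:
    g = np.exp(-0.5 * ((t - apex) / width) ** 2)
    if tailing > 0:
        # exponentially modified Gaussian via convolution with a decay kernel
        decay = np.exp(-np.arange(len(t)) / tailing)
        g = np.convolve(g, decay)[: len(t)]
        g /= g.max()
    return g


def generate_matrix(spec: SyntheticSpec):
    """Generate a (DataMatrix, labels) pair; labels give each column's cluster."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_times, dtype=float)
    columns = []
    labels = []
    for c in range(spec.n_clusters):
        for _ in range(spec.columns_per_cluster):
            apex = spec.apex_times[c] + rng.normal(0.0, spec.apex_jitter)
            apex = float(np.clip(apex, 0, spec.n_times - 1))
            scale = rng.uniform(*spec.intensity_range)
            profile = scale * _peak(t, apex, spec.widths[c], spec.tailing)
            noise = rng.normal(0.0, spec.noise_sd * scale, size=spec.n_times)
            columns.append(np.clip(profile + noise, 0.0, None))
            labels.append(c)
    values = np.column_stack(columns)
    # guard: a column of pure clipped noise could in principle be all-zero
    values[:, values.sum(axis=0) == 0] = 1e-12
    n_cols = values.shape[1]
    matrix = DataMatrix(
        values,
        row_times=t,
        col_mz=400.0 + np.arange(n_cols) * 0.5,  # one synthetic m/z per column
        provenance="synthetic",
    )
    return matrix, np.array(labels)


def generate_trace_csv(spec: SyntheticSpec, path, noise_fraction: float = 0.1):
    """Write a five-column trace CSV fixture; returns (matrix, labels).

    Non-zero matrix entries become data rows (trace = column index, envelope
    = cluster label); ``noise_fraction`` of additional random rows get trace
    label -1.
    """
    matrix, labels = generate_matrix(spec)
    values = np.asarray(matrix.values)
    rows, cols = np.nonzero(values)
    df = pd.DataFrame(
        {
            "mz": matrix.col_mz[cols],
            "rt": matrix.row_times[rows],
            "intensity": values[rows, cols],
            "trace": cols + 1,  # 0 is reserved for noise
            "envelope": labels[cols],
        }
    )
    rng = np.random.default_rng(spec.seed + 1)
    n_noise = int(np.ceil(noise_fraction * len(df)))
    if n_noise:
        noise = pd.DataFrame(
            {
                "mz": rng.uniform(matrix.col_mz.min(), matrix.col_mz.max(), n_noise),
                "rt": rng.choice(matrix.row_times, n_noise),
                "intensity": rng.uniform(1.0, 100.0, n_noise),
                "trace": rng.choice([-1, 0], n_noise),
                "envelope": -1,
            }
        )
        df = pd.concat([df, noise], ignore_index=True)
    df.to_csv(path, index=False)
    return matrix, labels


def generate_spectra(
    spec: SyntheticSpec, resolution: float = 60000.0, mz_min: float = 400.0
) -> list[Spectrum]:
    """Render the synthetic columns as profile-mode MS1 spectra.

    Each column is placed at a distinct m/z, its peak spread over several
    consecutive profile-mode points; one Spectrum per time sample.
    """
    matrix, _labels = generate_matrix(spec)
    values = np.asarray(matrix.values)
    if values.max() <= 1e-9:
        raise ValueError("zero-intensity spec produces no spectra")
    n_times, n_cols = values.shape
    # well-separated centers, a few profile points each, returning to a zero
    # baseline at the flanks (so inter-peak grid nodes interpolate to zero)
    centers = mz_min + 2.0 * (1 + np.arange(n_cols))
    offsets = np.array([-0.015, -0.01, -0.005, 0.0, 0.005, 0.01, 0.015])
    shape = np.array([0.0, 0.2, 0.6, 1.0, 0.6, 0.2, 0.0])
    spectra = []
    for i in range(n_times):
        mz = (centers[:, None] + offsets[None, :]).ravel()
        inten = (values[i][:, None] * shape[None, :]).ravel()
        spectra.append(Spectrum(mz, inten, retention_time=float(i)))
    return spectra


def two_cluster_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Two well-separated clusters (apexes 10 widths apart)."""
    defaults = dict(
        n_times=120, n_clusters=2, columns_per_cluster=30,
        apex_times=(40.0, 80.0), widths=(4.0, 4.0),
        apex_jitter=1.0, noise_sd=0.02, seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def eight_cluster_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Eight clusters spread over the time grid, >= 6-sigma separated.

    Sized at 256 columns per cluster (N = 2048) so that the derived target
    rank s = ceil(sqrt(k) N^(1/4)) exceeds the number of generating clusters,
    the regime the compression sizing formulas assume on real LC-MS matrices.
    """
    widths = (2.0,) * 8
    apexes = tuple(20.0 + 14.0 * np.arange(8))
    defaults = dict(
        n_times=160, n_clusters=8, columns_per_cluster=256,
        apex_times=apexes, widths=widths,
        apex_jitter=0.5, noise_sd=0.02, seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)
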