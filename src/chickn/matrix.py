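"""Build the chromatogram-column data matrix from MS1 spectra or pre-traced CSV points.

An LC-MS map is turned into a dense matrix whose rows are MS1 spectra
(indexed by retention time) and whose columns are chromatographic elution
profiles (indexed by m/z).  Two routes exist:

* resampling raw profile/centroid spectra from mzML/mzXML onto a
  resolution-adapted m/z grid, with linear interpolation of intensities;
* loading pre-traced points from a five-column CSV (m/z, retention time,
  intensity, trace label, envelope label), one column per trace.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MzGrid",
    "Spectrum",
    "DataMatrix",
    "build_mz_grid",
    "interpolate_spectrum",
    "assemble_matrix",
    "load_trace_csv",
    "export_trace_csv",
    "read_spectra",
]

TRACE_CSV_COLUMNS = ["mz", "rt", "intensity", "trace", "envelope"]


@dataclass(frozen=True)
class MzGrid:
    """Non-uniform m/z sampling grid adapted to the instrument resolution.

    Node spacing grows as ``0.015 * m^{3/2} / resolution`` so that the grid
    density follows the (Orbitrap-style) decay of resolving power with m/z.
    """

    nodes: np.ndarray
    resolution: float
    range: tuple[float, float]

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class Spectrum:
    """One MS1 scan: coupled m/z and intensity lists at a retention time."""

    mz: np.ndarray
    intensity: np.ndarray
    retention_time: float

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity must have the same length")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")


class DataMatrix:
    """Spectra x chromatograms intensity matrix.

    ``values`` may be an in-memory ndarray or an h5py dataset (column-chunked,
    so that :meth:`columns` never loads the full matrix).  All clustering code
    accesses columns through :meth:`column` / :meth:`columns`.
    """

    def __init__(self, values, row_times, col_mz, provenance: str):
        self.values = values
        self.row_times = np.asarray(row_times, dtype=float)
        self.col_mz = np.asarray(col_mz, dtype=float)
        self.provenance = provenance
        n_rows, n_cols = values.shape
        if len(self.row_times) != n_rows:
            raise ValueError("row_times length must match row count")
        if len(self.col_mz) != n_cols:
            raise ValueError("col_mz length must match column count")
        if np.any(np.diff(self.row_times) < 0):
            raise ValueError("row_times must be non-decreasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> np.ndarray:
        return np.asarray(self.values[:, j], dtype=float)

    def columns(self, idx) -> np.ndarray:
        """Return the sub-matrix of the requested columns as ndarray (rows x len(idx))."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        # h5py fancy indexing requires sorted unique indices
        order = np.argsort(idx, kind="stable")
        sorted_idx = idx[order]
        block = np.asarray(self.values[:, sorted_idx], dtype=float)
        inverse = np.empty_like(order)
        inverse[order] = np.arange(len(order))
        return block[:, inverse]

    def to_hdf5(self, path: str | os.PathLike) -> None:
        import h5py

        arr = np.asarray(self.values, dtype=float)
        n_rows, n_cols = arr.shape
        with h5py.File(path, "w") as f:
            f.create_dataset(
                "values", data=arr, chunks=(n_rows, min(64, n_cols))
            )
            f.create_dataset("row_times", data=self.row_times)
            f.create_dataset("col_mz", data=self.col_mz)
            f.attrs["provenance"] = self.provenance

    @classmethod
    def from_hdf5(cls, path: str | os.PathLike, in_memory: bool = False) -> "DataMatrix":
        import h5py

        f = h5py.File(path, "r")
        values = f["values"]
        if in_memory:
            values = np.asarray(values)
        mat = cls(
            values,
            np.asarray(f["row_times"]),
            np.asarray(f["col_mz"]),
            str(f.attrs.get("provenance", "resampled")),
        )
        if in_memory:
            f.close()
        else:
            mat._h5file = f  # keep handle alive for lazy access
        return mat


def build_mz_grid(mz_min: float, mz_max: float, resolution: float) -> MzGrid:
    """Build the resolution-adapted m/z grid.

    Starting at ``mz_min``, each gap is ``0.015 * m_i**1.5 / resolution``;
    generation stops at the first node >= ``mz_max``.
    """
    if not (0 < mz_min < mz_max):
        raise ValueError("require 0 < mz_min < mz_max")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    nodes = [mz_min]
    m = mz_min
    while m < mz_max:
        m = m + 0.015 * m**1.5 / resolution
        nodes.append(m)
    return MzGrid(np.array(nodes), float(resolution), (float(mz_min), float(mz_max)))


def interpolate_spectrum(spectrum: Spectrum, grid: MzGrid) -> np.ndarray:
    """Linearly interpolate spectrum intensities onto the grid nodes.

    Nodes outside the spectrum's recorded m/z support get intensity 0
    (absent signal means zero ion count).
    """
    mz = spectrum.mz
    if np.any(np.diff(mz) < 0):
        raise ValueError("spectrum m/z values must be sorted ascending")
    if len(mz) == 0:
        return np.zeros(len(grid.nodes))
    return np.interp(grid.nodes, mz, spectrum.intensity, left=0.0, right=0.0)


def assemble_matrix(
    spectra: Sequence[Spectrum],
    grid: MzGrid,
    empty_threshold: float = 0.0,
) -> DataMatrix:
    """Stack interpolated spectra into a DataMatrix, dropping empty columns.

    A column is "empty" when every entry is <= ``empty_threshold``
    (strictly all-zero by default).
    """
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum")
    times = np.array([s.retention_time for s in spectra], dtype=float)
    order = np.argsort(times, kind="stable")  # acquisition order, ties by file order
    rows = np.stack([interpolate_spectrum(spectra[i], grid) for i in order])
    keep = np.flatnonzero((rows > empty_threshold).any(axis=0))
    if keep.size == 0:
        raise ValueError("all columns empty: no signal on the grid")
    return DataMatrix(
        rows[:, keep], times[order], grid.nodes[keep], provenance="resampled"
    )


def read_spectra(
    path: str | os.PathLike, fmt: str | None = None, ms_level: int = 1
) -> list[Spectrum]:
    """Read MS spectra of the requested MS level from an mzML or mzXML file.

    Streaming XML parse covering the subset of both PSI/Sashimi schemata that
    instrument converters emit for MS1 maps: 32/64-bit float arrays, zlib or
    no compression, retention times in seconds or minutes.
    """
    path = os.fspath(path)
    if fmt is None:
        fmt = "mzxml" if path.lower().endswith(".mzxml") else "mzml"
    if fmt == "mzml":
        spectra = list(_iter_mzml(path, ms_level))
    elif fmt == "mzxml":
        spectra = list(_iter_mzxml(path, ms_level))
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    spectra.sort(key=lambda s: s.retention_time)
    return spectra


def _decode_array(b64_text: str, bits: int, zlib_compressed: bool) -> np.ndarray:
    import base64
    import zlib

    raw = base64.b64decode(b64_text)
    if zlib_compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype="<f4" if bits == 32 else "<f8").astype(float)


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _iter_mzml(path, ms_level):
    import xml.etree.ElementTree as ET

    for _event, elem in ET.iterparse(path, events=("end",)):
        if _localname(elem.tag) != "spectrum":
            continue
        params = {}  # accession -> (value, unit)
        for cv in elem.iter():
            if _localname(cv.tag) == "cvParam":
                params[cv.get("accession")] = (cv.get("value"), cv.get("unitName"))
        level = int(params.get("MS:1000511", ("0", None))[0] or 0)
        if level != ms_level:
            elem.clear()
            continue
        rt_val, rt_unit = params.get("MS:1000016", ("0", "second"))
        rt = float(rt_val) * (60.0 if rt_unit and "minute" in rt_unit else 1.0)
        mz = intensity = None
        for array_el in elem.iter():
            if _localname(array_el.tag) != "binaryDataArray":
                continue
            acc = {cv.get("accession") for cv in array_el
                   if _localname(cv.tag) == "cvParam"}
            bits = 32 if "MS:1000521" in acc else 64
            compressed = "MS:1000574" in acc
            binary = next(
                (c for c in array_el if _localname(c.tag) == "binary"), None
            )
            data = _decode_array(binary.text or "", bits, compressed)
            if "MS:1000514" in acc:
                mz = data
            elif "MS:1000515" in acc:
                intensity = data
        elem.clear()
        if mz is not None and intensity is not None:
            yield Spectrum(mz, intensity, rt)


def _parse_mzxml_rt(text: str) -> float:
    """ISO-8601-style duration (PT600.5S, PT10M30S) or bare seconds."""
    if not text:
        return 0.0
    text = text.strip()
    if not text.startswith("PT"):
        return float(text)
    seconds = 0.0
    number = ""
    for ch in text[2:]:
        if ch in "HMS":
            value = float(number or 0)
            seconds += value * {"H": 3600.0, "M": 60.0, "S": 1.0}[ch]
            number = ""
        else:
            number += ch
    return seconds


def _iter_mzxml(path, ms_level):
    import xml.etree.ElementTree as ET

    for _event, elem in ET.iterparse(path, events=("end",)):
        if _localname(elem.tag) != "scan":
            continue
        if int(elem.get("msLevel", "0")) != ms_level:
            elem.clear()
            continue
        rt = _parse_mzxml_rt(elem.get("retentionTime", "0"))
        peaks = next((c for c in elem.iter() if _localname(c.tag) == "peaks"), None)
        if peaks is None or not (peaks.text or "").strip():
            elem.clear()
            continue
        import base64
        import zlib

        raw = base64.b64decode(peaks.text)
        if peaks.get("compressionType", "none") == "zlib":
            raw = zlib.decompress(raw)
        bits = int(peaks.get("precision", "64"))
        # network byte order = big-endian, m/z-intensity interleaved
        pairs = np.frombuffer(raw, dtype=">f4" if bits == 32 else ">f8").astype(float)
        elem.clear()
        yield Spectrum(pairs[0::2], pairs[1::2], rt)


def load_trace_csv(
    path: str | os.PathLike,
    return_truth: bool = False,
    noise_labels: tuple = (-1, 0),
):
    """Load pre-traced LC-MS points into a DataMatrix, one column per trace.

    Rows whose trace label is in ``noise_labels`` (-1 and 0 by the benchmark
    convention) are dropped.  When ``return_truth`` is set, the per-column
    envelope (ground-truth) labels are returned alongside the matrix.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing required columns: {missing}")
    df = df[~df["trace"].isin(list(noise_labels))]
    if df.empty:
        raise ValueError("all points are noise-labelled; matrix would be empty")

    traces = np.sort(df["trace"].unique())
    times = np.sort(df["rt"].unique())
    trace_pos = {t: j for j, t in enumerate(traces)}
    time_pos = {t: i for i, t in enumerate(times)}

    values = np.zeros((len(times), len(traces)))
    rows = df["rt"].map(time_pos).to_numpy()
    cols = df["trace"].map(trace_pos).to_numpy()
    values[rows, cols] = df["intensity"].to_numpy()

    # representative m/z per trace: intensity-weighted mean
    col_mz = (
        df.assign(w=df["intensity"] * df["mz"])
        .groupby("trace")
        .apply(lambda g: g["w"].sum() / max(g["intensity"].sum(), 1e-300), include_groups=False)
        .reindex(traces)
        .to_numpy()
    )
    mat = DataMatrix(values, times, col_mz, provenance="trace_csv")
    if return_truth:
        if "envelope" in df.columns:
            env = df.groupby("trace")["envelope"].first().reindex(traces).to_numpy()
        else:
            env = None
        return mat, env
    return mat


def export_trace_csv(
    matrix: DataMatrix, path: str | os.PathLike, assignment=None
) -> None:
    """Write every non-zero matrix entry as one CSV row.

    The column index stands in for the trace label; when ``assignment`` is
    supplied its leaf label is written in the envelope column.
    """
    values = np.asarray(matrix.values)
    rows, cols = np.nonzero(values)
    env = (
        np.asarray(assignment.labels)[cols]
        if assignment is not None
        else np.full(len(cols), -1)
    )
    pd.DataFrame(
        {
            "mz": matrix.col_mz[cols],
            "rt": matrix.row_times[rows],
            "intensity": values[rows, cols],
            "trace": cols,
            "envelope": env,
        }
    ).to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
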