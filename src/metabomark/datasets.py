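"""In-memory containers for binned NMR data and synthetic spectra.

The analysis operates on a samples x bins intensity matrix (arbitrary
units, AU) whose columns are fixed-width chemical-shift buckets, plus a
per-sample metadata table carrying the patient link, the disease class
(RRMS / SPMS), the sample-handling protocol and the QC flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CLASSES = ("RRMS", "SPMS")
QC_LABEL = "QC"
PROTOCOLS = ("optimised", "freeze_thaw", "min120", "min240")

META_COLUMNS = ["sample_id", "patient_id", "class_label", "protocol",
                "qc", "storage_years"]


def bin_label(lo: float, hi: float) -> str:
    """Column name for the half-open ppm bucket [lo, hi)."""
    return f"B{lo:.2f}_{hi:.2f}"


def make_bins(windows, bin_width):
    """Tile half-open [lo, hi) buckets of ``bin_width`` over the windows.

    Each window length must be an integer multiple of the width
    (tolerance 1e-9 on the multiple).
    """
    ranges = []
    for lo, hi in windows:
        if hi <= lo:
            raise ValueError(f"window ({lo}, {hi}) is empty")
        n = (hi - lo) / bin_width
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"bin width {bin_width} does not tile window ({lo}, {hi})")
        n = int(round(n))
        edges = lo + bin_width * np.arange(n + 1)
        ranges.extend((float(edges[i]), float(edges[i + 1]))
                      for i in range(n))
    ranges.sort()
    for (a_lo, a_hi), (b_lo, b_hi) in zip(ranges, ranges[1:]):
        if b_lo < a_hi - 1e-12:
            raise ValueError("windows overlap")
    return ranges


def _check_meta(meta: pd.DataFrame, n_rows: int) -> pd.DataFrame:
    meta = meta.reset_index(drop=True)
    if len(meta) != n_rows:
        raise ValueError(
            f"metadata has {len(meta)} rows, matrix has {n_rows}")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    bad = set(meta["class_label"]) - set(CLASSES) - {QC_LABEL}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    return meta


@dataclass
class BinnedDataset:
    """Samples x bins intensity matrix with ppm bucket labels and metadata.

    ``values[i, j]`` is sample i's integral over the half-open ppm range
    ``bin_ranges[j]``; ranges are disjoint, sorted and uniform in width.
    When ``normalised`` each row sums to 1 (relative intensities).
    """

    values: np.ndarray
    bin_ranges: list
    meta: pd.DataFrame
    normalised: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x bins)")
        if self.values.shape[1] != len(self.bin_ranges):
            raise ValueError("bin_ranges length does not match matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite intensities")
        if np.any(self.values < 0):
            raise ValueError("negative intensities")
        self.bin_ranges = [(float(lo), float(hi)) for lo, hi in self.bin_ranges]
        self.meta = _check_meta(self.meta, self.values.shape[0])

    # -- basic views -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_labels(self) -> list:
        return [bin_label(lo, hi) for lo, hi in self.bin_ranges]

    @property
    def qc_mask(self) -> np.ndarray:
        return self.meta["qc"].to_numpy(dtype=bool)

    @property
    def class_labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    def subset_samples(self, idx) -> "BinnedDataset":
        idx = np.asarray(idx)
        return replace(self, values=self.values[idx],
                       meta=self.meta.iloc[idx].reset_index(drop=True))

    def subset_bins(self, keep_idx) -> "BinnedDataset":
        keep_idx = list(keep_idx)
        return replace(self, values=self.values[:, keep_idx],
                       bin_ranges=[self.bin_ranges[j] for j in keep_idx])

    def without_qc(self) -> "BinnedDataset":
        return self.subset_samples(np.flatnonzero(~self.qc_mask))

    def find_bin(self, lo: float, hi: float) -> int:
        for j, (blo, bhi) in enumerate(self.bin_ranges):
            if abs(blo - lo) < 1e-9 and abs(bhi - hi) < 1e-9:
                return j
        raise KeyError(f"no bin [{lo}, {hi}) in dataset")

    # -- I/O -------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.bin_labels,
                            index=self.meta["sample_id"])

    def to_csv(self, matrix_path, meta_path=None):
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(matrix_path)
        if meta_path is not None:
            self.meta[META_COLUMNS].to_csv(meta_path, index=False)

    @classmethod
    def from_csv(cls, matrix_path, meta_path=None, normalised=False):
        df = pd.read_csv(matrix_path, index_col=0)
        ranges = []
        for col in df.columns:
            if not col.startswith("B") or "_" not in col:
                raise ValueError(f"cannot parse bin column name {col!r}")
            lo, hi = col[1:].split("_")
            ranges.append((float(lo), float(hi)))
        if meta_path is not None:
            meta = pd.read_csv(meta_path)
            # metadata may cover more samples (e.g. all protocols);
            # align to the matrix rows by sample id
            missing = set(df.index.astype(str)) - set(
                meta["sample_id"].astype(str))
            if missing:
                raise ValueError(
                    f"metadata lacks samples {sorted(missing)[:5]}")
            meta = (meta.set_index("sample_id")
                    .loc[df.index.astype(str)].reset_index())
        else:
            meta = pd.DataFrame({
                "sample_id": df.index.astype(str),
                "patient_id": df.index.astype(str),
                "class_label": "RRMS",
                "protocol": "optimised",
                "qc": False,
                "storage_years": 0.0,
            })
        meta["qc"] = meta["qc"].astype(bool)
        return cls(df.to_numpy(dtype=float), ranges, meta,
                   normalised=normalised)


@dataclass
class SpectrumSet:
    """Raw synthetic 1-D spectra: one shared ppm axis, one trace per sample."""

    ppm: np.ndarray
    intensities: np.ndarray          # (n_samples, n_points)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.ppm.ndim != 1:
            raise ValueError("ppm axis must be 1-D")
        if np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly increasing")
        if self.intensities.ndim != 2 or \
                self.intensities.shape[1] != self.ppm.size:
            raise ValueError("intensities must be (n_samples, n_points)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite spectral intensities")
        if np.any(self.intensities < 0):
            raise ValueError("negative spectral intensities")
        if not self.sample_ids:
            self.sample_ids = [f"S{i}" for i in range(len(self.intensities))]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
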