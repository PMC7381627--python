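"""Spectral bucketing and matrix clean-up.

Pipeline: integrate fixed-width ppm buckets over the two spectral
windows, drop designated/automatic noise bins, sum-normalise each
sample, drop bins whose coefficient of variation across the pooled QC
replicates exceeds the threshold, then re-normalise so rows again sum
to one.  The unbinned water region between the windows is never
represented.

The CV filter runs on normalised data by default (QC reproducibility of
relative intensities); a switch computes it on raw integrals instead.
Filtering only removes columns, never alters retained values (modulo
the final re-normalisation pass, which is logged in the report).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .datasets import BinnedDataset, SpectrumSet, bin_label, make_bins
from .synthetic import DEFAULT_BIN_WIDTH, DEFAULT_WINDOWS

CV_THRESHOLD_DEFAULT = 0.15


@dataclass
class FilterReport:
    """Which bins each clean-up stage removed, and why."""

    excluded_noise: list = field(default_factory=list)      # bin labels
    excluded_cv: list = field(default_factory=list)         # (label, cv)
    retained: list = field(default_factory=list)
    normalisation_passes: int = 0

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            excluded_noise=self.excluded_noise + other.excluded_noise,
            excluded_cv=self.excluded_cv + other.excluded_cv,
            retained=other.retained or self.retained,
            normalisation_passes=(self.normalisation_passes
                                  + other.normalisation_passes))

    def to_dict(self) -> dict:
        return {
            "excluded_noise": list(self.excluded_noise),
            "excluded_cv": [[lab, float(cv)] for lab, cv in self.excluded_cv],
            "retained": list(self.retained),
            "normalisation_passes": self.normalisation_passes,
        }


# -- bucketing ---------------------------------------------------------------

def bin_spectrum(ppm, intensity, windows=DEFAULT_WINDOWS,
                 bin_width=DEFAULT_BIN_WIDTH):
    """Trapezoidal integral of one spectrum over each half-open bucket.

    The buckets tile the windows exactly; the axis must be strictly
    increasing and cover every window.
    """
    ppm = np.asarray(ppm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if np.any(np.diff(ppm) <= 0):
        raise ValueError("ppm axis must be strictly increasing")
    ranges = make_bins(windows, bin_width)
    if ppm[0] > ranges[0][0] + 1e-12 or ppm[-1] < ranges[-1][1] - 1e-12:
        raise ValueError(
            f"ppm axis [{ppm[0]:.4f}, {ppm[-1]:.4f}] does not cover the "
            f"windows {list(windows)}")
    # cumulative trapezoid, then edge interpolation: exact for the
    # piecewise-linear interpolant up to edge sub-intervals
    cum = np.concatenate([[0.0], cumulative_trapezoid(intensity, ppm)])
    edges_lo = np.array([lo for lo, _ in ranges])
    edges_hi = np.array([hi for _, hi in ranges])
    return np.interp(edges_hi, ppm, cum) - np.interp(edges_lo, ppm, cum)


def bin_spectra(spectra: SpectrumSet, windows=DEFAULT_WINDOWS,
                bin_width=DEFAULT_BIN_WIDTH, meta=None) -> BinnedDataset:
    """Bucket every spectrum in the set into one BinnedDataset."""
    import pandas as pd

    ranges = make_bins(windows, bin_width)
    values = np.vstack([bin_spectrum(spectra.ppm, row, windows, bin_width)
                        for row in spectra.intensities])
    values = np.clip(values, 0.0, None)
    if meta is None:
        meta = pd.DataFrame({
            "sample_id": spectra.sample_ids,
            "patient_id": spectra.sample_ids,
            "class_label": "RRMS",
            "protocol": "optimised",
            "qc": False,
            "storage_years": 0.0,
        })
    return BinnedDataset(values, ranges, meta)


# -- normalisation and filters -----------------------------------------------

def sum_normalise(dataset: BinnedDataset) -> BinnedDataset:
    """Divide each row by its own total (relative intensities, rows sum to 1)."""
    sums = dataset.values.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = dataset.meta["sample_id"].iloc[bad].tolist()
        raise ValueError(f"cannot sum-normalise samples with non-positive "
                         f"total intensity: {names}")
    return replace(dataset, values=dataset.values / sums[:, np.newaxis],
                   normalised=True)


def qc_cv_filter(dataset: BinnedDataset,
                 cv_threshold: float = CV_THRESHOLD_DEFAULT):
    """Drop bins whose CV across the QC replicates strictly exceeds the threshold.

    CV = sd / mean per bin over QC rows (sd with the n-1 denominator).
    Bins with zero QC mean are removed as noise.  A CV exactly at the
    threshold is retained ("exceeding" is strict).
    """
    qc_rows = dataset.values[dataset.qc_mask]
    if qc_rows.shape[0] < 2:
        raise ValueError(
            "QC CV filter needs >= 2 QC samples; none/too few present — "
            "skip the filter explicitly if the dataset has no QC replicates")
    means = qc_rows.mean(axis=0)
    sds = qc_rows.std(axis=0, ddof=1)
    labels = dataset.bin_labels
    report = FilterReport()
    keep = []
    for j in range(dataset.n_bins):
        if means[j] <= 0:
            report.excluded_noise.append(labels[j])
            continue
        cv = sds[j] / means[j]
        if cv > cv_threshold:
            report.excluded_cv.append((labels[j], float(cv)))
        else:
            keep.append(j)
    report.retained = [labels[j] for j in keep]
    return dataset.subset_bins(keep), report


def exclude_noise_bins(dataset: BinnedDataset, rule):
    """Remove signal-free bins.

    ``rule`` is either an explicit list of bin ranges ``(lo, hi)`` /
    labels, or an automatic criterion ``{"min_median_frac": k}`` that
    flags bins whose median intensity over the QC rows (all rows if no
    QC) falls below ``k`` times the across-bin median of those medians
    (a robust proxy for the baseline noise level).
    """
    labels = dataset.bin_labels
    report = FilterReport()
    if rule is None or rule == [] or rule == {}:
        report.retained = list(labels)
        return dataset, report
    if isinstance(rule, dict):
        k = float(rule["min_median_frac"])
        ref_rows = dataset.values[dataset.qc_mask] \
            if dataset.qc_mask.any() else dataset.values
        med = np.median(ref_rows, axis=0)
        level = np.median(med)
        drop = set(np.flatnonzero(med < k * level))
    else:
        drop = set()
        for item in rule:
            if isinstance(item, str):
                if item not in labels:
                    raise ValueError(f"bin {item!r} not present")
                drop.add(labels.index(item))
            else:
                drop.add(dataset.find_bin(*item))
    keep = [j for j in range(dataset.n_bins) if j not in drop]
    report.excluded_noise = [labels[j] for j in sorted(drop)]
    report.retained = [labels[j] for j in keep]
    return dataset.subset_bins(keep), report


def apply_filter_report(dataset: BinnedDataset,
                        report: FilterReport) -> BinnedDataset:
    """Re-apply a previous run's bin selection to another dataset, then
    sum-normalise.  Used to process perturbed-protocol matrices with the
    bin set determined on the reference (optimised) protocol, so all
    protocols share identical columns."""
    labels = dataset.bin_labels
    missing = [lab for lab in report.retained if lab not in labels]
    if missing:
        raise ValueError(f"dataset lacks retained bins {missing}")
    keep = [labels.index(lab) for lab in report.retained]
    return sum_normalise(dataset.subset_bins(keep))


def preprocess(dataset: BinnedDataset, noise_rule=None,
               cv_threshold: float = CV_THRESHOLD_DEFAULT,
               cv_on_normalised: bool = True,
               qc_filter: bool = True):
    """Full clean-up: noise exclusion -> normalise -> QC CV filter -> re-normalise.

    Returns the processed dataset and a merged :class:`FilterReport`.
    With ``qc_filter`` off (e.g. no QC replicates) only noise exclusion
    and normalisation run.
    """
    ds, report = exclude_noise_bins(dataset, noise_rule)
    if not cv_on_normalised and qc_filter:
        ds, cv_rep = qc_cv_filter(ds, cv_threshold)
        report = report.merge(cv_rep)
        ds = sum_normalise(ds)
        report.normalisation_passes += 1
        return ds, report
    ds = sum_normalise(ds)
    report.normalisation_passes += 1
    if qc_filter:
        ds, cv_rep = qc_cv_filter(ds, cv_threshold)
        report = report.merge(cv_rep)
        ds = sum_normalise(ds)
        report.normalisation_passes += 1
    return ds, report
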