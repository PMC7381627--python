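"""VIP-based biomarker ranking, knee-point cutoff, and fold changes.

Bins are ranked by their VIP score from a full-data OPLS-DA fit on a
class-balanced copy of the dataset (the "representative model"), or
alternatively by the mean VIP across a cross-validation ensemble.  The
selection cutoff is the inflexion point of the descending VIP ranking
curve, located as the rank of maximum perpendicular distance from the
chord joining the first and last points (a kneedle-style rule); the
cutoff value is always an attained VIP score, never interpolated.
Fold change is mean SPMS intensity over mean RRMS intensity per bin,
computed on sum-normalised data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import BinnedDataset
from .opls import fit_opls_da
from .validation import CVConfig, balanced_external_cv


@dataclass
class CutoffResult:
    cutoff_value: float
    cutoff_rank: int        # number of selected bins (0 if degenerate)
    method: str


def aggregate_vip(dataset: BinnedDataset, n_orth: int = 1,
                  scaling: str = "uv", mode: str = "full",
                  seed: int = 0, cv_config: CVConfig = None) -> np.ndarray:
    """Per-bin VIP scores for the whole dataset.

    mode="full" (default): one OPLS-DA fit on all samples after random
    undersampling of the majority class (seeded).  mode="ensemble":
    mean VIP over every model of a balanced external CV ensemble.
    """
    ds = dataset.without_qc()
    if mode == "full":
        rng = np.random.default_rng(seed)
        cls = ds.class_labels
        idx_r = np.flatnonzero(cls == "RRMS")
        idx_s = np.flatnonzero(cls == "SPMS")
        if idx_r.size == 0 or idx_s.size == 0:
            raise ValueError("both classes must be present")
        m = min(idx_r.size, idx_s.size)
        keep = np.concatenate([rng.choice(idx_r, m, replace=False),
                               rng.choice(idx_s, m, replace=False)])
        sub = ds.subset_samples(np.sort(keep))
        model = fit_opls_da(sub.values, sub.class_labels, n_orth=n_orth,
                            scaling=scaling, bin_labels=sub.bin_labels)
        return model.vip_
    if mode == "ensemble":
        cfg = cv_config or CVConfig(seed=seed, n_orth=n_orth,
                                    scaling=scaling)
        cfg.store_vip = True
        ens = balanced_external_cv(ds, cfg)
        return ens.vip_matrix.mean(axis=0)
    raise ValueError(f"unknown mode {mode!r}; use 'full' or 'ensemble'")


def inflexion_cutoff(vip_sorted, method: str = "max_chord_distance"
                     ) -> CutoffResult:
    """Knee of a descending VIP ranking curve.

    "max_chord_distance": rank maximising the perpendicular distance of
    (rank, VIP) from the chord joining (1, VIP_max) to (n, VIP_min);
    ties break to the smaller rank.  "second_difference": rank of the
    largest discrete second difference.  A flat curve has no knee: the
    returned cutoff selects nothing, with a warning.
    """
    v = np.asarray(vip_sorted, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 VIP values to locate a knee")
    if np.any(np.diff(v) > 1e-12):
        raise ValueError("VIP values must be sorted in descending order")
    if np.ptp(v) == 0:
        warnings.warn("all VIP values equal; no inflexion point — "
                      "cutoff selects nothing", stacklevel=2)
        return CutoffResult(cutoff_value=np.inf, cutoff_rank=0,
                            method=method)
    n = v.size
    if method == "max_chord_distance":
        # absolute perpendicular distance from the chord (a descending
        # steep-then-flat curve lies below it), constant factors dropped;
        # argmax takes the first (smallest rank) on ties
        i = np.arange(n)
        d = np.abs((v - v[0]) * (n - 1) - (v[-1] - v[0]) * i)
        knee = int(np.argmax(d))
    elif method == "second_difference":
        d2 = v[:-2] - 2 * v[1:-1] + v[2:]
        knee = int(np.argmax(d2)) + 1
    else:
        raise ValueError(f"unknown knee method {method!r}")
    return CutoffResult(cutoff_value=float(v[knee]), cutoff_rank=knee + 1,
                        method=method)


def fold_changes(dataset: BinnedDataset, bins=None) -> pd.Series:
    """Per-bin mean(SPMS) / mean(RRMS) on the dataset's intensity scale."""
    ds = dataset.without_qc()
    cls = ds.class_labels
    if not (cls == "SPMS").any() or not (cls == "RRMS").any():
        raise ValueError("both classes must be present")
    mean_s = ds.values[cls == "SPMS"].mean(axis=0)
    mean_r = ds.values[cls == "RRMS"].mean(axis=0)
    if np.any(mean_r == 0):
        bad = [ds.bin_labels[j] for j in np.flatnonzero(mean_r == 0)]
        raise ValueError(f"zero RRMS mean in bins {bad}")
    fc = pd.Series(mean_s / mean_r, index=ds.bin_labels, name="fold_change")
    if bins is not None:
        labels = [b if isinstance(b, str)
                  else ds.bin_labels[ds.find_bin(*b)] for b in bins]
        fc = fc.loc[labels]
    return fc


def map_bins_to_metabolites(bin_ranges, annotation_map) -> list:
    """Annotate bins from a {(lo, hi): name} map; unmatched -> "unassigned".

    Map entries must not overlap each other; a bin matches an entry if
    the two ppm intervals overlap.
    """
    entries = sorted(((float(lo), float(hi)), name)
                     for (lo, hi), name in annotation_map.items())
    for ((a_lo, a_hi), na), ((b_lo, b_hi), nb) in zip(entries, entries[1:]):
        if b_lo < a_hi - 1e-12:
            raise ValueError(
                f"overlapping annotation entries [{a_lo}, {a_hi}) ({na}) "
                f"and [{b_lo}, {b_hi}) ({nb})")
    out = []
    for lo, hi in bin_ranges:
        name = "unassigned"
        for (e_lo, e_hi), e_name in entries:
            if lo < e_hi - 1e-12 and e_lo < hi - 1e-12:
                name = e_name
                break
        out.append(name)
    return out


def biomarker_table(dataset: BinnedDataset, n_orth: int = 1,
                    scaling: str = "uv", mode: str = "full", seed: int = 0,
                    annotation_map: dict = None,
                    knee_method: str = "max_chord_distance"):
    """Ranked biomarker table: VIP, rank, knee cutoff, fold change, annotation.

    Returns ``(table, cutoff)`` where the table is one row per bin
    sorted by descending VIP, and ``selected`` marks bins with
    VIP >= the knee cutoff.
    """
    ds = dataset.without_qc()
    vip_vec = aggregate_vip(ds, n_orth=n_orth, scaling=scaling, mode=mode,
                            seed=seed)
    fc = fold_changes(ds)
    order = np.argsort(-vip_vec, kind="stable")
    cutoff = inflexion_cutoff(vip_vec[order], method=knee_method)
    annotations = map_bins_to_metabolites(
        ds.bin_ranges, annotation_map or {})
    table = pd.DataFrame({
        "bin": [ds.bin_labels[j] for j in order],
        "ppm_lo": [ds.bin_ranges[j][0] for j in order],
        "ppm_hi": [ds.bin_ranges[j][1] for j in order],
        "vip": vip_vec[order],
        "vip_rank": np.arange(1, ds.n_bins + 1),
        "fold_change": fc.to_numpy()[order],
        "metabolite": [annotations[j] for j in order],
    })
    table["selected"] = table["vip"] >= cutoff.cutoff_value
    return table, cutoff
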