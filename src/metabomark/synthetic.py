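"""Synthetic serum NMR cohort generator.

Emulates the statistical structure of a two-class (RRMS vs SPMS) binned
CPMG serum study: a common per-bin baseline profile, multiplicative
disease effects planted on designated bins, patient-level log-normal
biological spread, pooled QC replicates with technical spread, and
class-neutral sample-handling (protocol) perturbations applied to every
sample of a protocol.  Each patient contributes one sample per protocol
from the same blood draw, so the biological deviate of a patient is
shared across protocols.

Intensities are generated on the raw (un-normalised) scale; the
processing module performs sum normalisation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datasets import (PROTOCOLS, BinnedDataset, SpectrumSet, make_bins)

DEFAULT_WINDOWS = ((0.80, 4.20), (5.20, 8.50))
DEFAULT_BIN_WIDTH = 0.02

#: baseline raw intensity of a bin carrying a planted metabolite signal,
#: relative to the 1.0 background of ordinary metabolite bins
PLANTED_BASELINE = 3.0
#: baseline of designated noise bins (empty spectral regions)
NOISE_BASELINE = 0.01
#: additive half-normal noise floor scale for noise bins
NOISE_FLOOR_SD = 0.006
#: technical CV applied to QC replicates on designated high-variability bins
QC_HIGH_CV = 0.25
#: Lorentzian half-width at half-maximum (ppm) for synthetic lines
DEFAULT_HWHM = 3e-4
#: ppm step of the synthetic axis (must be finer than bin_width / 10)
DEFAULT_PPM_STEP = 1e-4


def _load_default_panel() -> dict:
    ref = importlib.resources.files("metabomark.data") / "default_panel.yaml"
    return yaml.safe_load(ref.read_text())


def _as_range(r):
    lo, hi = r
    return (float(lo), float(hi))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 31 RRMS vs 28 SPMS patients,
    4 pooled QC replicates, 0.02-ppm buckets over 0.80-4.20 and
    5.20-8.50 ppm, the packaged 12-bin / 7-metabolite planted-effect
    panel, and four sample-handling protocols.
    """

    n_rrms: int = 31
    n_spms: int = 28
    n_qc: int = 4
    bin_width: float = DEFAULT_BIN_WIDTH
    windows: tuple = DEFAULT_WINDOWS
    planted_effects: list = None          # [(bin_range, fold_change)]
    biological_cv: float = 0.10
    technical_cv: float = 0.05
    protocol_effects: dict = None         # protocol -> [(bin_range, shift)]
    storage_drift: dict = None            # bin_range -> factor (years > 5)
    noise_bins: list = None
    qc_high_cv_bins: list = None
    qc_high_cv: float = QC_HIGH_CV
    amplitude: float = 1.0            # overall intensity scale (0 = silent)
    storage_years: float = 0.0
    seed: int = 0
    annotations: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        panel = None
        if self.planted_effects is None or self.noise_bins is None \
                or self.qc_high_cv_bins is None \
                or self.protocol_effects is None:
            panel = _load_default_panel()
        if self.planted_effects is None:
            self.planted_effects = []
            for met in panel["metabolites"]:
                for rng in met["bins"]:
                    self.planted_effects.append(
                        (_as_range(rng), float(met["fold_change"])))
                    self.annotations[_as_range(rng)] = met["name"]
        else:
            self.planted_effects = [(_as_range(r), float(f))
                                    for r, f in self.planted_effects]
        if self.protocol_effects is None:
            self.protocol_effects = {
                proto: [(_as_range(e["bins"][i]), float(e["shift"]))
                        for e in entries for i in range(len(e["bins"]))]
                for proto, entries in panel["protocol_effects"].items()}
        else:
            self.protocol_effects = {
                p: [(_as_range(r), float(s)) for r, s in effs]
                for p, effs in self.protocol_effects.items()}
        if self.noise_bins is None:
            self.noise_bins = [_as_range(r) for r in panel["noise_bins"]]
        else:
            self.noise_bins = [_as_range(r) for r in self.noise_bins]
        if self.qc_high_cv_bins is None:
            self.qc_high_cv_bins = [_as_range(r)
                                    for r in panel["qc_high_cv_bins"]]
        else:
            self.qc_high_cv_bins = [_as_range(r)
                                    for r in self.qc_high_cv_bins]
        if self.storage_drift is None:
            self.storage_drift = {}
        self.windows = tuple((float(lo), float(hi))
                             for lo, hi in self.windows)
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self):
        problems = []
        if self.n_rrms < 2:
            problems.append("n_rrms must be >= 2")
        if self.n_spms < 2:
            problems.append("n_spms must be >= 2")
        if self.n_qc < 0:
            problems.append("n_qc must be >= 0")
        if self.bin_width <= 0:
            problems.append("bin_width must be positive")
        if self.biological_cv < 0:
            problems.append("biological_cv must be >= 0")
        if self.technical_cv < 0:
            problems.append("technical_cv must be >= 0")
        if self.amplitude < 0:
            problems.append("amplitude must be >= 0")
        for rng, fold in self.planted_effects:
            if fold <= 0:
                problems.append(f"planted_effects: fold {fold} on bin "
                                f"{rng} must be > 0")
            if not any(lo - 1e-9 <= rng[0] and rng[1] <= hi + 1e-9
                       for lo, hi in self.windows):
                problems.append(f"planted_effects: bin {rng} lies outside "
                                "the spectral windows")
        def in_windows(rng):
            return any(lo - 1e-9 <= rng[0] and rng[1] <= hi + 1e-9
                       for lo, hi in self.windows)

        for proto, effs in self.protocol_effects.items():
            for rng, shift in effs:
                if shift <= 0:
                    problems.append(f"protocol_effects[{proto}]: shift "
                                    f"{shift} on bin {rng} must be > 0")
                if not in_windows(rng):
                    problems.append(f"protocol_effects[{proto}]: bin "
                                    f"{rng} lies outside the windows")
        for name, bins in (("noise_bins", self.noise_bins),
                           ("qc_high_cv_bins", self.qc_high_cv_bins)):
            for rng in bins:
                if not in_windows(rng):
                    problems.append(f"{name}: bin {rng} lies outside "
                                    "the windows")
        for rng, factor in self.storage_drift.items():
            if factor <= 0:
                problems.append(f"storage_drift: factor {factor} on bin "
                                f"{rng} must be > 0")
        if problems:
            raise ValueError("invalid GeneratorConfig: "
                             + "; ".join(problems))

    @property
    def protocols(self) -> list:
        extra = [p for p in PROTOCOLS if p in self.protocol_effects]
        other = sorted(set(self.protocol_effects) - set(PROTOCOLS))
        return ["optimised"] + extra + other

    def bin_ranges(self) -> list:
        return make_bins(self.windows, self.bin_width)


def _lognormal_sigma(cv: float) -> float:
    """sigma of a mean-one log-normal with the given coefficient of variation."""
    return float(np.sqrt(np.log1p(cv ** 2)))


def _range_index(bin_ranges, rng):
    for j, (lo, hi) in enumerate(bin_ranges):
        if abs(lo - rng[0]) < 1e-9 and abs(hi - rng[1]) < 1e-9:
            return j
    raise ValueError(f"bin range {rng} is not a generated bin")


def baseline_profile(config: GeneratorConfig) -> np.ndarray:
    """Per-bin baseline raw intensity shared by both classes."""
    ranges = config.bin_ranges()
    base = np.ones(len(ranges))
    for rng, _fold in config.planted_effects:
        base[_range_index(ranges, rng)] = PLANTED_BASELINE
    for rng in config.noise_bins:
        base[_range_index(ranges, rng)] = NOISE_BASELINE
    return base * config.amplitude


def fold_vector(config: GeneratorConfig) -> np.ndarray:
    """Per-bin SPMS/RRMS multiplicative effect (1.0 where no effect)."""
    ranges = config.bin_ranges()
    folds = np.ones(len(ranges))
    for rng, fold in config.planted_effects:
        folds[_range_index(ranges, rng)] = fold
    return folds


def protocol_shift_vector(config: GeneratorConfig, protocol: str) -> np.ndarray:
    ranges = config.bin_ranges()
    shifts = np.ones(len(ranges))
    if protocol == "optimised":
        return shifts
    if protocol not in config.protocol_effects:
        raise ValueError(f"unknown protocol {protocol!r}; known: "
                         f"{config.protocols}")
    for rng, shift in config.protocol_effects[protocol]:
        shifts[_range_index(ranges, rng)] *= shift
    return shifts


def apply_protocol_perturbation(matrix: np.ndarray, protocol: str,
                                config: GeneratorConfig) -> np.ndarray:
    """Multiply designated bins by the protocol's shift, every sample alike.

    ``optimised`` is the identity.  The perturbation is class-neutral by
    construction, so per-bin class-mean ratios are unchanged.
    """
    shifts = protocol_shift_vector(config, protocol)
    return np.asarray(matrix, dtype=float) * shifts[np.newaxis, :]


def _storage_drift_vector(config: GeneratorConfig) -> np.ndarray:
    ranges = config.bin_ranges()
    drift = np.ones(len(ranges))
    if config.storage_years > 5:
        for rng, factor in config.storage_drift.items():
            drift[_range_index(ranges, _as_range(rng))] = factor
    return drift


def generate_cohort(config: GeneratorConfig):
    """Generate one raw binned matrix per protocol plus the metadata table.

    Returns ``(datasets, meta)`` where ``datasets`` maps protocol name to
    a :class:`BinnedDataset` of ``n_rrms + n_spms + n_qc`` rows and
    ``meta`` is the concatenated metadata of all protocols.  The same
    patient keeps the same biological deviate in every protocol (one
    blood draw split across handling protocols); QC rows are fresh
    technical replicates of the pooled cohort mean in each protocol.
    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    ranges = config.bin_ranges()
    n_bins = len(ranges)
    base = baseline_profile(config)
    folds = fold_vector(config)
    drift = _storage_drift_vector(config)

    n_pat = config.n_rrms + config.n_spms
    classes = np.array(["RRMS"] * config.n_rrms + ["SPMS"] * config.n_spms)
    sigma_bio = _lognormal_sigma(config.biological_cv)
    # patient-level deviates, shared across protocols (mean-one log-normal)
    if sigma_bio > 0:
        bio = np.exp(sigma_bio * rng.standard_normal((n_pat, n_bins))
                     - 0.5 * sigma_bio ** 2)
    else:
        bio = np.ones((n_pat, n_bins))

    expected = base[np.newaxis, :] * np.where(
        (classes == "SPMS")[:, np.newaxis], folds[np.newaxis, :], 1.0)
    patients = expected * bio * drift[np.newaxis, :]

    noise_idx = [_range_index(ranges, r) for r in config.noise_bins]
    high_cv_idx = [_range_index(ranges, r) for r in config.qc_high_cv_bins]
    qc_mean = patients.mean(axis=0)
    sigma_tech = _lognormal_sigma(config.technical_cv)
    sigma_high = _lognormal_sigma(config.qc_high_cv)

    datasets = {}
    meta_frames = []
    for protocol in config.protocols:
        shifts = protocol_shift_vector(config, protocol)
        values = patients * shifts[np.newaxis, :]
        if noise_idx:
            values[:, noise_idx] += config.amplitude * np.abs(
                rng.normal(0.0, NOISE_FLOOR_SD,
                           size=(n_pat, len(noise_idx))))
        if config.n_qc > 0:
            sig = np.full(n_bins, sigma_tech)
            sig[high_cv_idx] = sigma_high
            qc = (qc_mean * shifts)[np.newaxis, :] * np.exp(
                sig[np.newaxis, :]
                * rng.standard_normal((config.n_qc, n_bins))
                - 0.5 * sig[np.newaxis, :] ** 2)
            if noise_idx:
                qc[:, noise_idx] += config.amplitude * np.abs(
                    rng.normal(0.0, NOISE_FLOOR_SD,
                               size=(config.n_qc, len(noise_idx))))
            values = np.vstack([values, qc])
        meta = pd.DataFrame({
            "sample_id": [f"{protocol}_P{i:03d}" for i in range(n_pat)]
            + [f"{protocol}_QC{i}" for i in range(config.n_qc)],
            "patient_id": [f"P{i:03d}" for i in range(n_pat)]
            + [f"QCpool{i}" for i in range(config.n_qc)],
            "class_label": list(classes) + ["QC"] * config.n_qc,
            "protocol": protocol,
            "qc": [False] * n_pat + [True] * config.n_qc,
            "storage_years": config.storage_years,
        })
        datasets[protocol] = BinnedDataset(values, ranges, meta)
        meta_frames.append(meta)

    return datasets, pd.concat(meta_frames, ignore_index=True)


# -- raw spectra -------------------------------------------------------------

def lorentzian_bin_fraction(center: float, hwhm: float, lo: float,
                            hi: float) -> float:
    """Closed-form fraction of a unit-area Lorentzian inside [lo, hi)."""
    return float((np.arctan((hi - center) / hwhm)
                  - np.arctan((lo - center) / hwhm)) / np.pi)


def generate_spectra(config: GeneratorConfig, protocol: str = "optimised",
                     hwhm: float = DEFAULT_HWHM,
                     ppm_step: float = DEFAULT_PPM_STEP) -> SpectrumSet:
    """Synthesize raw 1-D spectra whose bin integrals match the cohort.

    Each sample's spectrum is a sum of Lorentzian lines, one per bin,
    centred on the bin midpoint, plus a low-amplitude flat baseline.
    Line areas are renormalised by the closed-form in-bin Lorentzian
    fraction so that integrating a spectrum over a bin recovers that
    sample's generated bin intensity (up to tail leakage from adjacent
    lines, below 2% at the default linewidth).
    """
    if ppm_step > config.bin_width / 10:
        raise ValueError(
            f"ppm_step {ppm_step} is coarser than bin_width/10 "
            f"({config.bin_width / 10}); bins would be unresolvable")
    datasets, _ = generate_cohort(config)
    ds = datasets[protocol]
    ranges = ds.bin_ranges
    lo_axis = min(lo for lo, _ in ranges) - 0.1
    hi_axis = max(hi for _, hi in ranges) + 0.1
    ppm = np.arange(lo_axis, hi_axis + ppm_step / 2, ppm_step)

    centers = np.array([(lo + hi) / 2 for lo, hi in ranges])
    # frac[j, k]: fraction of line j's unit area falling into bin k
    frac = np.array([[lorentzian_bin_fraction(c, hwhm, lo, hi)
                      for lo, hi in ranges] for c in centers])
    diag = np.diag(frac).copy()
    off = frac - np.diag(diag)
    # line areas: own-bin renormalisation plus one Jacobi step against
    # the analytic tail-leakage matrix, clipped to keep areas >= 0
    # (near-zero bins flanked by strong lines absorb residual leakage)
    areas = ds.values / diag[np.newaxis, :]
    areas = np.clip((ds.values - areas @ off) / diag[np.newaxis, :],
                    0.0, None)
    # unit-area Lorentzian evaluated on the axis, one row per line
    shapes = (hwhm / np.pi) / ((ppm[np.newaxis, :]
                                - centers[:, np.newaxis]) ** 2 + hwhm ** 2)
    intensities = areas @ shapes
    baseline = 1e-5 * float(ds.values.mean())
    intensities += baseline
    return SpectrumSet(ppm, intensities, list(ds.meta["sample_id"]))
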