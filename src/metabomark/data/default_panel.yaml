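# Default planted-effect panel for the synthetic cohort generator.
#
# Seven serum metabolites, spread over 12 chemical-shift buckets, that
# discriminate secondary progressive from relapsing-remitting multiple
# sclerosis in CPMG serum spectra.  fold_change is the multiplicative
# SPMS/RRMS effect planted on every listed bin; bins are half-open
# [lo, hi) ppm ranges of width 0.02.
metabolites:
  - name: "Mobile -CH3 HDL/LDL"
    fold_change: 0.83
    bins: [[0.80, 0.82], [0.82, 0.84], [0.84, 0.86], [0.86, 0.88]]
  - name: "3-Hydroxybutyrate"
    fold_change: 0.84
    bins: [[1.20, 1.22]]
  - name: "Mobile (-CH2-)n LDL"
    fold_change: 0.84
    bins: [[1.22, 1.24], [1.24, 1.26]]
  - name: "Mobile (-CH2-)n Chylomicron/VLDL"
    fold_change: 0.92
    bins: [[1.26, 1.28]]
  - name: "NAC1 N-acetyl glycoprotein"
    fold_change: 1.07
    bins: [[2.04, 2.06]]
  - name: "Mobile -N(CH3)3 / free Choline"
    fold_change: 0.86
    bins: [[3.20, 3.22], [3.22, 3.24]]
  - name: "Glucose"
    fold_change: 1.07
    bins: [[3.88, 3.90]]

# Pre-analytical handling perturbations, applied multiplicatively to the
# listed bins of EVERY sample of that protocol (class-neutral).  The
# directions are motivated by known serum chemistry (freeze-thaw raises
# measured glucose and N-acetyl signals; standing time lets glycolysis
# consume glucose and produce lactate); the magnitudes are modest
# placeholder choices (<= 15%), not measured values.
protocol_effects:
  freeze_thaw:
    - bins: [[3.88, 3.90]]
      shift: 1.12
    - bins: [[2.04, 2.06]]
      shift: 1.10
  min120:
    - bins: [[3.88, 3.90]]
      shift: 0.95
    - bins: [[1.30, 1.32]]
      shift: 1.08
  min240:
    - bins: [[3.88, 3.90]]
      shift: 0.90
    - bins: [[1.30, 1.32]]
      shift: 1.15

# Bins carrying no metabolite resonance (empty aromatic stretch):
# populated with a low-amplitude noise floor so the noise-exclusion
# rule has something to remove.
noise_bins:
  - [5.20, 5.22]
  - [5.22, 5.24]
  - [5.24, 5.26]
  - [5.26, 5.28]
  - [5.28, 5.30]
  - [5.30, 5.32]

# Bins given inflated technical variability in the QC replicates so the
# 15% coefficient-of-variation filter has something to remove.
qc_high_cv_bins:
  - [7.50, 7.52]
  - [7.52, 7.54]
  - [7.54, 7.56]
  - [7.56, 7.58]
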