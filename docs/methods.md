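# Methods

## Scope and data model

The pipeline operates on a samples × bins intensity matrix
(`BinnedDataset`): fixed-width chemical-shift buckets over the two serum
CPMG windows, plus per-sample metadata (patient link, class RRMS/SPMS,
sample-handling protocol, QC flag). Raw synthetic spectra
(`SpectrumSet`) exist only to exercise the bucketing stage; all
downstream statistics consume the binned matrix, whether generated,
binned from spectra, or loaded from user CSVs.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not serum chemistry. For patient i (class c) and bin j the raw
intensity is

    x_ij = amplitude · base_j · fold_j^[c = SPMS] · shift_j(protocol)
           · drift_j(storage) · exp(σ z_ij − σ²/2)

with σ = √log(1 + CV²) so the log-normal deviate has mean exactly 1 —
hence at biological CV → 0 the empirical fold change equals the planted
one exactly, and the Monte-Carlo plant-recovery tests converge to the
configured values without bias. The patient-level deviate z_ij is drawn
once per patient and shared across protocols (one blood draw split
across handling protocols), which is what makes cross-protocol
evaluation meaningful: a patient's perturbed sample resembles their
optimised sample. QC rows are technical replicates of the pooled cohort
mean with their own log-normal spread, drawn fresh per protocol.

Defaults are the study conditions: 31 RRMS vs 28 SPMS patients, 4 QC
replicates, biological CV 10%, technical CV 5%, and the packaged
planted-effect panel — 12 bins in 7 metabolites with multiplicative
SPMS/RRMS fold changes 0.83 (lipoprotein –CH₃), 0.84
(3-hydroxybutyrate; lipid –CH₂–), 0.92 (VLDL/chylomicron), 1.07
(N-acetyl glycoprotein; glucose) and 0.86 (choline). Planted bins carry
baseline 3.0 against a background of 1.0, so the panel contributes a
realistic minority of total intensity and sum normalisation distorts
planted ratios by only ~1%. Designated noise bins (empty aromatic
stretch, baseline 0.01 plus a half-normal floor) feed the
noise-exclusion rule, and four bins get 25% technical CV in the QC
replicates so the 15% CV filter has work to do.

Protocol perturbations are class-neutral multiplicative shifts applied
to every sample of a protocol. The shipped magnitudes (≤ 15%, on
glucose/N-acetyl bins for freeze–thaw and glucose/lactate bins for
standing time) are deliberate placeholders: the source observations for
these effects are significance calls, not effect sizes, so the defaults
are chosen small enough to reproduce the qualitative behaviour — a
modest accuracy cost when testing across protocols, and no gain from
pooling heterogeneous protocols in training. A storage-drift map
(applied only when storage years > 5) models long-frozen cohorts.

What the generator does **not** emulate: peak overlap and shift
misalignment, baseline and phasing artefacts, correlated metabolite
panels (bins are independent given class), batch/run-order effects, or
any mechanistic clotting/glycolysis chemistry. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
noise model, not performance on real spectra.

Raw spectra are sums of Lorentzian lines (HWHM 3·10⁻⁴ ppm) centred on
bin midpoints over a 10⁻⁴-ppm axis. Line areas are renormalised by the
closed-form in-bin Lorentzian fraction and corrected with one clipped
Jacobi step against the analytic tail-leakage matrix, so integrating a
spectrum over a bin reproduces the generated bin intensity to ≲ 0.1%;
near-zero bins flanked by strong lines absorb residual heavy-tail
leakage and are the one place the 2% consistency bound can fail.

## Processing

Order of operations: integrate → exclude noise bins → sum-normalise →
QC CV filter → re-normalise. Computing the CV on normalised data makes
it a measure of QC reproducibility of *relative* intensities, which is
what the downstream model consumes; `cv_on_normalised=False` switches
to raw integrals, and the filter report logs how many normalisation
passes ran. Filters only remove columns — retained values are untouched
except by the final re-normalisation that restores the unit row sum.
The CV uses the n−1 denominator; a CV exactly at the threshold is
retained ("exceeding" is strict); bins with zero QC mean are removed as
noise. When several protocol matrices are analysed together, the bin
selection is determined once on the optimised protocol and re-applied
to the others (`apply_filter_report`), so all datasets share identical
columns.

Bucket integration uses the cumulative trapezoid with edge
interpolation, exact for the piecewise-linear interpolant; bins are
half-open [lo, hi), ascending ppm.

## OPLS-DA

Scaling defaults to unit variance after mean centring (Pareto and
centre-only are options); the class coding is RRMS → −1, SPMS → +1 with
decision threshold 0 and exact ties assigned RRMS deterministically
(with a warning). For a single response the NIPALS fixed point is
reached in one step, so each component is closed-form — no iteration is
needed anywhere. The default is one predictive plus one orthogonal
component, the conventional binary-class OPLS configuration; component
counts are never auto-selected.

One algebraic point deserves emphasis: the predictive *weight*
w ∝ X'y is mathematically invariant under orthogonal deflation, because
the orthogonal score t_o = Xw_o satisfies t_o'y = ‖X'y‖·w'w_o = 0. What
changes with n_orth is the predictive *score* t = Xw of the deflated
matrix and hence the effective coefficient vector
β = (∏ₐ(I − w_oₐ p_oₐ'))·w·c exposed as `OplsModel.coef_`; it is β, not
w, that realigns with the class contrast once an orthogonal confounder
is removed, and the oracle tests assert exactly that.

VIP is √p·|w_j|/‖w‖ for one predictive component and the standard
sum-of-squares-weighted generalisation for several; mean VIP² = 1 holds
identically and is asserted on every fit. Prediction applies the stored
training centring/scaling (never re-estimated), filters the orthogonal
components sequentially, and classifies by the sign of ŷ. Models
serialise losslessly to JSON.

## Validation ensembles

All CV variants share one patient-level core: per repetition the
majority class is undersampled to the minority size (without
replacement), patients are shuffled within class and dealt round-robin
into k folds (fold sizes differ by at most one per class), and per fold
an OPLS-DA model is fitted on the training patients' samples and scored
on the held-out patients' samples. Working on patients rather than
samples gives the no-overlap guarantee structurally — in cross-protocol
evaluation the held-out patients contribute only their other-protocol
samples while *all* their samples leave the training side, and in
pooled-protocol CV every sample of a patient stays on one side. It also
makes the degenerate cases exact identities: cross-protocol with the
training protocol as test set, and pooled CV over a single protocol,
reproduce plain balanced CV bit-for-bit under the same seed.

The permutation null permutes class labels over patients (preserving
class counts) freshly per repetition before balancing, then runs the
identical machinery; its mean accuracy converges to 50% under the
balanced design. Ensembles are compared by the two-sample KS test on
accuracy distributions (asymptotic p by default, exact optional) along
with the mean difference. Metrics are percentages, reported as
mean ± SD over all k × repetitions records; sensitivity is defined
against SPMS as the positive class, stated in output headers.

Seeding: every ensemble expands its config seed into per-repetition
`SeedSequence` children, so runs are reproducible end-to-end and
subsets of repetitions are independent.

## Biomarker selection

The headline VIP ranking comes from a single full-data fit on a
class-balanced copy of the dataset (the "representative model");
ensemble-mean VIP across all CV members is available as an alternative
mode, and the two rankings agree closely on well-separated data. The
cutoff is the knee of the descending VIP curve: the rank maximising the
absolute perpendicular distance from the chord joining the first and
last points (kneedle-style; a discrete second-difference method is the
option), ties broken to the smaller rank, and the cutoff value is
always an attained VIP score. A flat curve has no knee and yields an
empty selection with a warning. Fold change is the ratio of group
means (not medians) of sum-normalised intensities, SPMS over RRMS;
annotation joins a {ppm-range → metabolite} map with overlap
validation, defaulting to the packaged panel.

## Problem sizes

The test suite exercises compact cohorts (10–40 patients per class,
4–5 folds, 2–10 repetitions) for unit and contract tests, and the full
defaults — 59 patients, 10 folds × 100 repetitions = 1,000 models — for
the end-to-end checks; parameter-recovery runs use 100 patients per
class over 20 generator seeds, and robustness comparisons average 5–8
seeds. `scripts/acceptance.py` runs the complete default analysis
(≈ 6,000 model fits) in well under a minute on one core.

## Known limitations

- The generator's independence of bins given class understates the
  collinearity of real lipoprotein envelopes; VIP rankings on real data
  will be flatter than on synthetic data.
- Protocol-effect magnitudes are placeholders (see above); conclusions
  about the *size* of cross-protocol accuracy loss transfer only
  qualitatively.
- Accuracy at n = 59 with 10-fold CV is quantised in ~17% steps per
  fold, so ensemble SDs are large by construction; comparisons should
  use ensemble means (as the KS test does).
- No multi-class extension, no Q²-based component selection, no
  ROC/AUC reporting, and no peak alignment or alternative
  normalisations — out of scope by design.
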