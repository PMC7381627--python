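"""Class-balanced external cross-validation, permutation nulls, and
cross-protocol evaluation.

Every variant below runs the same patient-level core: per repetition
the majority class is randomly undersampled to the minority size,
patients are dealt into k stratified folds, and for each fold an
OPLS-DA model is fitted on the training patients' samples and scored on
the held-out patients' samples.  Because folds are formed on patients
(not samples), no patient ever contributes to both sides of a split —
also when the test samples come from a different sample-handling
protocol, or when samples from several protocols are pooled.

The permutation null reruns the identical procedure after randomly
reassigning class labels at the patient level, preserving the original
class counts.  Accuracy, sensitivity and specificity are reported in
percent; SPMS is the positive class (sensitivity = SPMS recall,
specificity = RRMS recall).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .datasets import BinnedDataset
from .opls import fit_opls_da, predict


@dataclass
class CVConfig:
    """Knobs of the external cross-validation procedure."""

    k_folds: int = 10
    repetitions: int = 100
    balance: bool = True
    seed: int = 0
    n_orth: int = 1
    scaling: str = "uv"
    n_pred: int = 1
    store_vip: bool = False

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class CVEnsemble:
    """Per-model records of a cross-validation (or permutation) ensemble."""

    records: pd.DataFrame
    vip_matrix: np.ndarray = None       # records x bins, if collected
    bin_labels: list = None

    @property
    def accuracies(self) -> np.ndarray:
        return self.records["accuracy"].to_numpy()

    def summary(self) -> dict:
        out = {"n_models": int(len(self.records))}
        for metric in ("accuracy", "sensitivity", "specificity"):
            vals = self.records[metric].to_numpy(dtype=float)
            out[f"{metric}_mean"] = float(np.nanmean(vals))
            out[f"{metric}_sd"] = float(np.nanstd(vals, ddof=1))
        return out

    def to_csv(self, path):
        df = self.records.copy()
        for col in ("test_sample_ids", "test_patient_ids",
                    "train_patient_ids"):
            df[col] = df[col].map(lambda ids: ";".join(ids))
        df.to_csv(path, index=False)


@dataclass
class EnsembleComparison:
    """Two-sample KS comparison of ensemble accuracy distributions."""

    ks_statistic: float
    p_value: float
    mean_difference: float      # mean(real) - mean(null), percentage points
    real_mean: float
    null_mean: float


# -- core --------------------------------------------------------------------

def _patient_table(datasets) -> pd.DataFrame:
    frames = [ds.meta.loc[~ds.meta["qc"], ["patient_id", "class_label"]]
              for ds in datasets]
    pat = pd.concat(frames).drop_duplicates()
    if pat["patient_id"].duplicated().any():
        dup = pat[pat["patient_id"].duplicated()]["patient_id"].tolist()
        raise ValueError(f"patients with conflicting class labels: {dup}")
    return pat.reset_index(drop=True)


def _check_shared_bins(datasets):
    ref = datasets[0].bin_labels
    for ds in datasets[1:]:
        if ds.bin_labels != ref:
            missing = sorted(set(ref) - set(ds.bin_labels))
            extra = sorted(set(ds.bin_labels) - set(ref))
            raise ValueError(f"bin mismatch between datasets: missing "
                             f"{missing}, extra {extra}")


def _metrics(true_labels, pred_labels):
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    correct = true_labels == pred_labels
    acc = 100.0 * correct.mean()
    pos = true_labels == "SPMS"
    neg = true_labels == "RRMS"
    sens = 100.0 * correct[pos].mean() if pos.any() else np.nan
    spec = 100.0 * correct[neg].mean() if neg.any() else np.nan
    return acc, sens, spec


def _run_patient_cv(train_pool, test_pool, config: CVConfig,
                    permute: bool = False) -> CVEnsemble:
    train_pool = list(train_pool)
    test_pool = list(test_pool)
    _check_shared_bins(train_pool + test_pool)
    train_pool = [ds.without_qc() for ds in train_pool]
    test_pool = [ds.without_qc() for ds in test_pool]
    patients = _patient_table(train_pool)
    test_patients = set(pd.concat([ds.meta["patient_id"]
                                   for ds in test_pool]))
    if not test_patients & set(patients["patient_id"]):
        raise ValueError("no patient linkage between training and test "
                         "datasets (patient_id sets are disjoint)")

    pat_ids = patients["patient_id"].to_numpy()
    pat_cls = patients["class_label"].to_numpy()
    k = config.k_folds

    rep_seeds = np.random.SeedSequence(config.seed).spawn(config.repetitions)
    rows = []
    vips = [] if config.store_vip else None
    for rep, seq in enumerate(rep_seeds):
        rng = np.random.default_rng(seq)
        cls = pat_cls
        if permute:
            cls = rng.permutation(pat_cls)
        idx_r = np.flatnonzero(cls == "RRMS")
        idx_s = np.flatnonzero(cls == "SPMS")
        if config.balance:
            m = min(idx_r.size, idx_s.size)
            idx_r = rng.choice(idx_r, size=m, replace=False)
            idx_s = rng.choice(idx_s, size=m, replace=False)
        if min(idx_r.size, idx_s.size) < k:
            raise ValueError(
                f"class size {min(idx_r.size, idx_s.size)} after balancing "
                f"is smaller than k_folds={k}")
        # stratified folds: shuffle within class, deal round-robin
        folds = [[] for _ in range(k)]
        for idx in (idx_r, idx_s):
            for i, pidx in enumerate(rng.permutation(idx)):
                folds[i % k].append(pidx)
        balanced = set(np.concatenate([idx_r, idx_s]))
        cls_of = dict(zip(pat_ids, cls))

        for fold_no, fold in enumerate(folds):
            fold_pat = {pat_ids[i] for i in fold}
            train_pat = {pat_ids[i] for i in balanced} - fold_pat

            X_tr, y_tr = [], []
            for ds in train_pool:
                mask = ds.meta["patient_id"].isin(train_pat).to_numpy()
                X_tr.append(ds.values[mask])
                y_tr.extend(cls_of[p] for p in
                            ds.meta["patient_id"].to_numpy()[mask])
            X_tr = np.vstack(X_tr)

            X_te, y_te, te_samples, te_patients = [], [], [], []
            for ds in test_pool:
                mask = ds.meta["patient_id"].isin(fold_pat).to_numpy()
                X_te.append(ds.values[mask])
                sub = ds.meta.loc[mask]
                y_te.extend(cls_of[p] for p in sub["patient_id"])
                te_samples.extend(sub["sample_id"])
                te_patients.extend(sub["patient_id"])
            X_te = np.vstack(X_te)
            if X_te.shape[0] == 0:
                raise ValueError(
                    f"fold {fold_no} of repetition {rep} has no test "
                    "samples (held-out patients absent from test datasets)")
            assert not (set(te_patients) & train_pat)

            model = fit_opls_da(X_tr, y_tr, n_orth=config.n_orth,
                                scaling=config.scaling,
                                n_pred=config.n_pred)
            pred = predict(model, X_te)
            acc, sens, spec = _metrics(y_te, pred.label)
            rows.append({
                "repetition": rep, "fold": fold_no,
                "accuracy": acc, "sensitivity": sens, "specificity": spec,
                "n_train": X_tr.shape[0], "n_test": X_te.shape[0],
                "test_sample_ids": tuple(te_samples),
                "test_patient_ids": tuple(sorted(set(te_patients))),
                "train_patient_ids": tuple(sorted(train_pat)),
            })
            if vips is not None:
                vips.append(model.vip_)

    return CVEnsemble(records=pd.DataFrame(rows),
                      vip_matrix=np.vstack(vips) if vips else None,
                      bin_labels=train_pool[0].bin_labels)


# -- public operations -------------------------------------------------------

def balanced_external_cv(dataset: BinnedDataset,
                         config: CVConfig) -> CVEnsemble:
    """Repeated class-balanced stratified k-fold external CV on one dataset.

    ``k_folds x repetitions`` OPLS-DA models are fitted, each evaluated
    on its held-out fold only; with the defaults (k=10, 100 repetitions)
    this is an ensemble of 1,000 models.  QC rows are excluded.
    """
    return _run_patient_cv([dataset], [dataset], config)


def permutation_null(dataset: BinnedDataset, config: CVConfig) -> CVEnsemble:
    """The identical balanced CV run after random class reassignment.

    Labels are permuted over patients before balancing, preserving the
    original class counts, freshly in every repetition: the resulting
    accuracy distribution is the chance baseline for
    :func:`compare_ensembles`.
    """
    return _run_patient_cv([dataset], [dataset], config, permute=True)


def compare_ensembles(real: CVEnsemble, null: CVEnsemble,
                      method: str = "asymp") -> EnsembleComparison:
    """Two-sample Kolmogorov-Smirnov comparison of accuracy distributions."""
    a, b = real.accuracies, null.accuracies
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare empty ensembles")
    res = ks_2samp(a, b, method=method)
    return EnsembleComparison(
        ks_statistic=float(res.statistic), p_value=float(res.pvalue),
        mean_difference=float(a.mean() - b.mean()),
        real_mean=float(a.mean()), null_mean=float(b.mean()))


def cross_protocol_evaluate(train_set: BinnedDataset,
                            test_set: BinnedDataset,
                            config: CVConfig) -> CVEnsemble:
    """Balanced CV trained on one protocol, tested on another.

    The patients dealt to each test fold contribute ONLY their
    ``test_set`` (other-protocol) samples to the test set, and all their
    ``train_set`` samples are removed from training, so the test set is
    always patient-independent of the training set.  With
    ``test_set is train_set`` this reduces exactly to
    :func:`balanced_external_cv`.
    """
    return _run_patient_cv([train_set], [test_set], config)


def multiprotocol_cv(datasets, config: CVConfig) -> CVEnsemble:
    """Balanced CV on samples pooled across several protocols.

    Each patient contributes one sample per listed protocol; folds are
    formed at the patient level so all of a patient's samples stay on
    one side of every split.  A single-dataset list reduces exactly to
    :func:`balanced_external_cv`.
    """
    datasets = list(datasets)
    return _run_patient_cv(datasets, datasets, config)
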