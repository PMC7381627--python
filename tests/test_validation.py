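"""Cross-validation machinery: bookkeeping, calibration, protocol scenarios."""

import numpy as np
import pytest
from scipy.stats import distributions

from metabomark import (CVConfig, GeneratorConfig, balanced_external_cv,
                        compare_ensembles, cross_protocol_evaluate,
                        generate_cohort, multiprotocol_cv, permutation_null,
                        preprocess)
from metabomark.processing import apply_filter_report
from metabomark.validation import CVEnsemble

import pandas as pd


def _ensemble_from_accuracies(acc):
    n = len(acc)
    return CVEnsemble(records=pd.DataFrame({
        "repetition": 0, "fold": range(n), "accuracy": acc,
        "sensitivity": acc, "specificity": acc,
        "n_train": 10, "n_test": 2,
        "test_sample_ids": [("s",)] * n,
        "test_patient_ids": [("p",)] * n,
        "train_patient_ids": [("q",)] * n,
    }))


@pytest.fixture(scope="module")
def quick_cfg():
    return CVConfig(k_folds=5, repetitions=4, seed=11)


@pytest.fixture(scope="module")
def quick_ensemble(small_processed, quick_cfg):
    processed, _ = small_processed
    return balanced_external_cv(processed, quick_cfg)


def test_record_count_and_metric_ranges(quick_ensemble, quick_cfg):
    ens = quick_ensemble
    assert len(ens.records) == quick_cfg.k_folds * quick_cfg.repetitions
    for metric in ("accuracy", "sensitivity", "specificity"):
        vals = ens.records[metric].to_numpy()
        assert np.all((vals >= 0) & (vals <= 100))


def test_each_balanced_sample_tested_once_per_repetition(quick_ensemble):
    for _, rep in quick_ensemble.records.groupby("repetition"):
        tested = [s for ids in rep["test_sample_ids"] for s in ids]
        assert len(tested) == len(set(tested))
        # balanced design: 2 x minority-class patients, one sample each
        assert len(tested) == 2 * 12


def test_fold_sizes_balanced_within_one(quick_ensemble):
    for _, rep in quick_ensemble.records.groupby("repetition"):
        sizes = rep["n_test"].to_numpy()
        assert sizes.max() - sizes.min() <= 2   # <=1 per class


def test_no_patient_in_both_train_and_test(quick_ensemble):
    for _, row in quick_ensemble.records.iterrows():
        assert not set(row["train_patient_ids"]) & set(
            row["test_patient_ids"])


def test_accuracy_is_class_weighted_sens_spec(small_processed,
                                              quick_ensemble):
    processed, _ = small_processed
    cls = dict(zip(processed.meta["sample_id"],
                   processed.meta["class_label"]))
    for _, row in quick_ensemble.records.iterrows():
        labels = np.array([cls[s] for s in row["test_sample_ids"]])
        n_s, n_r = (labels == "SPMS").sum(), (labels == "RRMS").sum()
        expected = (n_s * row["sensitivity"]
                    + n_r * row["specificity"]) / (n_s + n_r)
        assert row["accuracy"] == pytest.approx(expected, abs=1e-9)


def test_seeded_determinism(small_processed, quick_cfg):
    processed, _ = small_processed
    a = balanced_external_cv(processed, quick_cfg)
    b = balanced_external_cv(processed, quick_cfg)
    pd.testing.assert_frame_equal(a.records, b.records)
    na = permutation_null(processed, quick_cfg)
    nb = permutation_null(processed, quick_cfg)
    pd.testing.assert_frame_equal(na.records, nb.records)
    # and the null differs from the real ensemble
    assert not np.array_equal(a.accuracies, na.accuracies)


def test_separable_data_reaches_full_accuracy():
    cfg = GeneratorConfig(n_rrms=12, n_spms=12, n_qc=2,
                          biological_cv=0.01, seed=21)
    datasets, _ = generate_cohort(cfg)
    processed, _ = preprocess(datasets["optimised"])
    ens = balanced_external_cv(processed,
                               CVConfig(k_folds=5, repetitions=3, seed=2))
    assert ens.summary()["accuracy_mean"] == 100.0


def test_k_larger_than_class_errors(small_processed):
    processed, _ = small_processed
    with pytest.raises(ValueError, match="k_folds"):
        balanced_external_cv(processed,
                             CVConfig(k_folds=20, repetitions=1, seed=0))


def test_permutation_null_centred_at_chance(small_processed):
    """Mean null accuracy approaches 50% for balanced label reassignment."""
    processed, _ = small_processed
    means = []
    for seed in range(4):
        null = permutation_null(processed,
                                CVConfig(k_folds=5, repetitions=5,
                                         seed=seed))
        means.append(null.summary()["accuracy_mean"])
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means) - 50.0) < 3 * max(se, 1.0)


# -- ensemble comparison -----------------------------------------------------

def test_identical_ensembles_compare_equal():
    ens = _ensemble_from_accuracies([80.0, 90.0, 100.0, 85.0])
    comp = compare_ensembles(ens, ens)
    assert comp.ks_statistic == 0.0
    assert comp.p_value == pytest.approx(1.0)
    assert comp.mean_difference == 0.0


def test_disjoint_ensembles_ks_one():
    hi = _ensemble_from_accuracies([100.0] * 6)
    lo = _ensemble_from_accuracies([0.0] * 6)
    assert compare_ensembles(hi, lo).ks_statistic == 1.0


def test_ks_matches_textbook_oracle():
    """D from hand-built ECDFs, p from the two-sample KS survival
    function with effective size mn/(m+n), to 1e-10."""
    rng = np.random.default_rng(5)
    a = rng.uniform(40, 100, size=80)
    b = rng.uniform(30, 90, size=60)
    comp = compare_ensembles(_ensemble_from_accuracies(a),
                             _ensemble_from_accuracies(b))
    grid = np.sort(np.concatenate([a, b]))
    F1 = np.searchsorted(np.sort(a), grid, side="right") / a.size
    F2 = np.searchsorted(np.sort(b), grid, side="right") / b.size
    D = np.max(np.abs(F1 - F2))
    en = a.size * b.size / (a.size + b.size)
    p = distributions.kstwo.sf(D, int(round(en)))
    assert comp.ks_statistic == pytest.approx(D, abs=1e-10)
    assert comp.p_value == pytest.approx(p, abs=1e-10)


def test_empty_ensemble_rejected():
    ens = _ensemble_from_accuracies([80.0])
    empty = CVEnsemble(records=ens.records.iloc[:0])
    with pytest.raises(ValueError, match="empty"):
        compare_ensembles(ens, empty)


# -- cross-protocol scenarios ------------------------------------------------

@pytest.fixture(scope="module")
def protocol_sets(small_cohort):
    datasets, _ = small_cohort
    processed, report = preprocess(datasets["optimised"],
                                   noise_rule={"min_median_frac": 0.1})
    others = {p: apply_filter_report(d, report)
              for p, d in datasets.items() if p != "optimised"}
    return processed, others


def test_cross_protocol_degenerate_self_consistency(protocol_sets,
                                                    quick_cfg):
    """Testing on the training protocol reproduces the plain balanced CV
    exactly under the same seed."""
    processed, _ = protocol_sets
    a = cross_protocol_evaluate(processed, processed, quick_cfg)
    b = balanced_external_cv(processed, quick_cfg)
    pd.testing.assert_frame_equal(a.records.drop(columns="test_sample_ids"),
                                  b.records.drop(columns="test_sample_ids"))


def test_cross_protocol_test_samples_come_from_test_protocol(protocol_sets,
                                                             quick_cfg):
    processed, others = protocol_sets
    ens = cross_protocol_evaluate(processed, others["freeze_thaw"],
                                  quick_cfg)
    for ids in ens.records["test_sample_ids"]:
        assert all(s.startswith("freeze_thaw_") for s in ids)
    for _, row in ens.records.iterrows():
        assert not set(row["train_patient_ids"]) & set(
            row["test_patient_ids"])


def test_class_neutral_perturbation_off_markers_harmless(quick_cfg):
    """A shift confined to non-discriminatory bins leaves cross-protocol
    accuracy within sampling error of the optimised-test accuracy."""
    cfg = GeneratorConfig(
        n_rrms=14, n_spms=12, n_qc=4, seed=31,
        protocol_effects={"freeze_thaw": [((6.00, 6.02), 1.15),
                                          ((7.00, 7.02), 0.9)]})
    datasets, _ = generate_cohort(cfg)
    processed, report = preprocess(datasets["optimised"])
    other = apply_filter_report(datasets["freeze_thaw"], report)
    base = cross_protocol_evaluate(processed, processed, quick_cfg)
    cross = cross_protocol_evaluate(processed, other, quick_cfg)
    diff = (base.summary()["accuracy_mean"]
            - cross.summary()["accuracy_mean"])
    assert abs(diff) < 5.0


def test_degradation_grows_with_perturbation_on_markers(quick_cfg):
    """Inflating the perturbation on the top planted bins in the test
    data monotonically degrades cross-protocol accuracy."""
    marker_bins = [(0.84, 0.86), (0.82, 0.84), (1.24, 1.26), (1.22, 1.24),
                   (3.22, 3.24), (3.20, 3.22), (0.80, 0.82), (0.86, 0.88)]
    means = []
    for shift in (1.0, 1.12, 1.3):
        cfg = GeneratorConfig(
            n_rrms=14, n_spms=12, n_qc=4, seed=33,
            protocol_effects={"freeze_thaw": [(b, shift)
                                              for b in marker_bins]})
        datasets, _ = generate_cohort(cfg)
        processed, report = preprocess(datasets["optimised"])
        other = apply_filter_report(datasets["freeze_thaw"], report)
        ens = cross_protocol_evaluate(processed, other, quick_cfg)
        means.append(ens.summary()["accuracy_mean"])
    assert means[0] > means[1] > means[2]


def test_multiprotocol_single_dataset_equals_plain_cv(protocol_sets,
                                                      quick_cfg):
    processed, _ = protocol_sets
    a = multiprotocol_cv([processed], quick_cfg)
    b = balanced_external_cv(processed, quick_cfg)
    pd.testing.assert_frame_equal(a.records, b.records)


def test_multiprotocol_patient_level_split(protocol_sets, quick_cfg):
    processed, others = protocol_sets
    ens = multiprotocol_cv([processed] + list(others.values()), quick_cfg)
    assert len(ens.records) == quick_cfg.k_folds * quick_cfg.repetitions
    for _, row in ens.records.iterrows():
        assert not set(row["train_patient_ids"]) & set(
            row["test_patient_ids"])
        # each held-out patient contributes one sample per protocol
        assert len(row["test_sample_ids"]) == \
            4 * len(row["test_patient_ids"])


def test_bin_mismatch_between_protocols_rejected(protocol_sets, quick_cfg):
    processed, others = protocol_sets
    truncated = others["min120"].subset_bins(
        range(others["min120"].n_bins - 1))
    with pytest.raises(ValueError, match="bin mismatch"):
        cross_protocol_evaluate(processed, truncated, quick_cfg)


def test_missing_patient_linkage_rejected(protocol_sets, quick_cfg):
    processed, others = protocol_sets
    foreign = others["min120"]
    renamed = foreign.meta.copy()
    renamed["patient_id"] = "X" + renamed["patient_id"]
    from dataclasses import replace
    with pytest.raises(ValueError, match="linkage"):
        cross_protocol_evaluate(processed,
                                replace(foreign, meta=renamed), quick_cfg)
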