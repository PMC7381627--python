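import numpy as np
import pandas as pd
import pytest

from metabomark import BinnedDataset, GeneratorConfig, generate_cohort, preprocess


@pytest.fixture(scope="session")
def small_config():
    """Compact cohort for fast tests (structure identical to defaults)."""
    return GeneratorConfig(n_rrms=14, n_spms=12, n_qc=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    datasets, meta = generate_cohort(small_config)
    return datasets, meta


@pytest.fixture(scope="session")
def small_processed(small_cohort):
    datasets, _ = small_cohort
    processed, report = preprocess(datasets["optimised"],
                                   noise_rule={"min_median_frac": 0.1})
    return processed, report


def toy_dataset(values, class_labels, qc=None, patient_ids=None,
                bin_width=0.02, start=0.80):
    """Small hand-built BinnedDataset for unit tests."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ranges = [(start + bin_width * j, start + bin_width * (j + 1))
              for j in range(p)]
    qc = [False] * n if qc is None else list(qc)
    if patient_ids is None:
        patient_ids = [f"P{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "patient_id": patient_ids,
        "class_label": class_labels,
        "protocol": "optimised",
        "qc": qc,
        "storage_years": 0.0,
    })
    return BinnedDataset(values, ranges, meta)
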