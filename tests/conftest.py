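import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ucscore.data import ClassLabels, apply_kit_correction
from ucscore.synthetic import CohortConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted cohort for unit tests: 300 probes, 68 biopsies."""
    config = CohortConfig(
        n_uc_biopsies=60, n_ibdu_biopsies=8, n_controls=10,
        n_probesets=300, n_signal_probesets=40, seed=7,
    )
    bundle, truth = generate_cohort(config)
    return config, bundle, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Study-scale planted cohort (2,000 probes) for power-style checks."""
    config = CohortConfig(n_probesets=2000, n_signal_probesets=150, seed=11)
    bundle, truth = generate_cohort(config)
    return config, bundle, truth


@pytest.fixture(scope="session")
def corrected_planted(planted_cohort):
    config, bundle, truth = planted_cohort
    matrix = apply_kit_correction(bundle.matrix, bundle.samples)
    return matrix, bundle, truth


def make_class_labels(n_active: int, n_inactive: int, tag: str = "Mayo_Prob_1") -> ClassLabels:
    ids = [f"A{i}" for i in range(n_active)] + [f"I{i}" for i in range(n_inactive)]
    labels = pd.Series(["active"] * n_active + ["inactive"] * n_inactive,
                       index=pd.Index(ids, name="sample_id"))
    return ClassLabels(labels=labels, cohort_tag=tag)


def make_matrix(values, probe_ids=None, sample_ids=None) -> pd.DataFrame:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"P{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                        columns=sample_ids)
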