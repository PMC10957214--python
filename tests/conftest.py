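import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import thermofc as tf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def roi() -> tf.RoiSet:
    return tf.RoiSet()


@pytest.fixture(scope="session")
def templates(roi):
    return tf.make_default_templates(roi)


@pytest.fixture(scope="session")
def quiet_config():
    """Generator settings without nuisance components (artifact-free)."""
    return tf.SimulationConfig(
        artifact_rate=0.0, drift_amplitude=0.0, global_amplitude=0.0
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-parameter cohort shared across tests (4 animals,
    2 conditions x 1 session, 1500 frames)."""
    cfg = tf.SimulationConfig(frames_per_acq=1500)
    results, manifest = tf.simulate_cohort(cfg, 4, 1, ["15C", "25C"], seed=42)
    return cfg, results, manifest


@pytest.fixture(scope="session")
def clean_series(quiet_config):
    acq, _ = tf.simulate_acquisition(quiet_config, "m01", "25C", seed=5)
    cs = tf.clean_acquisition(acq)
    assert cs is not None
    return cs


def occupancy_table_from_truth(results, k: int = 7) -> pd.DataFrame:
    """OccurrenceTable built from generator ground truth (no clustering)."""
    rows = []
    for acq, gt in results:
        for s in range(k):
            rows.append({
                "animal_id": acq.animal_id,
                "condition": acq.condition,
                "acquisition_id": acq.acquisition_id,
                "state": s,
                "rate": gt.occupancy_realized[s],
            })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def occ_table_from_truth():
    return occupancy_table_from_truth
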