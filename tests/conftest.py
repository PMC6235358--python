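import numpy as np
import pytest

from vtwarn.pipeline import featurize_cohort
from vtwarn.records import RRRecord
from vtwarn.synth import CohortSpec, generate_cohort


def make_record(
    intervals,
    labels=None,
    patient_id="pt-0",
    record_id="rec-0",
    rhythm_class="regular",
    event_anchored=False,
):
    intervals = np.asarray(intervals, dtype=float)
    if labels is None:
        labels = np.full(intervals.size, "N", dtype="U1")
    return RRRecord(
        patient_id=patient_id,
        record_id=record_id,
        rhythm_class=rhythm_class,
        intervals=intervals,
        labels=np.asarray(labels, dtype="U1"),
        event_anchored=event_anchored,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """A scaled-down study cohort (250 + 250 records, default class specs)."""
    return generate_cohort(CohortSpec(n_regular=250, n_preshock=250, seed=42))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Feature tables and window arrays for both warning horizons."""
    return {
        horizon: featurize_cohort(default_cohort, horizon)
        for horizon in ("five_minute", "ten_second")
    }
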