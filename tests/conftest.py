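import numpy as np
import pytest

from datscreen.epoch_features import EpochSeries


def make_series(
    bks,
    dks=None,
    tremor=None,
    worn=None,
    artifact=None,
    start="2024-01-01T09:00:00",
    subject_id="T",
):
    """Daytime epoch series on the 2-minute grid starting at ``start``."""
    bks = np.asarray(bks, dtype=float)
    n = bks.size
    ts = np.datetime64(start, "s") + (np.arange(n) * 120).astype("timedelta64[s]")
    return EpochSeries(
        subject_id=subject_id,
        timestamps=ts,
        bks=bks,
        dks=np.zeros(n) if dks is None else np.asarray(dks, float),
        tremor=np.zeros(n, bool) if tremor is None else np.asarray(tremor, bool),
        worn=np.ones(n, bool) if worn is None else np.asarray(worn, bool),
        artifact=artifact,
    )


@pytest.fixture
def series_factory():
    return make_series


@pytest.fixture(scope="session")
def default_cohort():
    """One draw of the default calibrated 172-row CP/CN cohort."""
    from datscreen.simulate import default_config, sample_cohort

    table, truth = sample_cohort(default_config(), n=172, seed=1)
    return table
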