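import dataclasses

import pandas as pd
import pytest

from contextprofile.synth import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Small but non-trivial cohort: 3 patients, 120 days, 1 UTI + 1 hosp each."""
    return SynthConfig(n_patients=3, n_days=120, uti_episodes_per_patient=1,
                       hosp_episodes_per_patient=1, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_features(small_cfg, small_cohort):
    from contextprofile.features import build_feature_series
    start = pd.Timestamp(small_cfg.start_date)
    end = start + pd.Timedelta(days=small_cfg.n_days - 1)
    return [build_feature_series(s, start=start, end=end) for s, _ in small_cohort]
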