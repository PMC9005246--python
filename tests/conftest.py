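"""Shared fixtures: small synthetic datasets and cached replicate batteries.

The replicate batteries are session-scoped because several acceptance
properties (curve recovery, AF calibration, threshold monotonicity) are
different summaries of the same set of simulated stage-1 fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from heatlag import attribution, dlnm_stage1, synthetic_data

STUDY_YEARS = range(1981, 2019)  # 38 seasons


@pytest.fixture(scope="session")
def small_area():
    """12-year synthetic area: fast enough for unit tests of stage 1."""
    daily, panel, truth = synthetic_data.simulate_area(range(2000, 2012), seed=42)
    return daily, panel, truth


@pytest.fixture(scope="session")
def small_fit(small_area):
    daily, _, _ = small_area
    cb = dlnm_stage1.build_crossbasis(daily)
    return dlnm_stage1.fit_dlnm(cb, daily["deaths"].to_numpy()), daily


def _one_stage1_replicate(seed: int):
    truth = synthetic_data.default_truth(seed=seed)
    panel = synthetic_data.simulate_indices(STUDY_YEARS, active="AMO", seed=seed)
    temps = synthetic_data.simulate_temperature(panel, truth)
    daily = synthetic_data.simulate_mortality(temps, truth)
    cb = dlnm_stage1.build_crossbasis(daily)
    fit = dlnm_stage1.fit_dlnm(cb, daily["deaths"].to_numpy())
    er = dlnm_stage1.predict_exposure_response(fit, pd.Timestamp(2000, 7, 1))
    mmt_df, af_df = attribution.attribution_table(fit, daily["deaths"].to_numpy())
    truth_af = synthetic_data.truth_implied_af(temps, truth)
    return {
        "truth": truth,
        "daily": daily,
        "fit": fit,
        "er": er,
        "mmt_df": mmt_df,
        "af_df": af_df,
        "truth_af": truth_af,
    }


@pytest.fixture(scope="session")
def stage1_battery():
    """50 full-scale (38-year, city-scale counts) stage-1 replicates."""
    return [_one_stage1_replicate(seed) for seed in range(50)]
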