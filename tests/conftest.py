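import numpy as np
import pandas as pd
import pytest

from pupavision.pipeline import PipelineConfig, process_series
from pupavision.synthetic import GeneratorConfig, generate_pupa_series, make_records


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    """A short-series cohort: 6 pupae, 4 capture days, eclosion on day 5."""
    return GeneratorConfig(n_pupae=6, male_fraction=0.5, unfledged_fraction=0.1, n_days=4, seed=7)


@pytest.fixture(scope="session")
def small_records(small_cfg):
    return make_records(small_cfg)


@pytest.fixture(scope="session")
def small_cohort_processed(small_cfg, small_records):
    """Full in-memory pipeline over the small cohort.

    Returns (records, features frame, list of per-day call lists, pupa calls).
    """
    pcfg = PipelineConfig()
    feats, daily_all, pupa_calls = [], [], []
    for rec in small_records:
        series = generate_pupa_series(small_cfg, rec)
        f, daily, pupa = process_series(series, small_cfg.um_per_px, pcfg)
        feats.append(f)
        daily_all.append(daily)
        pupa_calls.append(pupa)
    return small_records, pd.concat(feats, ignore_index=True), daily_all, pupa_calls


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
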