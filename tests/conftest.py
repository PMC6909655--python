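import dataclasses
from pathlib import Path

import pandas as pd
import pytest

from gdperf.config import RunConfig
from gdperf.pipeline import run_all
from gdperf.synthetic import GeneratorConfig, generate_cohort, write_raw_workbook

#: small corrupted cohort for platform/cleaning unit tests
SMALL_CFG = GeneratorConfig(
    n_patients=6, duration_minutes=(8.0, 12.0), seed=123,
    duplicate_row_rate=0.03, empty_row_rate=0.02, missing_cell_rate=0.02)

#: medium cohort with corruption disabled: derived values equal ground truth
CLEAN_CFG = GeneratorConfig(
    n_patients=30, duration_minutes=(60.0, 90.0), seed=7,
    duplicate_row_rate=0.0, empty_row_rate=0.0, missing_cell_rate=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CFG)


@pytest.fixture(scope="session")
def small_raw_dir(small_cohort, tmp_path_factory) -> Path:
    d = tmp_path_factory.mktemp("raw_small")
    write_raw_workbook(small_cohort, d)
    return d


@pytest.fixture(scope="session")
def clean_cohort():
    return generate_cohort(CLEAN_CFG)


@pytest.fixture(scope="session")
def clean_platform(clean_cohort, tmp_path_factory) -> pd.DataFrame:
    """Derived platform dataset of the corruption-free cohort."""
    from gdperf import platform

    d = tmp_path_factory.mktemp("raw_clean")
    write_raw_workbook(clean_cohort, d)
    merged = platform.ingest_and_merge(d)
    cleaned, _ = platform.clean(merged)
    interped, _ = platform.interpolate_gaps(cleaned)
    demographics = pd.read_csv(d / "demographics.csv")
    return platform.derive_columns(interped, demographics)


@pytest.fixture(scope="session")
def default_run_dir(tmp_path_factory) -> Path:
    """One full-default pipeline run (272 patients), shared session-wide."""
    out = tmp_path_factory.mktemp("run") / "default"
    cfg = dataclasses.replace(RunConfig(output_dir=str(out))).with_seed(0)
    return run_all(cfg)
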