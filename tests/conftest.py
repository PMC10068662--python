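"""Shared fixtures: synthetic bundles and a loaded warehouse.

Session-scoped so that the generator and full ETL run once; tests must
not mutate the fixture objects (take .copy() first).
"""

from __future__ import annotations

import pandas as pd
import pytest

import periopdw as pw

MAP_EPISODES = pw.EpisodeSpec(
    signal_code="MAP",
    threshold=65.0,
    direction="below",
    episode_rate=2.0,
    depth_range=(5.0, 20.0),
    duration_range=(120, 600),
)


@pytest.fixture(scope="session")
def clean_bundle():
    """~12 patients over a 12-day span so one flow-2 window covers all."""
    bundle, truth = pw.generate_bundle(
        12, seed=101, episode_spec=[MAP_EPISODES], study_days=12
    )
    return bundle, truth


@pytest.fixture(scope="session")
def warehouse(clean_bundle, tmp_path_factory):
    """Warehouse loaded from the clean bundle via the weekly cadence."""
    bundle, _truth = clean_bundle
    root = tmp_path_factory.mktemp("wh")
    bundle.to_csv(root / "src")
    wh, logs = pw.run_etl(root / "src", root / "stage", root / "wh.sqlite")
    yield wh, logs
    wh.close()


CORRUPTION_RATES = {
    "missing_id": 0.01,
    "wrong_unit": 0.10,
    "out_of_range": 0.01,
    "misspelled_vocab": 0.01,
    "duplicate_vocab": 0.01,
    "date_discordance": 0.20,
}


@pytest.fixture(scope="session")
def corrupted_bundle(clean_bundle):
    bundle, truth = clean_bundle
    return pw.corrupt_bundle(bundle, CORRUPTION_RATES, seed=202, truth=truth)


@pytest.fixture(scope="session")
def transformed_corrupted(corrupted_bundle):
    bundle, _log = corrupted_bundle
    return pw.transform(bundle, pw.default_config())
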