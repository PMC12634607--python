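import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pvsignal as pv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Study-default drug panel at a size small enough for unit tests."""
    return pv.default_config(n_cases=4000, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return pv.generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_background(small_bundle):
    """Deduplicated, event-flagged background for the small bundle."""
    kept, _, _ = pv.deduplicate(small_bundle.demo)
    background, _ = pv.build_background(kept, small_bundle.drug)
    return pv.add_event_flag(background, small_bundle.reac)


@pytest.fixture(scope="session")
def truth_kept(small_bundle):
    """Truth table restricted to the version deduplication should keep."""
    return small_bundle.truth


def demo_row(caseid, primaryid, fda_dt, **extra):
    """A minimal DEMO row for dedup tests."""
    row = {c: "" for c in pv.io.DEMO_COLUMNS}
    row.update(caseid=caseid, primaryid=primaryid, fda_dt=fda_dt, **extra)
    return row


@pytest.fixture
def demo_frame():
    def build(rows):
        return pd.DataFrame([demo_row(*r) if isinstance(r, tuple) else demo_row(**r)
                             for r in rows], dtype=str)
    return build
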