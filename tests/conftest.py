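"""Shared fixtures: small seeded survey realizations and simple records."""

from __future__ import annotations

import numpy as np
import pytest

from geocontracep.geodata import GeoPoint, WomanRecord
from geocontracep.synthetic import SimConfig, generate_survey


def make_woman(
    woman_id="W0", ea_id="EA0", lon=38.7, lat=9.0, weight=1.0,
    uses_modern=False, method=None, residence="urban", region="Addis Ababa",
    sdp_distance_km=1.0, **overrides,
) -> WomanRecord:
    """A valid record with overridable fields (reference levels by default)."""
    base = dict(
        woman_id=woman_id, ea_id=ea_id,
        household_location=GeoPoint(lon, lat), weight=weight,
        age_group="25-34", education="never", marital="married_union",
        religion="christian", wealth="low", parity="2-3", media="no",
        ever_pregnant="yes", partner_discussion="no",
        partner_feeling="disapprove", fertility_intention="have_another",
        residence=residence, region=region, zone=f"{region}-0W",
        uses_modern=uses_modern,
        method=("injectable" if uses_modern else "none") if method is None else method,
        sdp_distance_km=sdp_distance_km,
    )
    base.update(overrides)
    return WomanRecord(**base)


@pytest.fixture(scope="session")
def small_survey():
    """A 60-EA realization shared by survey/spatial/pipeline tests."""
    return generate_survey(SimConfig(seed=11, n_ea=60, women_in_need_per_ea_mean=12.0,
                                     n_sdp=180))


@pytest.fixture(scope="session")
def default_survey():
    """One full-size default realization (the study conditions)."""
    return generate_survey(SimConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
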