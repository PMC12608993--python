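"""Shared fixtures: small in-memory survey objects and a seeded generator."""

from datetime import date, datetime

import numpy as np
import pytest

from camoverlap import (
    Deployment,
    DetectionEvent,
    SimConfig,
    Site,
    generate_dataset,
)


def dt(*args) -> datetime:
    return datetime(*args)


@pytest.fixture
def rng():
    return np.random.default_rng(20230901)


@pytest.fixture
def tiny_sites():
    return [
        Site("S1", 116.15, 25.15, 400.0, 300.0, 450.0),
        Site("S2", 116.20, 25.20, 650.0, 800.0, 900.0),
        Site("S3", 116.25, 25.25, 1100.0, 2000.0, 2500.0),
    ]


@pytest.fixture
def tiny_deployments():
    return [
        Deployment("S1", date(2023, 1, 1), date(2023, 3, 1)),
        Deployment("S2", date(2023, 1, 1), date(2023, 3, 1)),
        Deployment("S3", date(2023, 1, 1), date(2023, 3, 1),
                   last_photo_date=date(2023, 2, 1)),
    ]


@pytest.fixture(scope="session")
def small_survey():
    """A compact simulated survey reused by pipeline-level tests."""
    cfg = SimConfig(seed=42, n_sites=60, start=date(2023, 1, 10),
                    planned_end=date(2023, 7, 10))
    return cfg, generate_dataset(cfg)


def events_from_frame(det) -> list[DetectionEvent]:
    return [
        DetectionEvent(r.site_id, r.species,
                       datetime.fromisoformat(r.timestamp), bool(r.is_human))
        for r in det.itertuples(index=False)
    ]


def sites_from_frame(sites) -> list[Site]:
    return [
        Site(r.site_id, r.lon, r.lat, r.altitude_m, r.dist_road_m,
             r.dist_settlement_m)
        for r in sites.itertuples(index=False)
    ]


def deployments_from_frame(deps) -> list[Deployment]:
    out = []
    for r in deps.itertuples(index=False):
        last = r.last_photo_date
        out.append(Deployment(
            r.site_id, date.fromisoformat(r.start),
            date.fromisoformat(r.planned_end),
            None if (last is None or last == "") else date.fromisoformat(last)))
    return out
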