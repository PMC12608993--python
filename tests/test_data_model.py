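"""Independence filtering, trap-day counting and RAI."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camoverlap import (
    Deployment,
    DetectionEvent,
    filter_independent,
    human_presence_rate,
    rai,
    site_rai_table,
    site_trap_days,
    trap_days,
)
from camoverlap.data_model import read_detections


def ev(site, species, *ts, human=False):
    return DetectionEvent(site, species, datetime(*ts), is_human=human)


class TestFilterIndependent:
    def test_single_event_retained(self):
        events = [ev("S1", "civet", 2023, 1, 1, 12, 0)]
        assert filter_independent(events) == events

    def test_quiet_period_from_last_retained(self):
        # t, t+10, t+35: the middle trigger falls inside the 30-min window of
        # the first retained event; the third clears it
        events = [ev("S1", "civet", 2023, 1, 1, 12, 0),
                  ev("S1", "civet", 2023, 1, 1, 12, 10),
                  ev("S1", "civet", 2023, 1, 1, 12, 35)]
        kept = filter_independent(events)
        assert [e.timestamp.minute for e in kept] == [0, 35]

    def test_exactly_window_apart_is_independent(self):
        events = [ev("S1", "civet", 2023, 1, 1, 12, 0),
                  ev("S1", "civet", 2023, 1, 1, 12, 30)]
        assert len(filter_independent(events)) == 2

    def test_groups_do_not_suppress_each_other(self):
        events = [ev("S1", "civet", 2023, 1, 1, 12, 0),
                  ev("S1", "rat", 2023, 1, 1, 12, 0),
                  ev("S2", "civet", 2023, 1, 1, 12, 0)]
        assert len(filter_independent(events)) == 3

    def test_idempotent(self):
        events = [ev("S1", "civet", 2023, 1, 1, 12, m) for m in
                  (0, 5, 31, 40, 59)]
        once = filter_independent(events)
        assert filter_independent(once) == once

    @given(minutes=st.lists(st.integers(0, 24 * 60 - 1), min_size=1,
                            max_size=40),
           w1=st.integers(1, 120), w2=st.integers(1, 120))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_retained_count_monotone_in_window(self, minutes, w1, w2):
        base = datetime(2023, 1, 1)
        events = [DetectionEvent("S1", "civet", base + timedelta(minutes=m))
                  for m in minutes]
        lo, hi = sorted((w1, w2))
        assert len(filter_independent(events, hi)) <= \
            len(filter_independent(events, lo))


class TestTrapDays:
    def test_single_day_deployment(self):
        d = Deployment("S1", date(2023, 1, 1), date(2023, 1, 1))
        assert trap_days(d) == 1

    def test_failure_truncates_at_last_photo(self):
        d = Deployment("S1", date(2023, 1, 1), date(2023, 1, 31),
                       last_photo_date=date(2023, 1, 10))
        assert trap_days(d) == 10

    def test_exclusive_planned_end(self):
        d = Deployment("S1", date(2023, 1, 1), date(2023, 1, 31))
        assert trap_days(d) == 30

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            Deployment("S1", date(2023, 2, 1), date(2023, 1, 1))

    def test_site_totals_sum_over_deployments(self):
        deps = [Deployment("S1", date(2023, 1, 1), date(2023, 1, 11)),
                Deployment("S1", date(2023, 2, 1), date(2023, 2, 11)),
                Deployment("S2", date(2023, 1, 1), date(2023, 1, 6))]
        assert site_trap_days(deps) == {"S1": 20.0, "S2": 5.0}


class TestRAI:
    def test_zero_detections(self):
        assert rai(0, 100.0) == 0.0

    def test_linear_in_count_inverse_in_effort(self):
        assert rai(20, 100.0) == 2 * rai(10, 100.0)
        assert rai(10, 200.0) == rai(10, 100.0) / 2

    def test_nonpositive_effort_rejected(self):
        with pytest.raises(ValueError):
            rai(5, 0.0)

    def test_site_table_partitions_study_total(self, tiny_deployments):
        base = datetime(2023, 1, 5)
        events = []
        for k, site in enumerate(["S1", "S1", "S2", "S3"]):
            events.append(DetectionEvent(site, "civet",
                                         base + timedelta(days=k)))
        table = site_rai_table(events, tiny_deployments, ["civet"])
        effort = site_trap_days(tiny_deployments)
        counts = table.assign(
            n=lambda d: d.rai * d.site_id.map(effort) / 100.0)
        assert counts.n.sum() == pytest.approx(len(events))
        # every site appears exactly once per species, zero-filled
        assert sorted(table.site_id) == ["S1", "S2", "S3"]


class TestHumanPresence:
    def test_no_human_events(self, tiny_deployments):
        assert human_presence_rate([], tiny_deployments, "S1") == 0.0

    def test_direct_formula(self):
        deps = [Deployment("S1", date(2023, 1, 1), date(2023, 7, 20))]  # 200 d
        base = datetime(2023, 1, 2, 8, 0)
        events = [DetectionEvent("S1", "human", base + timedelta(days=k),
                                 is_human=True) for k in range(10)]
        assert human_presence_rate(events, deps, "S1") == pytest.approx(5.0)

    def test_unknown_site_rejected(self, tiny_deployments):
        with pytest.raises(KeyError):
            human_presence_rate([], tiny_deployments, "nope")

    def test_poisson_rate_recovery(self, rng):
        # lambda = 0.05/day over 2000 days -> rate estimate near 100*lambda
        lam, days = 0.05, 2000
        deps = [Deployment("S1", date(2018, 1, 1),
                           date(2018, 1, 1) + timedelta(days=days))]
        n = rng.poisson(lam * days)
        times = np.sort(rng.uniform(0, days * 1440, n))
        events = [DetectionEvent("S1", "human",
                                 datetime(2018, 1, 1) + timedelta(minutes=float(m)),
                                 is_human=True) for m in times]
        est = human_presence_rate(events, deps, "S1", window_minutes=None)
        assert est == pytest.approx(100 * lam, abs=3 * 100 * np.sqrt(lam / days))


def test_unparseable_timestamp_rejected_with_reason(tmp_path):
    p = tmp_path / "det.csv"
    p.write_text("site_id,species,timestamp,is_human\n"
                 "S1,civet,2023-01-01T12:00:00,0\n"
                 "S1,civet,not-a-time,0\n")
    events, rejects = read_detections(p)
    assert len(events) == 1
    assert len(rejects) == 1 and "timestamp" in rejects[0]
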