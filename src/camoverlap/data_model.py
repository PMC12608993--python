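"""Detection, site and deployment records, independence filtering and RAI.

The unit of every downstream count is the *independent detection*: a camera
trigger of a species at a site separated from the previously retained trigger
of that (site, species) group by at least the independence window (30 minutes
by default).  Sampling effort is measured in trap-days, truncated at the last
photo date when a camera failed, and abundance is summarised as the relative
abundance index (RAI): independent detections per 100 trap-days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Default quiet period between independent detections, in minutes.
DEFAULT_WINDOW_MINUTES = 30


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class DetectionEvent:
    """One camera trigger: a species seen at a site at a clock time.

    ``is_human`` flags human activity (people on foot and domestic animals);
    such triggers feed the human-presence covariate, not the wildlife counts.
    """

    site_id: str
    species: str
    timestamp: datetime
    is_human: bool = False

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")


@dataclass(frozen=True)
class Deployment:
    """A camera's active interval at a site.

    ``last_photo_date``, when present, truncates the deployment: the last
    photograph taken marks the final operational date of a failed camera.
    """

    site_id: str
    start: date
    planned_end: date
    last_photo_date: date | None = None

    @property
    def effective_end(self) -> date:
        """Exclusive end of the operational interval.

        A failed camera is operational through its last photo day, so the
        exclusive end is the day after; an intact camera runs up to (not
        including) the planned end / retrieval day.
        """
        if self.last_photo_date is not None:
            return min(self.planned_end, self.last_photo_date + timedelta(days=1))
        return self.planned_end

    def __post_init__(self) -> None:
        if self.effective_end < self.start:
            raise ValueError(
                f"deployment at {self.site_id}: effective end "
                f"{self.effective_end} before start {self.start}"
            )

    def contains(self, ts: datetime) -> bool:
        d = ts.date()
        # same-day deployments still cover their single calendar day
        return self.start <= d and (d < self.effective_end or d == self.start)


@dataclass(frozen=True)
class Site:
    """A camera station with its location and disturbance covariates."""

    site_id: str
    lon: float
    lat: float
    altitude: float
    dist_road: float
    dist_settlement: float
    human_presence: float = 0.0  # detections per 100 trap-days

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"site {self.site_id}: coordinates out of range")
        for name in ("altitude", "dist_road", "dist_settlement", "human_presence"):
            if getattr(self, name) < 0:
                raise ValueError(f"site {self.site_id}: {name} must be non-negative")


@dataclass(frozen=True)
class SiteRAI:
    """Per-site, per-species relative abundance index."""

    site_id: str
    species: str
    rai: float

    def __post_init__(self) -> None:
        if self.rai < 0:
            raise ValueError("rai must be non-negative")


# ---------------------------------------------------------------------------
# Independence filtering
# ---------------------------------------------------------------------------

def filter_independent(
    events: Iterable[DetectionEvent],
    window_minutes: int = DEFAULT_WINDOW_MINUTES,
) -> list[DetectionEvent]:
    """Keep one detection per quiet period within each (site, species) group.

    Within a group ordered by time, an event is retained when it falls at
    least ``window_minutes`` after the *previously retained* event; the first
    event of every group is always retained.  Events exactly at the window
    boundary count as independent.  Groups never suppress each other.

    The rule is idempotent and the retained count is non-increasing in
    ``window_minutes``.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    window = timedelta(minutes=window_minutes)
    kept: list[DetectionEvent] = []
    last_kept: dict[tuple[str, str], datetime] = {}
    for ev in sorted(events, key=lambda e: (e.site_id, e.species, e.timestamp)):
        key = (ev.site_id, ev.species)
        prev = last_kept.get(key)
        if prev is None or ev.timestamp - prev >= window:
            kept.append(ev)
            last_kept[key] = ev.timestamp
    kept.sort(key=lambda e: (e.site_id, e.species, e.timestamp))
    return kept


# ---------------------------------------------------------------------------
# Effort and abundance
# ---------------------------------------------------------------------------

def trap_days(deployment: Deployment) -> float:
    """Operational days of a deployment.

    Counts whole days in [start, effective_end) — an exclusive-end convention,
    with the last photo day of a failed camera included.  A deployment whose
    start and end coincide still contributes one trap-day.
    """
    days = (deployment.effective_end - deployment.start).days
    return float(max(days, 1))


def rai(independent_count: int, trap_days: float) -> float:
    """Relative abundance index: detections per 100 trap-days."""
    if trap_days <= 0:
        raise ValueError("trap_days must be positive")
    if independent_count < 0:
        raise ValueError("independent_count must be non-negative")
    return 100.0 * independent_count / trap_days


def site_trap_days(deployments: Sequence[Deployment]) -> dict[str, float]:
    """Total trap-days per site, summed over a site's deployments."""
    out: dict[str, float] = {}
    for dep in deployments:
        out[dep.site_id] = out.get(dep.site_id, 0.0) + trap_days(dep)
    return out


def site_rai_table(
    events: Sequence[DetectionEvent],
    deployments: Sequence[Deployment],
    species: Sequence[str],
    window_minutes: int = DEFAULT_WINDOW_MINUTES,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Long-format per-site RAI for the given species.

    Sites with zero trap-days are excluded (with a logged count).  Every
    remaining site gets a row per species, zero-filled where the species was
    never detected, so RAI vectors over the same site set can be compared.
    """
    effort = site_trap_days(deployments)
    zero = [s for s, td in effort.items() if td <= 0]
    if zero:
        logger.info("excluding %d site(s) with zero trap-days", len(zero))
        effort = {s: td for s, td in effort.items() if td > 0}
    kept = list(events) if prefiltered else filter_independent(events, window_minutes)
    counts: dict[tuple[str, str], int] = {}
    for ev in kept:
        if ev.is_human or ev.species not in species:
            continue
        counts[(ev.site_id, ev.species)] = counts.get((ev.site_id, ev.species), 0) + 1
    rows = [
        {
            "site_id": site,
            "species": sp,
            "rai": rai(counts.get((site, sp), 0), effort[site]),
        }
        for site in sorted(effort)
        for sp in species
    ]
    return pd.DataFrame(rows, columns=["site_id", "species", "rai"])


def human_presence_rate(
    events: Sequence[DetectionEvent],
    deployments: Sequence[Deployment],
    site_id: str,
    window_minutes: int | None = DEFAULT_WINDOW_MINUTES,
) -> float:
    """Human-presence covariate: human/domestic triggers per 100 trap-days.

    Applies the same independence filter as the wildlife counts by default;
    pass ``window_minutes=None`` to count raw triggers.
    """
    effort = site_trap_days(deployments).get(site_id)
    if effort is None:
        raise KeyError(f"unknown site {site_id!r}")
    if effort <= 0:
        raise ValueError(f"site {site_id!r} has no positive trap-days")
    human = [e for e in events if e.site_id == site_id and e.is_human]
    if window_minutes is not None:
        human = filter_independent(human, window_minutes)
    return rai(len(human), effort)


# ---------------------------------------------------------------------------
# CSV I/O — the three standard input tables
# ---------------------------------------------------------------------------

DETECTIONS_COLUMNS = ["site_id", "species", "timestamp", "is_human"]
SITES_COLUMNS = ["site_id", "lon", "lat", "altitude_m", "dist_road_m",
                 "dist_settlement_m"]
DEPLOYMENTS_COLUMNS = ["site_id", "start", "planned_end", "last_photo_date"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def read_detections(path: str | Path) -> tuple[list[DetectionEvent], list[str]]:
    """Read detections.csv; returns (events, reject reasons).

    Records with unparseable timestamps are rejected, not fatal, and each
    reject is reported with its reason.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "species": str})
    _require_columns(df, DETECTIONS_COLUMNS[:3], "detections")
    if "is_human" not in df.columns:
        df["is_human"] = 0
    events: list[DetectionEvent] = []
    rejects: list[str] = []
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    for i, row in enumerate(df.itertuples(index=False)):
        t = ts.iloc[i]
        if pd.isna(t):
            rejects.append(f"row {i}: unparseable timestamp {row.timestamp!r}")
            continue
        try:
            events.append(
                DetectionEvent(
                    site_id=str(row.site_id),
                    species=str(row.species),
                    timestamp=t.to_pydatetime(),
                    is_human=bool(int(row.is_human)),
                )
            )
        except (ValueError, TypeError) as exc:
            rejects.append(f"row {i}: {exc}")
    for r in rejects:
        logger.warning("rejected detection %s", r)
    return events, rejects


def read_sites(path: str | Path) -> list[Site]:
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, SITES_COLUMNS, "sites")
    has_hp = "human_presence" in df.columns
    return [
        Site(
            site_id=str(r.site_id),
            lon=float(r.lon),
            lat=float(r.lat),
            altitude=float(r.altitude_m),
            dist_road=float(r.dist_road_m),
            dist_settlement=float(r.dist_settlement_m),
            human_presence=float(r.human_presence) if has_hp else 0.0,
        )
        for r in df.itertuples(index=False)
    ]


def read_deployments(path: str | Path) -> list[Deployment]:
    df = pd.read_csv(path, dtype={"site_id": str})
    _require_columns(df, DEPLOYMENTS_COLUMNS[:3], "deployments")
    if "last_photo_date" not in df.columns:
        df["last_photo_date"] = None
    out = []
    for r in df.itertuples(index=False):
        last = r.last_photo_date
        last_d = None if pd.isna(last) else pd.Timestamp(last).date()
        out.append(
            Deployment(
                site_id=str(r.site_id),
                start=pd.Timestamp(r.start).date(),
                planned_end=pd.Timestamp(r.planned_end).date(),
                last_photo_date=last_d,
            )
        )
    return out
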