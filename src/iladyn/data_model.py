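"""Domain types, CSV I/O, rescaling, episode geometry, and lag-pair rules.

The package works on long-format affect data collected under three
intensive-longitudinal assessment (ILA) methods:

* ``EMA`` -- momentary prompts, several per day, timestamped;
* ``EOD`` -- one end-of-day diary rating per day;
* ``DRM`` -- one day reconstructed as contiguous episodes, each rated on a
  0-6 scale and rescaled to 0-100 at ingest.

All downstream measures operate on 0-100 positive-affect (PA) and
negative-affect (NA) scores.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Method",
    "Affect",
    "SchemaError",
    "ValidationError",
    "AffectObservation",
    "DRMEpisode",
    "PersonSeries",
    "LagPair",
    "StudyDataset",
    "RESCALE_STEP",
    "rescale_drm",
    "drm_raw_from_score",
    "episode_midpoint",
    "episodes_to_series",
    "apply_inclusion_filter",
    "lagged_pairs",
    "method_lag_rules",
    "read_ila_csv",
    "read_observations_csv",
    "read_episodes_csv",
    "read_health_csv",
    "load_study",
    "write_observations_csv",
    "write_episodes_csv",
    "write_health_csv",
]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"

#: Width of one raw DRM scale step after rescaling to 0-100.
RESCALE_STEP = 100.0 / 7.0


class Method(str, enum.Enum):
    """Intensive-longitudinal assessment method."""

    EMA = "EMA"
    EOD = "EOD"
    DRM = "DRM"


class Affect(str, enum.Enum):
    """Affect valence of a rating column."""

    PA = "pa"
    NA = "na"


class SchemaError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(ValueError):
    """A record violates a range or ordering invariant."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


def rescale_drm(raw: int) -> float:
    """Map a raw 0-6 episode rating onto the 0-100 scale.

    The transform is ``100 * (raw + 0.5) / 7`` -- affine with slope 100/7,
    placing each raw category at the midpoint of its bin on 0-100.
    """
    if raw != int(raw):
        raise ValueError(f"raw DRM score must be an integer, got {raw!r}")
    raw = int(raw)
    if not 0 <= raw <= 6:
        raise ValueError(f"raw DRM score must be in [0, 6], got {raw}")
    return 100.0 * (raw + 0.5) / 7.0


def drm_raw_from_score(score: float) -> int:
    """Invert :func:`rescale_drm`: quantize a 0-100 value to raw 0-6.

    Uses round-half-away-from-zero; ties cannot occur for scores produced
    by :func:`rescale_drm` because they sit mid-bin.
    """
    x = score * 7.0 / 100.0 - 0.5
    raw = int(x + 0.5) if x >= 0 else -int(-x + 0.5)
    return min(6, max(0, raw))


@dataclass(frozen=True)
class AffectObservation:
    """One time-stamped PA/NA rating by one person under one method."""

    person_id: str
    method: Method
    timestamp: datetime
    day_index: int
    pa: float
    na: float

    def __post_init__(self):
        for name in ("pa", "na"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name}={v} outside [0, 100]")

    def value(self, affect: Affect | str) -> float:
        return getattr(self, Affect(affect).value)


@dataclass(frozen=True)
class DRMEpisode:
    """One self-defined episode of a reconstructed day, rated on 0-6."""

    person_id: str
    start: datetime
    end: datetime
    raw_pa: int
    raw_na: int
    label: str = ""

    def __post_init__(self):
        if self.end < self.start:
            raise ValidationError(
                f"episode end {self.end} precedes start {self.start}"
            )
        for name in ("raw_pa", "raw_na"):
            v = getattr(self, name)
            if v != int(v) or not 0 <= int(v) <= 6:
                raise ValidationError(f"{name}={v} not an integer in [0, 6]")


def episode_midpoint(e: DRMEpisode) -> datetime:
    """Temporal midpoint of an episode; lag gaps for DRM use midpoints."""
    if e.end == e.start:
        warnings.warn(
            f"zero-duration episode for {e.person_id} at {e.start}; "
            "midpoint equals start",
            stacklevel=2,
        )
        return e.start
    return e.start + (e.end - e.start) / 2


@dataclass
class PersonSeries:
    """Ordered affect observations of one person under one method."""

    person_id: str
    method: Method
    observations: list[AffectObservation]

    def __post_init__(self):
        if not self.observations:
            raise ValidationError(
                f"empty series for person {self.person_id!r}"
            )
        self.observations = sorted(self.observations, key=lambda o: o.timestamp)
        for prev, nxt in zip(self.observations, self.observations[1:]):
            if nxt.timestamp <= prev.timestamp:
                raise ValidationError(
                    f"non-increasing timestamps for person "
                    f"{self.person_id!r}/{self.method.value} at {nxt.timestamp}"
                )

    def __len__(self) -> int:
        return len(self.observations)

    def values(self, affect: Affect | str) -> list[float]:
        a = Affect(affect)
        return [o.value(a) for o in self.observations]

    def timestamps(self) -> list[datetime]:
        return [o.timestamp for o in self.observations]


@dataclass(frozen=True)
class LagPair:
    """Two successive observations retained by the lag rules."""

    prev: AffectObservation
    next: AffectObservation

    @property
    def gap_hours(self) -> float:
        return (self.next.timestamp - self.prev.timestamp).total_seconds() / 3600.0

    def diff(self, affect: Affect | str) -> float:
        a = Affect(affect)
        return self.next.value(a) - self.prev.value(a)


@dataclass
class StudyDataset:
    """All series of a study plus per-person daily health records."""

    series: dict[tuple[str, Method], PersonSeries] = field(default_factory=dict)
    health: pd.DataFrame | None = None
    exclusions: list[dict] = field(default_factory=list)

    def persons(self) -> list[str]:
        return sorted({pid for pid, _ in self.series})

    def methods(self) -> list[Method]:
        present = {m for _, m in self.series}
        return [m for m in Method if m in present]

    def get(self, person_id: str, method: Method) -> PersonSeries | None:
        return self.series.get((person_id, Method(method)))

    def series_for_method(self, method: Method) -> dict[str, PersonSeries]:
        m = Method(method)
        return {pid: s for (pid, mm), s in self.series.items() if mm == m}

    def add(self, series: PersonSeries) -> None:
        self.series[(series.person_id, series.method)] = series


# ---------------------------------------------------------------------------
# lag rules


def method_lag_rules(method: Method) -> dict:
    """Default lag-pair construction rules per method.

    EMA drops overnight pairs and pairs with gaps over 10 h; DRM (midpoint
    timestamps) applies only the 10 h cap; EOD keeps only pairs of diaries
    from consecutive calendar days, with no hour cap.
    """
    method = Method(method)
    if method is Method.EMA:
        return {"max_gap_hours": 10.0, "cross_day_rule": "omit_cross_day"}
    if method is Method.DRM:
        return {"max_gap_hours": 10.0, "cross_day_rule": "none"}
    return {"max_gap_hours": None, "cross_day_rule": "consecutive_days_only"}


def lagged_pairs(
    s: PersonSeries,
    max_gap_hours: float | None = 10.0,
    cross_day_rule: str = "omit_cross_day",
) -> list[LagPair]:
    """Successive-observation pairs passing the active gap rules.

    Parameters
    ----------
    max_gap_hours : float or None
        Drop pairs further apart than this many hours. ``None`` disables
        the cap (used for end-of-day diaries).
    cross_day_rule : {"omit_cross_day", "consecutive_days_only", "none"}
        ``omit_cross_day`` drops pairs whose timestamps fall on different
        calendar dates (the overnight rule for EMA); ``consecutive_days_only``
        keeps only pairs whose day indices differ by exactly 1 (EOD);
        ``none`` applies no day-based rule.
    """
    if cross_day_rule not in ("omit_cross_day", "consecutive_days_only", "none"):
        raise ValueError(f"unknown cross_day_rule {cross_day_rule!r}")
    out: list[LagPair] = []
    obs = s.observations
    for prev, nxt in zip(obs, obs[1:]):
        gap = (nxt.timestamp - prev.timestamp).total_seconds() / 3600.0
        if max_gap_hours is not None and gap > max_gap_hours:
            continue
        if cross_day_rule == "omit_cross_day":
            if prev.timestamp.date() != nxt.timestamp.date():
                continue
        elif cross_day_rule == "consecutive_days_only":
            if nxt.day_index - prev.day_index != 1:
                continue
        out.append(LagPair(prev, nxt))
    return out


def lagged_pairs_for_method(s: PersonSeries) -> list[LagPair]:
    """Lag pairs under the series' own method defaults."""
    return lagged_pairs(s, **method_lag_rules(s.method))


# ---------------------------------------------------------------------------
# inclusion filter


def apply_inclusion_filter(
    dataset: StudyDataset, min_obs: int = 4
) -> tuple[StudyDataset, list[dict]]:
    """Retain persons with at least ``min_obs`` observations on every method.

    Observation counts are taken after ingest validation and before lag
    filtering. Returns the filtered dataset and an exclusion report listing
    each dropped person with the failing method(s). Idempotent.
    """
    if not dataset.series:
        raise ValueError("empty dataset")
    methods = dataset.methods()
    report: list[dict] = []
    keep: set[str] = set()
    for pid in dataset.persons():
        failing = []
        for m in methods:
            s = dataset.get(pid, m)
            n = len(s) if s is not None else 0
            if n < min_obs:
                failing.append(m.value)
        if failing:
            report.append({"person_id": pid, "failing_methods": failing})
        else:
            keep.add(pid)
    series = {k: v for k, v in dataset.series.items() if k[0] in keep}
    health = dataset.health
    if health is not None:
        health = health[health["person_id"].isin(keep)].reset_index(drop=True)
    return StudyDataset(series=series, health=health, exclusions=report), report


# ---------------------------------------------------------------------------
# CSV I/O

OBSERVATION_COLUMNS = ["person_id", "method", "timestamp", "day_index", "pa", "na"]
EPISODE_COLUMNS = [
    "person_id",
    "date",
    "start_time",
    "end_time",
    "raw_pa",
    "raw_na",
    "label",
]
HEALTH_COLUMNS = ["person_id", "day_index", "general_health", "pain", "fatigue"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def _parse_timestamp(value: str, row: int) -> datetime:
    try:
        return datetime.strptime(str(value), TIMESTAMP_FORMAT)
    except ValueError:
        try:
            return datetime.fromisoformat(str(value))
        except ValueError:
            raise ValidationError(
                f"timestamp {value!r} does not parse as ISO-8601", row=row
            ) from None


def read_observations_csv(path) -> list[AffectObservation]:
    """Read and validate an observations CSV (EMA/EOD/DRM long format)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, OBSERVATION_COLUMNS, path)
    out = []
    for i, rec in enumerate(df.itertuples(index=False)):
        row = i + 2  # header is row 1
        try:
            method = Method(rec.method)
        except ValueError:
            raise ValidationError(f"unknown method {rec.method!r}", row=row) from None
        ts = _parse_timestamp(rec.timestamp, row)
        try:
            pa, na = float(rec.pa), float(rec.na)
            day = int(rec.day_index)
        except ValueError as exc:
            raise ValidationError(str(exc), row=row) from None
        if not 0.0 <= pa <= 100.0:
            raise ValidationError(f"pa={pa} outside [0, 100]", row=row)
        if not 0.0 <= na <= 100.0:
            raise ValidationError(f"na={na} outside [0, 100]", row=row)
        out.append(AffectObservation(str(rec.person_id), method, ts, day, pa, na))
    out.sort(key=lambda o: (o.person_id, o.method.value, o.timestamp))
    seen: dict[tuple[str, Method], datetime] = {}
    for o in out:
        key = (o.person_id, o.method)
        if key in seen and o.timestamp <= seen[key]:
            raise ValidationError(
                f"duplicate timestamp {o.timestamp} for person "
                f"{o.person_id!r}/{o.method.value}"
            )
        seen[key] = o.timestamp
    return out


def read_episodes_csv(path) -> list[DRMEpisode]:
    """Read and validate a DRM episodes CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, [c for c in EPISODE_COLUMNS if c != "label"], path)
    out = []
    for i, rec in enumerate(df.itertuples(index=False)):
        row = i + 2
        try:
            d = date.fromisoformat(str(rec.date))
            start_t = time.fromisoformat(str(rec.start_time))
            end_t = time.fromisoformat(str(rec.end_time))
            raw_pa, raw_na = int(rec.raw_pa), int(rec.raw_na)
        except ValueError as exc:
            raise ValidationError(str(exc), row=row) from None
        start = datetime.combine(d, start_t)
        end = datetime.combine(d, end_t)
        if end < start:
            raise ValidationError(
                f"episode end {end_t} precedes start {start_t}", row=row
            )
        label = getattr(rec, "label", "")
        try:
            out.append(DRMEpisode(str(rec.person_id), start, end, raw_pa, raw_na, label))
        except ValidationError as exc:
            raise ValidationError(str(exc), row=row) from None
    out.sort(key=lambda e: (e.person_id, e.start))
    for prev, nxt in zip(out, out[1:]):
        if prev.person_id == nxt.person_id and nxt.start < prev.end:
            raise ValidationError(
                f"overlapping episodes for person {prev.person_id!r} "
                f"at {nxt.start}"
            )
    return out


def read_health_csv(path) -> pd.DataFrame:
    """Read and validate the daily health CSV."""
    df = pd.read_csv(path)
    _require_columns(df, HEALTH_COLUMNS, path)
    for i, rec in enumerate(df.itertuples(index=False)):
        row = i + 2
        if not 1 <= rec.general_health <= 5:
            raise ValidationError(
                f"general_health={rec.general_health} outside [1, 5]", row=row
            )
        for name in ("pain", "fatigue"):
            v = getattr(rec, name)
            if not 0 <= v <= 100:
                raise ValidationError(f"{name}={v} outside [0, 100]", row=row)
    df = df.copy()
    df["person_id"] = df["person_id"].astype(str)
    return df.sort_values(["person_id", "day_index"]).reset_index(drop=True)


def read_ila_csv(path, schema: str):
    """Dispatching reader: ``schema`` is one of observations/episodes/health."""
    readers = {
        "observations": read_observations_csv,
        "episodes": read_episodes_csv,
        "health": read_health_csv,
    }
    if schema not in readers:
        raise SchemaError(f"unknown schema {schema!r}")
    return readers[schema](path)


def episodes_to_series(
    episodes: Iterable[DRMEpisode],
    day_origin: date | Mapping[str, date] | None = None,
) -> list[PersonSeries]:
    """Convert DRM episodes to midpoint-timestamped 0-100 observations.

    ``day_origin`` maps episode dates to 1-based study day indices (study
    day 1 starts at the origin date). If omitted, the earliest episode
    date in the input is used as the origin.
    """
    eps = sorted(episodes, key=lambda e: (e.person_id, e.start))
    if not eps:
        return []
    if day_origin is None:
        day_origin = min(e.start.date() for e in eps)
    out: list[PersonSeries] = []
    by_person: dict[str, list[DRMEpisode]] = {}
    for e in eps:
        by_person.setdefault(e.person_id, []).append(e)
    for pid, group in by_person.items():
        origin = day_origin[pid] if isinstance(day_origin, Mapping) else day_origin
        obs = []
        for e in group:
            mid = episode_midpoint(e)
            obs.append(
                AffectObservation(
                    person_id=pid,
                    method=Method.DRM,
                    timestamp=mid,
                    day_index=(e.start.date() - origin).days + 1,
                    pa=rescale_drm(e.raw_pa),
                    na=rescale_drm(e.raw_na),
                )
            )
        out.append(PersonSeries(pid, Method.DRM, obs))
    return out


def load_study(
    observations_path=None, episodes_path=None, health_path=None
) -> StudyDataset:
    """Assemble a :class:`StudyDataset` from the three CSV files."""
    ds = StudyDataset()
    origin = None
    if observations_path is not None:
        obs = read_observations_csv(observations_path)
        grouped: dict[tuple[str, Method], list[AffectObservation]] = {}
        for o in obs:
            grouped.setdefault((o.person_id, o.method), []).append(o)
        for (pid, m), group in grouped.items():
            ds.add(PersonSeries(pid, m, group))
        if obs:
            origin = min(
                o.timestamp.date() - timedelta(days=o.day_index - 1) for o in obs
            )
    if episodes_path is not None:
        for s in episodes_to_series(read_episodes_csv(episodes_path), origin):
            ds.add(s)
    if health_path is not None:
        ds.health = read_health_csv(health_path)
    return ds


def _format_float(x: float) -> str:
    return repr(float(x))


def write_observations_csv(dataset: StudyDataset, path) -> None:
    rows = []
    for (pid, m) in sorted(dataset.series, key=lambda k: (k[0], k[1].value)):
        for o in dataset.series[(pid, m)].observations:
            rows.append(
                {
                    "person_id": pid,
                    "method": m.value,
                    "timestamp": o.timestamp.strftime(TIMESTAMP_FORMAT),
                    "day_index": o.day_index,
                    "pa": _format_float(o.pa),
                    "na": _format_float(o.na),
                }
            )
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def write_episodes_csv(episodes: Sequence[DRMEpisode], path) -> None:
    rows = []
    for e in sorted(episodes, key=lambda e: (e.person_id, e.start)):
        rows.append(
            {
                "person_id": e.person_id,
                "date": e.start.date().isoformat(),
                "start_time": e.start.time().isoformat(timespec="seconds"),
                "end_time": e.end.time().isoformat(timespec="seconds"),
                "raw_pa": e.raw_pa,
                "raw_na": e.raw_na,
                "label": e.label,
            }
        )
    pd.DataFrame(rows, columns=EPISODE_COLUMNS).to_csv(path, index=False)


def write_health_csv(health: pd.DataFrame, path) -> None:
    health.to_csv(path, index=False)
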